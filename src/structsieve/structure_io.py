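"""Reading and writing protein coordinate files and aligned-FASTA alignments.

PDB parsing and writing go through gemmi.  Parsing selects a single chain and
model, drops waters, hydrogens and any residue without a carbon Cα (so amino
acids recorded as HETATM, e.g. selenomethionine, are kept while ligands and
metal ions are not), and resolves alternate locations by highest occupancy
(ties by file order).  Residues dropped for a missing Cα are counted in the
structure's parse report.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "ParseError",
    "Residue",
    "Structure",
    "CaTrace",
    "read_structure",
    "extract_ca_trace",
    "read_alignment_fasta",
    "write_alignment_fasta",
    "write_ensemble_pdb",
    "make_mixed_model",
    "trace_to_structure",
]

MIXED_MODEL_ATOMS = ("N", "CA", "C", "O", "CB")


class ParseError(ValueError):
    """Raised when a coordinate or alignment file cannot be interpreted."""


@dataclass
class Residue:
    """One amino-acid residue: identity plus atom-name -> coordinate map (Å)."""

    chain_id: str
    seq_number: int
    insertion_code: str
    residue_name: str
    atoms: dict
    elements: dict = field(default_factory=dict)

    @property
    def label(self) -> tuple:
        return (self.residue_name, self.seq_number, self.insertion_code)

    @property
    def ca(self) -> np.ndarray:
        return self.atoms["CA"]

    def one_letter(self) -> str:
        info = gemmi.find_tabulated_residue(self.residue_name)
        if info is None or not info.is_amino_acid():
            return "X"
        code = info.one_letter_code.upper()
        return code if code.isalpha() else "X"


@dataclass
class Structure:
    """An ordered single-chain residue sequence from one coordinate file."""

    structure_id: str
    residues: list
    source_path: str = ""
    parse_report: tuple = ()

    def __post_init__(self) -> None:
        if not self.residues:
            raise ParseError(f"structure {self.structure_id!r} has no residues")
        keys = [(r.chain_id, r.seq_number, r.insertion_code) for r in self.residues]
        if len(set(keys)) != len(keys):
            raise ParseError(
                f"structure {self.structure_id!r} has duplicate residue identifiers"
            )
        for r in self.residues:
            if "CA" not in r.atoms:
                raise ParseError(
                    f"residue {r.residue_name} {r.seq_number}{r.insertion_code} "
                    f"in {self.structure_id!r} lacks a CA atom"
                )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class CaTrace:
    """Cα coordinates of a structure with per-residue labels."""

    structure_id: str
    coords: np.ndarray
    labels: list

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        if len(self.coords) != len(self.labels):
            raise ParseError("coords and labels must have equal length")

    def __len__(self) -> int:
        return len(self.labels)

    def sequence(self) -> str:
        out = []
        for name, _, _ in self.labels:
            info = gemmi.find_tabulated_residue(name)
            ok = info is not None and info.is_amino_acid()
            code = info.one_letter_code.upper() if ok else "X"
            out.append(code if code.isalpha() else "X")
        return "".join(out)


def _select_altlocs(res: gemmi.Residue) -> list:
    """One atom per name: highest occupancy wins, ties go to file order."""
    chosen: dict = {}
    for atom in res:
        if atom.element.is_hydrogen:
            continue
        prev = chosen.get(atom.name)
        if prev is None or atom.occ > prev.occ:
            chosen[atom.name] = atom
    # preserve first-appearance order of atom names
    order = []
    for atom in res:
        if atom.name in chosen and atom.name not in order:
            order.append(atom.name)
    return [chosen[n] for n in order]


def read_structure(path, chain: str = "first", model: int = 1) -> Structure:
    """Read one chain of one model from a PDB (or mmCIF) file.

    Waters, hydrogens and residues without a carbon Cα are excluded; alternate
    locations are resolved by occupancy.  `chain="first"` selects the first
    chain in the file.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"coordinate file not found: {path}")
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as e:
        raise ParseError(f"cannot parse {path}: {e}") from None
    if len(st) == 0:
        raise ParseError(f"{path} contains no models")
    picked = None
    for m in st:
        if m.num == model:
            picked = m
            break
    if picked is None:
        if model == 1:
            picked = st[0]
        else:
            raise ParseError(f"{path} has no model {model}")
    if len(picked) == 0:
        raise ParseError(f"{path} model {picked.num} has no chains")
    if chain == "first":
        ch = picked[0]
    else:
        ch = picked.find_chain(chain)
        if ch is None:
            names = ", ".join(c.name for c in picked)
            raise ParseError(
                f"chain {chain!r} not found in {path} (available: {names})"
            )

    residues = []
    dropped = 0
    report = []
    for res in ch:
        if res.is_water():
            continue
        atoms = _select_altlocs(res)
        names = {a.name: a for a in atoms}
        ca = names.get("CA")
        if ca is None or ca.element.name != "C":
            dropped += 1
            continue
        residues.append(
            Residue(
                chain_id=ch.name,
                seq_number=res.seqid.num,
                insertion_code=(res.seqid.icode or "").strip(),
                residue_name=res.name,
                atoms={
                    a.name: np.array([a.pos.x, a.pos.y, a.pos.z]) for a in atoms
                },
                elements={a.name: a.element.name for a in atoms},
            )
        )
    if dropped:
        report.append(
            f"{path} chain {ch.name}: dropped {dropped} residue(s) without a CA atom"
        )
        logger.info(report[-1])
    if not residues:
        raise ParseError(f"no CA atoms found in {path} chain {ch.name}")
    return Structure(
        structure_id=f"{path.stem}:{ch.name}",
        residues=residues,
        source_path=str(path),
        parse_report=tuple(report),
    )


def extract_ca_trace(s: Structure) -> CaTrace:
    """Cα coordinates and labels of a Structure, in residue order."""
    coords = np.stack([r.ca for r in s.residues])
    labels = [r.label for r in s.residues]
    return CaTrace(structure_id=s.structure_id, coords=coords, labels=labels)


def read_alignment_fasta(path, traces=None):
    """Read an aligned-FASTA file into a MultipleAlignment.

    Gap character is '-'.  When `traces` are supplied (matched to rows by
    order), each row's letters are validated against the trace's residue
    sequence ('X' acts as a wildcard) and column entries become residue
    indices of that trace.
    """
    from Bio import SeqIO

    from .msa_engine import GAP, MultipleAlignment

    path = Path(path)
    if not path.exists():
        raise ParseError(f"alignment file not found: {path}")
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) < 2:
        raise ParseError(f"{path}: an alignment needs at least 2 rows")
    L = len(records[0].seq)
    for rec in records:
        if len(rec.seq) != L:
            raise ParseError(
                f"{path}: row {rec.id!r} has length {len(rec.seq)}, expected {L}"
            )
    if traces is not None:
        traces = list(traces)
        if len(traces) != len(records):
            raise ParseError(
                f"{path}: {len(records)} rows but {len(traces)} traces given"
            )
        by_id = {t.structure_id: t for t in traces}
        if set(by_id) == {rec.id for rec in records}:
            traces = [by_id[rec.id] for rec in records]
        ids = [t.structure_id for t in traces]
    else:
        ids = [rec.id for rec in records]
        if len(set(ids)) != len(ids):
            ids = [f"{rec.id}#{k}" for k, rec in enumerate(records)]

    M = np.full((len(records), L), GAP, dtype=int)
    for k, rec in enumerate(records):
        seq = str(rec.seq).upper()
        ref = traces[k].sequence() if traces is not None else None
        pos = 0
        for c, letter in enumerate(seq):
            if letter == "-":
                continue
            if ref is not None:
                if pos >= len(ref):
                    raise ParseError(
                        f"{path}: row {rec.id!r} has more residues than its trace"
                    )
                if letter != ref[pos] and letter != "X" and ref[pos] != "X":
                    raise ParseError(
                        f"{path}: row {rec.id!r} column {c + 1}: letter "
                        f"{letter!r} does not match residue {pos + 1} "
                        f"({ref[pos]!r}) of {ids[k]!r}"
                    )
            M[k, c] = pos
            pos += 1
        if ref is not None and pos != len(ref):
            raise ParseError(
                f"{path}: row {rec.id!r} covers {pos} residues but trace "
                f"{ids[k]!r} has {len(ref)}"
            )
    return MultipleAlignment(tuple(ids), M)


def write_alignment_fasta(msa, traces, path) -> None:
    """Write a MultipleAlignment as aligned FASTA ('-' gaps), one row per trace."""
    traces = list(traces)
    tmap = {t.structure_id: t for t in traces}
    if set(tmap) != set(msa.structure_ids):
        raise ParseError("traces do not match the alignment's structure ids")
    lines = []
    for k, sid in enumerate(msa.structure_ids):
        seq = tmap[sid].sequence()
        row = msa.index_matrix[k]
        lines.append(f">{sid}")
        lines.append("".join("-" if i < 0 else seq[i] for i in row))
    Path(path).write_text("\n".join(lines) + "\n")


def _guess_element(atom_name: str) -> str:
    name = atom_name.strip()
    if not name:
        return "C"
    return name[0] if name[0].isalpha() else (name[1] if len(name) > 1 else "C")


def write_ensemble_pdb(structures, superposition=None, model=None, path=None) -> None:
    """Write a superposed ensemble as a multi-MODEL PDB file.

    One MODEL/ENDMDL block per retained structure, every atom of each retained
    residue transformed by that structure's rigid transform.  When a
    SievedModel is given only residues mapped by its retained columns are
    written, and REMARK 300 lines record the threshold, NCORE and RMSD.
    `superposition=None` writes the structures untransformed.
    """
    from .superposition import RigidTransform

    structures = list(structures)
    smap = {s.structure_id: s for s in structures}

    if model is not None:
        superposition = model.superposition
    if superposition is not None:
        ids = [sid for sid in superposition.structure_ids if sid in smap]
        transforms = {
            sid: superposition.transform_for(sid) for sid in ids
        }
    else:
        ids = [s.structure_id for s in structures]
        transforms = {sid: RigidTransform.identity() for sid in ids}
    if not ids:
        raise ParseError("no retained structures to write")

    keep_residues = None
    if model is not None:
        keep_residues = {}
        aln = model.alignment
        for sid in ids:
            k = aln.structure_ids.index(sid)
            row = aln.index_matrix[k]
            keep_residues[sid] = set(int(i) for i in row[row >= 0])

    st = gemmi.Structure()
    st.name = "structsieve ensemble"
    remarks = []
    if model is not None:
        remarks.append(f"REMARK 300 SIEVE THRESHOLD {model.threshold:.3f} ANGSTROM")
        remarks.append(f"REMARK 300 NCORE {model.ncore}")
        remarks.append(
            f"REMARK 300 POOLED RMSD {model.superposition.pooled_rmsd:.4f} ANGSTROM"
        )
    elif superposition is not None:
        remarks.append(
            f"REMARK 300 POOLED RMSD {superposition.pooled_rmsd:.4f} ANGSTROM"
        )
    for num, sid in enumerate(ids, start=1):
        remarks.append(f"REMARK 300 MEMBER {num} STRUCTURE {sid}")

    for num, sid in enumerate(ids, start=1):
        s = smap[sid]
        T = transforms[sid]
        gm = gemmi.Model(num)
        gch = gemmi.Chain(s.residues[0].chain_id or "A")
        for ri, res in enumerate(s.residues):
            if keep_residues is not None and ri not in keep_residues[sid]:
                continue
            gr = gemmi.Residue()
            gr.name = res.residue_name
            gr.seqid = gemmi.SeqId(res.seq_number, res.insertion_code or " ")
            for name, xyz in res.atoms.items():
                a = gemmi.Atom()
                a.name = name
                x, y, z = T.apply(np.asarray(xyz, dtype=float)[None, :])[0]
                a.pos = gemmi.Position(x, y, z)
                a.occ = 1.0
                elem = res.elements.get(name) or _guess_element(name)
                a.element = gemmi.Element(elem)
                gr.add_atom(a)
            gch.add_residue(gr)
        gm.add_chain(gch)
        st.add_model(gm)
    st.raw_remarks = remarks
    Path(path).write_text(st.make_pdb_string())


def make_mixed_model(s: Structure, conserved_mask) -> Structure:
    """Alanine-trim non-conserved residues of a full-atom structure.

    Residues where the mask is False are renamed ALA and truncated to
    {N, CA, C, O, CB}; glycines are left untouched (no CB is fabricated).
    Conserved residues are copied unchanged.  Coordinates of kept atoms are
    never modified.
    """
    mask = list(conserved_mask)
    if len(mask) != len(s.residues):
        raise ParseError(
            f"mask length {len(mask)} does not match residue count {len(s.residues)}"
        )
    out = []
    for res, keep in zip(s.residues, mask):
        if keep or res.residue_name == "GLY":
            out.append(
                Residue(
                    res.chain_id,
                    res.seq_number,
                    res.insertion_code,
                    res.residue_name,
                    dict(res.atoms),
                    dict(res.elements),
                )
            )
        else:
            atoms = {
                n: v for n, v in res.atoms.items() if n in MIXED_MODEL_ATOMS
            }
            elements = {n: v for n, v in res.elements.items() if n in atoms}
            out.append(
                Residue(
                    res.chain_id,
                    res.seq_number,
                    res.insertion_code,
                    "ALA",
                    atoms,
                    elements,
                )
            )
    return Structure(
        structure_id=s.structure_id,
        residues=out,
        source_path=s.source_path,
        parse_report=s.parse_report,
    )


def trace_to_structure(trace: CaTrace, chain_id: str = "A") -> Structure:
    """Promote a Cα trace to a CA-only Structure (for writing fixtures)."""
    residues = [
        Residue(
            chain_id=chain_id,
            seq_number=num,
            insertion_code=icode,
            residue_name=name,
            atoms={"CA": np.asarray(trace.coords[i], dtype=float)},
            elements={"CA": "C"},
        )
        for i, (name, num, icode) in enumerate(trace.labels)
    ]
    return Structure(structure_id=trace.structure_id, residues=residues)
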