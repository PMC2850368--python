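import numpy as np
import pytest

from structsieve.msa_engine import MultipleAlignment
from structsieve.structure_io import (
    ParseError,
    extract_ca_trace,
    make_mixed_model,
    read_alignment_fasta,
    read_structure,
    trace_to_structure,
    write_alignment_fasta,
    write_ensemble_pdb,
)
from structsieve.superposition import superpose_ensemble
from structsieve.synthetic_fixtures import make_core_loop_ensemble, make_template


class TestReadStructure:
    def test_chain_selection(self, two_chain_pdb):
        sB = read_structure(two_chain_pdb, chain="B")
        assert [r.residue_name for r in sB.residues] == ["ALA", "SER"]
        assert all(r.chain_id == "B" for r in sB.residues)

    def test_first_chain_default(self, two_chain_pdb):
        s = read_structure(two_chain_pdb, chain="first")
        assert s.residues[0].chain_id == "A"
        assert len(s) == 3

    def test_altloc_keeps_highest_occupancy(self, two_chain_pdb):
        s = read_structure(two_chain_pdb, chain="A")
        # residue 2 has altLoc A (occ 0.4) and B (occ 0.6): B's coordinates win
        np.testing.assert_allclose(s.residues[1].ca, [13.503, 8.883, -3.263])

    def test_waters_hydrogens_and_ca_less_ligands_excluded(self, two_chain_pdb):
        s = read_structure(two_chain_pdb, chain="A")
        names = {r.residue_name for r in s.residues}
        assert "HOH" not in names and "CA" not in names
        assert "H" not in s.residues[2].atoms  # LYS hydrogen dropped
        assert any("dropped" in line for line in s.parse_report)

    def test_errors_name_file_and_chain(self, two_chain_pdb, tmp_path):
        with pytest.raises(ParseError, match="not found"):
            read_structure(tmp_path / "nope.pdb")
        with pytest.raises(ParseError, match="chain 'Z'"):
            read_structure(two_chain_pdb, chain="Z")

    def test_write_read_round_trip_preserves_ca_and_identity(self, tmp_path):
        template = make_template(25, "random-walk", seed=13)
        s = trace_to_structure(template)
        out = tmp_path / "rt.pdb"
        write_ensemble_pdb([s], path=out)
        trace = extract_ca_trace(read_structure(out))
        assert np.abs(trace.coords - template.coords).max() < 1e-3
        assert [l[0] for l in trace.labels] == [l[0] for l in template.labels]


class TestCaTrace:
    def test_order_and_labels_preserved(self, two_chain_pdb):
        s = read_structure(two_chain_pdb, chain="A")
        trace = extract_ca_trace(s)
        assert len(trace) == 3
        assert [l[0] for l in trace.labels] == ["LEU", "GLY", "LYS"]
        np.testing.assert_allclose(trace.coords[0], s.residues[0].ca)


class TestAlignmentFasta:
    def test_identical_rows_fully_aligned(self, tmp_path):
        p = tmp_path / "a.afasta"
        p.write_text(">x\nGASKL\n>y\nGASKL\n")
        msa = read_alignment_fasta(p)
        assert msa.ncore == 5

    def test_gap_column_maps_no_partner(self, tmp_path):
        p = tmp_path / "g.afasta"
        p.write_text(">x\nAG-SD\n>y\nAGKSD\n")
        msa = read_alignment_fasta(p)
        assert msa.index_matrix[0, 2] == -1
        assert msa.index_matrix[1, 2] == 2
        assert msa.ncore == 4

    def test_round_trip_is_identity(self, tmp_path, helix):
        ens = make_core_loop_ensemble(3, helix, np.ones(30, bool), 0.1, 0.1, seed=2)
        rng = np.random.default_rng(5)
        # random valid alignment: delete a few residues per row into gaps
        M = np.tile(np.arange(30), (3, 1))
        cols = np.ones((3, 30), dtype=int) * M
        for k in range(3):
            drop = rng.choice(30, size=4, replace=False)
            cols[k, drop] = -1
        # renumber each row's surviving indices to stay strictly increasing
        for k in range(3):
            kept = cols[k] >= 0
            cols[k, kept] = np.arange(kept.sum())
        trimmed = [
            type(t)(t.structure_id, t.coords[: (cols[k] >= 0).sum()],
                    t.labels[: (cols[k] >= 0).sum()])
            for k, t in enumerate(ens.traces)
        ]
        msa = MultipleAlignment(tuple(t.structure_id for t in trimmed), cols)
        p = tmp_path / "rt.afasta"
        write_alignment_fasta(msa, trimmed, p)
        msa2 = read_alignment_fasta(p, trimmed)
        assert msa2.structure_ids == msa.structure_ids
        assert np.array_equal(msa2.index_matrix, msa.index_matrix)

    def test_ragged_rows_rejected(self, tmp_path):
        p = tmp_path / "r.afasta"
        p.write_text(">x\nAG-SD\n>y\nAGKS\n")
        with pytest.raises(ParseError, match="length"):
            read_alignment_fasta(p)

    def test_mismatched_letters_name_row_and_column(self, tmp_path, helix):
        ens = make_core_loop_ensemble(2, helix, np.ones(30, bool), 0.1, 0.1, seed=2)
        p = tmp_path / "m.afasta"
        seq = ens.traces[0].sequence()
        bad = "W" + seq[1:]
        p.write_text(f">{ens.traces[0].structure_id}\n{seq}\n"
                     f">{ens.traces[1].structure_id}\n{bad}\n")
        with pytest.raises(ParseError, match="column 1"):
            read_alignment_fasta(p, ens.traces)


class TestWriteEnsemblePdb:
    def test_sieved_model_writes_only_retained_residues(self, tmp_path, core_loop_ensemble):
        from structsieve.sieving import sieve_to_threshold

        ens = core_loop_ensemble(seed=21)
        model = sieve_to_threshold(ens.true_alignment, ens.traces, 0.6)
        structures = [trace_to_structure(t) for t in ens.traces]
        out = tmp_path / "sieved.pdb"
        write_ensemble_pdb(structures, model=model, path=out)
        text = out.read_text()
        assert text.count("MODEL") >= len(ens.traces)
        blocks = text.split("MODEL")[1:]
        for block in blocks:
            n_ca = block.count(" CA ")
            assert n_ca == model.ncore
        assert "SIEVE THRESHOLD" in text

    def test_rewritten_ensemble_reproduces_recorded_rmsd(self, tmp_path, core_loop_ensemble):
        ens = core_loop_ensemble(seed=22)
        msa = ens.true_alignment
        sup = superpose_ensemble(ens.traces, msa)
        structures = [trace_to_structure(t) for t in ens.traces]
        out = tmp_path / "sup.pdb"
        write_ensemble_pdb(structures, sup, path=out)
        # re-read each MODEL block and re-superpose
        import gemmi

        st = gemmi.read_structure(str(out))
        traces2 = []
        for m, sid in zip(st, sup.structure_ids):
            ch = m[0]
            coords = np.array(
                [[a.pos.x, a.pos.y, a.pos.z] for r in ch for a in r if a.name == "CA"]
            )
            labels = [("ALA", i + 1, "") for i in range(len(coords))]
            from structsieve.structure_io import CaTrace

            traces2.append(CaTrace(sid, coords, labels))
        sup2 = superpose_ensemble(traces2, msa)
        assert sup2.pooled_rmsd == pytest.approx(sup.pooled_rmsd, abs=1e-3)


class TestMixedModel:
    def _leu_gly_lys(self, two_chain_pdb):
        return read_structure(two_chain_pdb, chain="A")

    def test_all_true_mask_is_identity(self, two_chain_pdb):
        s = self._leu_gly_lys(two_chain_pdb)
        out = make_mixed_model(s, [True] * 3)
        assert [r.residue_name for r in out.residues] == ["LEU", "GLY", "LYS"]
        assert [set(r.atoms) for r in out.residues] == [set(r.atoms) for r in s.residues]

    def test_all_false_trims_to_alanine_but_keeps_glycine(self, two_chain_pdb):
        s = self._leu_gly_lys(two_chain_pdb)
        out = make_mixed_model(s, [False] * 3)
        assert [r.residue_name for r in out.residues] == ["ALA", "GLY", "ALA"]
        assert set(out.residues[0].atoms) == {"N", "CA", "C", "O", "CB"}
        assert set(out.residues[1].atoms) == set(s.residues[1].atoms)
        assert set(out.residues[2].atoms) == {"N", "CA", "C", "O", "CB"}

    def test_mixed_mask_changes_only_unconserved(self, two_chain_pdb):
        s = self._leu_gly_lys(two_chain_pdb)
        out = make_mixed_model(s, [True, True, False])
        for a, b in zip(s.residues[:2], out.residues[:2]):
            assert a.residue_name == b.residue_name and set(a.atoms) == set(b.atoms)
        assert out.residues[2].residue_name == "ALA"
        # kept atoms never move, none added
        for ra, rb in zip(s.residues, out.residues):
            assert set(rb.atoms) <= set(ra.atoms)
            for name, xyz in rb.atoms.items():
                np.testing.assert_array_equal(xyz, ra.atoms[name])

    def test_mask_length_mismatch(self, two_chain_pdb):
        with pytest.raises(ParseError, match="mask length"):
            make_mixed_model(self._leu_gly_lys(two_chain_pdb), [True])
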