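"""Multiple structural alignment of Cα traces.

The engine is a progressive aligner in the classic mould: all-against-all
pairwise structural alignments score a UPGMA guide tree, and groups are merged
along the tree, each group represented by the consensus coordinates of its
fully aligned columns.  The pairwise stage is an iterative
superpose-score-realign loop: a gapless window scan seeds a rigid fit, a
distance-derived similarity matrix S(i,j) = 1 / (1 + (d_ij/d0)^2) is aligned
by global affine-gap dynamic programming, accepted pairs (d_ij <= 8 Å) are
refit, and the loop repeats until the pair set stabilises.

Alignments produced elsewhere (e.g. by a dedicated MSA program) can be
imported verbatim through :func:`import_alignment` and sieved exactly as
engine-produced ones.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from numba import njit

from .superposition import RigidTransform, kabsch, superpose_ensemble

__all__ = [
    "AlignmentError",
    "MultipleAlignment",
    "PairwiseAlignment",
    "GuideTree",
    "pairwise_structural_alignment",
    "build_guide_tree",
    "progressive_msa",
    "import_alignment",
]

GAP = -1
PAIR_DISTANCE_CUTOFF = 8.0  # Å; DP path cells farther than this are rejected
SEED_WINDOW = 15  # residues in the gapless seed scan
MIN_TRACE_LEN = 8


class AlignmentError(ValueError):
    """Raised for invalid alignments or failed alignment stages."""


@dataclass(frozen=True)
class MultipleAlignment:
    """K x L alignment of residue indices; -1 marks a gap.

    Row k column c holds the 0-based residue index of structure
    ``structure_ids[k]`` placed in that column, or -1.  Per row the non-gap
    indices are strictly increasing (linear, order-preserving alignment) and
    no residue appears twice.
    """

    structure_ids: tuple
    index_matrix: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        ids = tuple(self.structure_ids)
        M = np.asarray(self.index_matrix, dtype=int)
        if M.ndim != 2 or M.shape[0] != len(ids):
            raise AlignmentError("index matrix must be K x L with one row per id")
        if len(set(ids)) != len(ids):
            raise AlignmentError("duplicate structure ids")
        for k, row in enumerate(M):
            idx = row[row != GAP]
            if np.any(idx < 0):
                raise AlignmentError(f"row {ids[k]!r} has negative residue indices")
            if np.any(np.diff(idx) <= 0):
                raise AlignmentError(
                    f"row {ids[k]!r} residue indices are not strictly increasing"
                )
        M.setflags(write=False)
        object.__setattr__(self, "structure_ids", ids)
        object.__setattr__(self, "index_matrix", M)

    @property
    def n_structures(self) -> int:
        return len(self.structure_ids)

    @property
    def n_columns(self) -> int:
        return self.index_matrix.shape[1]

    def fully_aligned_columns(self) -> np.ndarray:
        """Indices of columns with no gap in any row (the correspondences)."""
        return np.flatnonzero((self.index_matrix != GAP).all(axis=0))

    @property
    def ncore(self) -> int:
        return int(len(self.fully_aligned_columns()))

    def restrict(self, columns) -> "MultipleAlignment":
        """Alignment restricted to the given columns (original order kept)."""
        cols = np.asarray(sorted(set(int(c) for c in columns)), dtype=int)
        if len(cols) and (cols[0] < 0 or cols[-1] >= self.n_columns):
            raise AlignmentError("column index out of range")
        return MultipleAlignment(self.structure_ids, self.index_matrix[:, cols])

    def subset_structures(self, ids: Sequence[str]) -> "MultipleAlignment":
        """Row subset in the given order; columns are kept (indices stable)."""
        try:
            rows = [self.structure_ids.index(i) for i in ids]
        except ValueError as e:
            raise AlignmentError(f"unknown structure id in subset: {e}") from None
        return MultipleAlignment(tuple(ids), self.index_matrix[rows])

    def residue_indices(self, structure_id: str, columns=None) -> np.ndarray:
        k = self.structure_ids.index(structure_id)
        row = self.index_matrix[k] if columns is None else self.index_matrix[k, list(columns)]
        return row[row != GAP]


@dataclass(frozen=True)
class PairwiseAlignment:
    """Residue-index correspondences between two traces, with fit quality."""

    pairs: tuple
    rmsd: float
    score: float
    transform: RigidTransform | None = None

    def __post_init__(self) -> None:
        pairs = tuple((int(i), int(j)) for i, j in self.pairs)
        if pairs:
            ii, jj = zip(*pairs)
            if np.any(np.diff(ii) <= 0) or np.any(np.diff(jj) <= 0):
                raise AlignmentError("pair lists must be strictly increasing")
        object.__setattr__(self, "pairs", pairs)


@njit(cache=False)
def _gotoh(S, gap_open, gap_extend):  # pragma: no cover - exercised via wrapper
    """Global affine-gap DP maximising sum of similarities minus gap costs.

    A gap of length L costs gap_open + (L - 1) * gap_extend.  Returns the
    optimal score and the matched-cell path as parallel index arrays.
    """
    n, m = S.shape
    NEG = -1e30
    M = np.full((n + 1, m + 1), NEG)
    Ix = np.full((n + 1, m + 1), NEG)  # gap in second sequence (vertical)
    Iy = np.full((n + 1, m + 1), NEG)  # gap in first sequence (horizontal)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        Ix[i, 0] = -gap_open - (i - 1) * gap_extend
    for j in range(1, m + 1):
        Iy[0, j] = -gap_open - (j - 1) * gap_extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            best = M[i - 1, j - 1]
            if Ix[i - 1, j - 1] > best:
                best = Ix[i - 1, j - 1]
            if Iy[i - 1, j - 1] > best:
                best = Iy[i - 1, j - 1]
            M[i, j] = best + S[i - 1, j - 1]
            a = M[i - 1, j] - gap_open
            b = Ix[i - 1, j] - gap_extend
            Ix[i, j] = a if a >= b else b
            a = M[i, j - 1] - gap_open
            b = Iy[i, j - 1] - gap_extend
            Iy[i, j] = a if a >= b else b

    # traceback, preferring match > vertical > horizontal on ties
    i, j = n, m
    if M[i, j] >= Ix[i, j] and M[i, j] >= Iy[i, j]:
        state = 0
        score = M[i, j]
    elif Ix[i, j] >= Iy[i, j]:
        state = 1
        score = Ix[i, j]
    else:
        state = 2
        score = Iy[i, j]
    pi = np.empty(min(n, m), dtype=np.int64)
    pj = np.empty(min(n, m), dtype=np.int64)
    npairs = 0
    while i > 0 or j > 0:
        if state == 0:
            pi[npairs] = i - 1
            pj[npairs] = j - 1
            npairs += 1
            if i == 1 and j == 1:
                break
            if M[i - 1, j - 1] >= Ix[i - 1, j - 1] and M[i - 1, j - 1] >= Iy[i - 1, j - 1]:
                state = 0
            elif Ix[i - 1, j - 1] >= Iy[i - 1, j - 1]:
                state = 1
            else:
                state = 2
            i -= 1
            j -= 1
        elif state == 1:
            if M[i - 1, j] - gap_open >= Ix[i - 1, j] - gap_extend:
                state = 0
            i -= 1
            if i == 0 and j > 0:
                state = 2
        else:
            if M[i, j - 1] - gap_open >= Iy[i, j - 1] - gap_extend:
                state = 0
            j -= 1
            if j == 0 and i > 0:
                state = 1
    return score, pi[:npairs][::-1].copy(), pj[:npairs][::-1].copy()


def _batched_window_rmsd(P: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """RMSD of each (w, 3) window pair in stacked (B, w, 3) arrays."""
    P0 = P - P.mean(axis=1, keepdims=True)
    Q0 = Q - Q.mean(axis=1, keepdims=True)
    H = np.einsum("bwi,bwj->bij", Q0, P0)
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(np.einsum("bij,bjk->bik", Vt.transpose(0, 2, 1), U.transpose(0, 2, 1))))
    S = S.copy()
    S[:, -1] *= d
    w = P.shape[1]
    e = (
        np.einsum("bwi,bwi->b", P0, P0)
        + np.einsum("bwi,bwi->b", Q0, Q0)
        - 2.0 * S.sum(axis=1)
    )
    return np.sqrt(np.maximum(e, 0.0) / w)


def _seed_candidates(A: np.ndarray, B: np.ndarray, top_n: int = 5) -> list:
    """Best gapless diagonal windows under rigid superposition.

    Scans every diagonal offset; within each overlap, 15-residue windows
    (strided, with the final position always included) are superposed by
    batched SVD.  Offsets are ranked by how much of the full overlap falls
    within the pair-acceptance cutoff under the best window's transform
    (ties by window RMSD), which disambiguates internally periodic folds
    such as helices, where shifted windows superpose equally well.  The best
    window of each of the `top_n` best offsets is returned — iterating from
    several seed registers lets the refinement escape self-similar decoys.
    """
    nA, nB = len(A), len(B)
    cands = []
    for o in range(-(nB - MIN_TRACE_LEN), nA - MIN_TRACE_LEN + 1):
        lo = max(0, o)
        hi = min(nA, nB + o)
        L = hi - lo
        if L < MIN_TRACE_LEN:
            continue
        w = min(SEED_WINDOW, L)
        starts = list(range(0, L - w + 1, 3))
        if starts[-1] != L - w:
            starts.append(L - w)
        P = np.stack([A[lo + s : lo + s + w] for s in starts])
        Q = np.stack([B[lo + s - o : lo + s - o + w] for s in starts])
        r = _batched_window_rmsd(P, Q)
        k = int(np.argmin(r))
        i0 = lo + starts[k]
        T, _ = kabsch(A[i0 : i0 + w], B[i0 - o : i0 - o + w])
        d = np.linalg.norm(A[lo:hi] - T.apply(B[lo - o : hi - o]), axis=1)
        key = (-int((d <= PAIR_DISTANCE_CUTOFF).sum()), float(r[k]))
        cands.append((key, (i0, i0 - o, w)))
    if not cands:
        raise AlignmentError("no seed window with at least 8 residue pairs")
    cands.sort(key=lambda c: c[0])
    return [
        [(i0 + t, j0 + t) for t in range(w)] for _, (i0, j0, w) in cands[:top_n]
    ]


def pairwise_structural_alignment(
    A,
    B,
    d0: float = 3.0,
    gap_open: float = 4.0,
    gap_extend: float = 0.5,
    max_iter: int = 30,
) -> PairwiseAlignment:
    """Iterative superpose/score/realign alignment of two Cα traces.

    Parameters follow conventional Cα-aligner choices: d0 = 3.0 Å softens the
    similarity kernel around typical backbone deviations, and the affine gap
    costs (4.0 open, 0.5 extend) are on the scale of one to a few similarity
    units.  The superpose/DP loop is run from each of the top few seed
    registers; within a run, iteration stops when the accepted pair set
    repeats or after `max_iter` rounds.  The highest-scoring iterate over all
    runs is returned.
    """
    CA = np.asarray(A.coords, dtype=float)
    CB = np.asarray(B.coords, dtype=float)
    if len(CA) < MIN_TRACE_LEN or len(CB) < MIN_TRACE_LEN:
        raise AlignmentError(
            f"traces must have at least {MIN_TRACE_LEN} residues "
            f"(got {len(CA)} and {len(CB)})"
        )
    best = None
    for pairs in _seed_candidates(CA, CB):
        seen = set()
        for _ in range(max_iter):
            key = tuple(pairs)
            if key in seen:
                break
            seen.add(key)
            ii = np.fromiter((p[0] for p in pairs), int)
            jj = np.fromiter((p[1] for p in pairs), int)
            T, _ = kabsch(CA[ii], CB[jj])
            Bt = T.apply(CB)
            D = np.sqrt(
                np.maximum(
                    np.sum((CA[:, None, :] - Bt[None, :, :]) ** 2, axis=2), 0.0
                )
            )
            S = 1.0 / (1.0 + (D / d0) ** 2)
            score, pi, pj = _gotoh(S, gap_open, gap_extend)
            keep = D[pi, pj] <= PAIR_DISTANCE_CUTOFF
            new_pairs = list(zip(pi[keep].tolist(), pj[keep].tolist()))
            if len(new_pairs) >= 3 and (best is None or score > best[0]):
                best = (float(score), tuple(new_pairs))
            if len(new_pairs) < 3:
                break
            pairs = new_pairs
    if best is None:
        raise AlignmentError("alignment failed: fewer than 3 close residue pairs")
    score, bpairs = best
    ii = np.fromiter((p[0] for p in bpairs), int)
    jj = np.fromiter((p[1] for p in bpairs), int)
    T, rmsd = kabsch(CA[ii], CB[jj])
    return PairwiseAlignment(pairs=bpairs, rmsd=rmsd, score=score, transform=T)


@dataclass(frozen=True)
class GuideTree:
    """Rooted binary merge order: each entry joins two disjoint id groups."""

    merges: tuple  # of (tuple_of_ids, tuple_of_ids)

    @property
    def root(self) -> tuple:
        left, right = self.merges[-1]
        return tuple(left) + tuple(right)


def build_guide_tree(pairwise_scores: np.ndarray, ids: Sequence[str]) -> GuideTree:
    """UPGMA merge order on distance = 1 - normalized pairwise score.

    Scores are normalised by the largest off-diagonal entry and clipped to
    [0, 1].  Ties are broken by the lexicographically smallest pair of
    cluster representatives (each cluster represented by its smallest id),
    so the tree is deterministic.
    """
    S = np.asarray(pairwise_scores, dtype=float)
    ids = list(ids)
    K = len(ids)
    if S.shape != (K, K):
        raise AlignmentError("score matrix shape does not match ids")
    if K < 2:
        raise AlignmentError("need at least 2 structures")
    if not np.all(np.isfinite(S)):
        raise AlignmentError("scores must be finite")
    if not np.allclose(S, S.T, atol=1e-8):
        raise AlignmentError("score matrix must be symmetric")
    off = S[~np.eye(K, dtype=bool)]
    smax = float(off.max()) if off.size and off.max() > 0 else 1.0
    D = 1.0 - np.clip(S / smax, 0.0, 1.0)

    dist = {
        frozenset((a, b)): D[ids.index(a), ids.index(b)]
        for a, b in itertools.combinations(ids, 2)
    }
    merges = []
    active = [(i,) for i in ids]
    while len(active) > 1:
        best = None
        for ca, cb in itertools.combinations(active, 2):
            d = _cluster_dist(dist, ca, cb)
            key = (d, min(min(ca), min(cb)), max(min(ca), min(cb)))
            if best is None or key < best[0]:
                best = (key, ca, cb)
        _, ca, cb = best
        if min(cb) < min(ca):
            ca, cb = cb, ca
        merged = tuple(ca) + tuple(cb)
        merges.append((tuple(ca), tuple(cb)))
        active = [c for c in active if c not in (ca, cb)] + [merged]
    return GuideTree(merges=tuple(merges))


def _cluster_dist(dist, ca, cb) -> float:
    """Average-linkage distance between two clusters of leaf ids."""
    tot = 0.0
    for a in ca:
        for b in cb:
            tot += dist[frozenset((a, b))]
    return tot / (len(ca) * len(cb))


@dataclass
class _Group:
    """Progressive-alignment working state for a merged set of traces."""

    ids: tuple
    matrix: np.ndarray  # (k, L) residue indices / -1
    rep_coords: np.ndarray  # (n_core, 3) consensus coordinates
    rep_cols: np.ndarray  # alignment columns the representative rows map to


def _group_from_trace(trace) -> _Group:
    n = len(trace.coords)
    return _Group(
        ids=(trace.structure_id,),
        matrix=np.arange(n, dtype=int)[None, :],
        rep_coords=np.asarray(trace.coords, dtype=float),
        rep_cols=np.arange(n, dtype=int),
    )


def _refresh_representative(group: _Group, trace_map) -> None:
    """Recompute consensus coordinates over the group's fully aligned columns."""
    msa = MultipleAlignment(group.ids, group.matrix)
    cols = msa.fully_aligned_columns()
    if len(group.ids) == 1:
        group.rep_cols = cols
        tr = trace_map[group.ids[0]]
        group.rep_coords = tr.coords[msa.index_matrix[0, cols]]
        return
    if len(cols) < 3:
        raise AlignmentError(
            "merged group has fewer than 3 fully aligned columns; "
            "structures may be too divergent to align progressively"
        )
    sup = superpose_ensemble([trace_map[i] for i in group.ids], msa, cols)
    group.rep_cols = cols
    group.rep_coords = sup.consensus


class _RepTrace:
    """Minimal CaTrace-like view over a group's consensus coordinates."""

    def __init__(self, group: _Group):
        self.structure_id = "+".join(group.ids)
        self.coords = group.rep_coords


def _merge_groups(g1: _Group, g2: _Group, matches) -> _Group:
    """Merge two profile matrices given a monotone column matching.

    Unmatched columns between consecutive matches are emitted first from g1,
    then from g2 (deterministic).
    """
    K1, L1 = g1.matrix.shape
    K2, L2 = g2.matrix.shape
    cols = []
    ia = ib = 0
    for ca, cb in matches:
        while ia < ca:
            cols.append((ia, None))
            ia += 1
        while ib < cb:
            cols.append((None, ib))
            ib += 1
        cols.append((ca, cb))
        ia, ib = ca + 1, cb + 1
    while ia < L1:
        cols.append((ia, None))
        ia += 1
    while ib < L2:
        cols.append((None, ib))
        ib += 1
    M = np.full((K1 + K2, len(cols)), GAP, dtype=int)
    for c, (a, b) in enumerate(cols):
        if a is not None:
            M[:K1, c] = g1.matrix[:, a]
        if b is not None:
            M[K1:, c] = g2.matrix[:, b]
    return _Group(
        ids=g1.ids + g2.ids,
        matrix=M,
        rep_coords=np.empty((0, 3)),
        rep_cols=np.empty(0, dtype=int),
    )


def progressive_msa(traces: Sequence, **pairwise_kwargs) -> MultipleAlignment:
    """Progressive multiple structural alignment of K >= 2 Cα traces.

    All-against-all pairwise alignments supply guide-tree scores (normalised
    by the shorter trace length); groups are merged along the UPGMA tree with
    each group represented by the consensus coordinates of its fully aligned
    columns.  Row order of the result follows the input trace order.
    """
    traces = list(traces)
    K = len(traces)
    if K < 2:
        raise AlignmentError("need at least 2 traces")
    ids = [t.structure_id for t in traces]
    if len(set(ids)) != K:
        raise AlignmentError("structure ids must be unique")
    trace_map = {t.structure_id: t for t in traces}

    S = np.zeros((K, K))
    for a, b in itertools.combinations(range(K), 2):
        pw = pairwise_structural_alignment(traces[a], traces[b], **pairwise_kwargs)
        norm = min(len(traces[a].coords), len(traces[b].coords))
        S[a, b] = S[b, a] = max(0.0, pw.score) / norm
    tree = build_guide_tree(S, ids)

    groups = {(i,): _group_from_trace(trace_map[i]) for i in ids}
    for left, right in tree.merges:
        g1 = groups.pop(tuple(left))
        g2 = groups.pop(tuple(right))
        pw = pairwise_structural_alignment(
            _RepTrace(g1), _RepTrace(g2), **pairwise_kwargs
        )
        matches = [
            (int(g1.rep_cols[a]), int(g2.rep_cols[b])) for a, b in pw.pairs
        ]
        merged = _merge_groups(g1, g2, matches)
        _refresh_representative(merged, trace_map)
        groups[merged.ids] = merged

    (final,) = groups.values()
    msa = MultipleAlignment(final.ids, final.matrix)
    return msa.subset_structures(tuple(ids))


def import_alignment(msa_path, traces) -> MultipleAlignment:
    """Load an externally produced aligned-FASTA file verbatim.

    The row sequences must match the traces residue-for-residue; no
    realignment is performed, so numbers computed downstream reproduce the
    external aligner's correspondences exactly.
    """
    from .structure_io import read_alignment_fasta

    return read_alignment_fasta(msa_path, traces)
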