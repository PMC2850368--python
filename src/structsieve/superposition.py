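"""Rigid-body superposition of Cα coordinate sets.

Pairwise least-squares superposition (Kabsch, via SVD with a proper-rotation
sign correction) and an alternating consensus superposition for ensembles of
two or more structures over a shared set of aligned columns.

All RMSD definitions used elsewhere in the package are defined here.  For an
ensemble, RMSD is the root-mean-square deviation of every transformed Cα from
the per-column consensus (mean) position.  With uniform weights this pooled
quantity decomposes exactly both ways::

    pooled_rmsd**2 == mean_k per_structure_rmsd[k]**2
                   == mean_c per_column_dev[c]**2

so per-structure and per-correspondence misfit statistics are mutually
consistent with the headline number.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "RigidTransform",
    "EnsembleSuperposition",
    "SuperpositionError",
    "kabsch",
    "superpose_ensemble",
    "column_deviation",
]


class SuperpositionError(ValueError):
    """Raised for degenerate or inconsistent superposition inputs."""


@dataclass(frozen=True)
class RigidTransform:
    """A proper rigid motion ``x -> rotation @ x + translation`` (Å)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        if R.shape != (3, 3) or t.shape != (3,):
            raise SuperpositionError("rotation must be 3x3 and translation 3-vector")
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-9):
            raise SuperpositionError("rotation is not orthonormal")
        if np.linalg.det(R) < 0:
            raise SuperpositionError("rotation is a reflection (det < 0)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, coords: np.ndarray) -> np.ndarray:
        """Transform an (n, 3) coordinate array."""
        X = np.asarray(coords, dtype=float)
        return X @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the transform equivalent to applying `other` then `self`."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -(self.rotation.T @ self.translation))


@dataclass(frozen=True)
class EnsembleSuperposition:
    """Result of superposing K structures over a common column set.

    ``transforms[k]`` maps structure k's input coordinates onto the consensus
    frame; ``consensus`` holds the per-column mean of the transformed
    coordinates, centred at the origin.  ``columns`` are the alignment column
    indices the fit used, in increasing order.
    """

    structure_ids: tuple
    transforms: tuple
    columns: tuple
    consensus: np.ndarray
    pooled_rmsd: float
    per_structure_rmsd: Mapping[str, float]
    per_column_dev: Mapping[int, float]
    n_iterations: int = 0
    transformed: np.ndarray = field(repr=False, default=None)

    @property
    def ncore(self) -> int:
        return len(self.columns)

    def transform_for(self, structure_id: str) -> RigidTransform:
        try:
            return self.transforms[self.structure_ids.index(structure_id)]
        except ValueError:
            raise SuperpositionError(f"no transform for structure {structure_id!r}")


def kabsch(P, Q, weights=None) -> tuple[RigidTransform, float]:
    """Optimal rigid superposition of Q onto P.

    Returns the proper rotation + translation minimising the (weighted) RMSD
    of the transformed Q coordinates from P, together with that RMSD in Å.
    Reflections are excluded by the usual sign correction on the smallest
    singular vector.

    Parameters
    ----------
    P, Q : (n, 3) arrays, n >= 3
    weights : optional (n,) non-negative array; uniform when omitted.
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.ndim != 2 or P.shape[1] != 3 or Q.shape != P.shape:
        raise SuperpositionError(
            f"expected matching (n, 3) arrays, got {P.shape} and {Q.shape}"
        )
    n = P.shape[0]
    if n < 3:
        raise SuperpositionError(f"need at least 3 points, got {n}")
    if weights is None:
        w = np.full(n, 1.0 / n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n,):
            raise SuperpositionError("weights must have one entry per point")
        if np.any(w < 0) or w.sum() <= 0:
            raise SuperpositionError("weights must be non-negative with positive sum")
        w = w / w.sum()

    cp = w @ P
    cq = w @ Q
    P0 = P - cp
    Q0 = Q - cq
    H = (w[:, None] * Q0).T @ P0
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cp - R @ cq
    diff = Q0 @ R.T - P0
    msd = float(np.sum(w * np.einsum("ij,ij->i", diff, diff)))
    return RigidTransform(R, t), float(np.sqrt(max(msd, 0.0)))


def _column_coords(traces, msa, columns) -> np.ndarray:
    """Stack (K, n_cols, 3) Cα coordinates for the given alignment columns."""
    K = len(traces)
    cols = np.asarray(columns, dtype=int)
    X = np.empty((K, len(cols), 3), dtype=float)
    for k, trace in enumerate(traces):
        idx = msa.index_matrix[k, cols]
        if np.any(idx < 0):
            bad = int(cols[np.argmax(idx < 0)])
            raise SuperpositionError(
                f"structure {trace.structure_id!r} has a gap in requested column {bad}"
            )
        X[k] = trace.coords[idx]
    return X


def superpose_ensemble(
    traces: Sequence,
    msa,
    columns: Iterable[int] | None = None,
    *,
    tol: float = 1e-6,
    max_iter: int = 100,
    init_consensus: np.ndarray | None = None,
) -> EnsembleSuperposition:
    """Consensus superposition of K >= 2 Cα traces over aligned columns.

    Alternates (a) superposing every structure onto the current consensus and
    (b) recomputing the consensus as the per-column mean of the transformed
    coordinates, until the pooled RMSD changes by less than `tol` Å or
    `max_iter` rounds.  Both half-steps are least-squares improvements, so the
    pooled RMSD is non-increasing over rounds.  The consensus is initialised
    from the first structure unless `init_consensus` is given (used by the
    sieve to warm-start after a column removal, which keeps the removal trace
    monotone).  The result is translated so the consensus centroid sits at
    the origin.
    """
    traces = list(traces)
    K = len(traces)
    if K < 2:
        raise SuperpositionError("need at least 2 structures")
    order = {sid: i for i, sid in enumerate(msa.structure_ids)}
    if set(order) != {t.structure_id for t in traces}:
        raise SuperpositionError("traces do not match the alignment's structures")
    traces.sort(key=lambda t: order[t.structure_id])

    if columns is None:
        cols = msa.fully_aligned_columns()
    else:
        cols = np.asarray(sorted(set(int(c) for c in columns)), dtype=int)
    if len(cols) < 3:
        raise SuperpositionError(
            f"need at least 3 usable columns, got {len(cols)}"
        )
    X = _column_coords(traces, msa, cols)
    n = len(cols)

    consensus = np.array(X[0] if init_consensus is None else init_consensus, dtype=float)
    if consensus.shape != (n, 3):
        raise SuperpositionError("init_consensus shape mismatch")

    transforms = [RigidTransform.identity()] * K
    Y = np.empty_like(X)
    pooled_prev = np.inf
    pooled = np.inf
    it = 0
    for it in range(1, max_iter + 1):
        for k in range(K):
            T, _ = kabsch(consensus, X[k])
            transforms[k] = T
            Y[k] = T.apply(X[k])
        consensus = Y.mean(axis=0)
        dev = Y - consensus[None, :, :]
        pooled = float(np.sqrt(np.mean(np.sum(dev * dev, axis=2))))
        if pooled_prev - pooled < tol:
            break
        pooled_prev = pooled

    # centre the consensus frame at the consensus centroid
    centroid = consensus.mean(axis=0)
    consensus = consensus - centroid
    Y = Y - centroid
    transforms = [
        RigidTransform(T.rotation, T.translation - centroid) for T in transforms
    ]

    dev = Y - consensus[None, :, :]
    sq = np.sum(dev * dev, axis=2)  # (K, n)
    per_structure = {
        traces[k].structure_id: float(np.sqrt(sq[k].mean())) for k in range(K)
    }
    per_column = {int(cols[c]): float(np.sqrt(sq[:, c].mean())) for c in range(n)}
    pooled = float(np.sqrt(sq.mean()))

    return EnsembleSuperposition(
        structure_ids=tuple(t.structure_id for t in traces),
        transforms=tuple(transforms),
        columns=tuple(int(c) for c in cols),
        consensus=consensus,
        pooled_rmsd=pooled,
        per_structure_rmsd=per_structure,
        per_column_dev=per_column,
        n_iterations=it,
        transformed=Y,
    )


def column_deviation(sup: EnsembleSuperposition, column: int) -> float:
    """RMS distance (over structures) from the column consensus point.

    This is the per-correspondence misfit score the sieve ranks columns by.
    """
    try:
        return sup.per_column_dev[int(column)]
    except KeyError:
        raise SuperpositionError(
            f"column {column} is not part of this superposition"
        ) from None
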