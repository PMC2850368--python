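"""Iterative structural sieving of a multiple alignment.

Starting from the fully aligned columns of a multiple structural alignment,
the sieve repeatedly re-superposes the ensemble and removes the
worst-fitting correspondence (the column with the largest consensus
deviation, ties to the lower column index) until the pooled RMSD drops to the
requested threshold.  Removing the worst column and refitting can never
increase the pooled RMSD, so the removal trace is monotone.

Optionally, when column removal alone cannot reach the threshold before the
correspondence count hits its floor, the worst-fitting structure (largest
per-structure RMSD) is eliminated, the column set is restored to everything
fully aligned in the reduced ensemble, and column sieving restarts.

Sweeping thresholds produces the model family behind Lesk-Hubbard curves;
sweeping ensemble cardinality produces reduced-ensemble models for
search-model preparation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .msa_engine import MultipleAlignment
from .superposition import EnsembleSuperposition, superpose_ensemble

__all__ = [
    "SieveError",
    "SieveConfig",
    "RemovalStep",
    "SievedModel",
    "sieve_to_threshold",
    "sieve_sweep",
    "sieve_cardinality_sweep",
    "default_threshold_grid",
    "write_removal_trace_tsv",
]


class SieveError(ValueError):
    """Raised for invalid sieve parameters or unusable inputs."""


@dataclass(frozen=True)
class SieveConfig:
    """Sieve knobs.

    min_ncore      floor on retained correspondences (>= 3, the minimum for a
                   defined rigid superposition).
    drop_structures when True, eliminate the worst-fitting structure once
                   column sieving stalls at the floor.
    min_structures floor on ensemble cardinality (>= 2).
    batch          columns removed per re-superposition round.
    """

    min_ncore: int = 3
    drop_structures: bool = False
    min_structures: int = 2
    batch: int = 1

    def __post_init__(self) -> None:
        if self.min_ncore < 3:
            raise SieveError("min_ncore must be at least 3")
        if self.min_structures < 2:
            raise SieveError("min_structures must be at least 2")
        if self.batch < 1:
            raise SieveError("batch must be at least 1")


@dataclass(frozen=True)
class RemovalStep:
    """One sieve removal: a column index or a structure id, with the pooled
    RMSD measured after the removal and re-superposition."""

    step: int
    kind: str  # "column" | "structure"
    identity: object
    rmsd_after: float


@dataclass(frozen=True)
class SievedModel:
    """A sieved superposition: retained columns/structures at one threshold."""

    threshold: float
    retained_columns: tuple
    retained_structures: tuple
    superposition: EnsembleSuperposition
    alignment: MultipleAlignment  # restricted to retained rows and columns
    ncore_unsieved: int
    removal_trace: tuple
    floor_reached: bool = False

    @property
    def ncore(self) -> int:
        return len(self.retained_columns)

    @property
    def ncore_ratio(self) -> float:
        return self.ncore / self.ncore_unsieved

    @property
    def rmsd(self) -> float:
        return self.superposition.pooled_rmsd


def _trace_subset(traces, ids):
    tmap = {t.structure_id: t for t in traces}
    missing = [i for i in ids if i not in tmap]
    if missing:
        raise SieveError(f"no trace provided for structure(s): {missing}")
    return [tmap[i] for i in ids]


def sieve_to_threshold(
    msa: MultipleAlignment,
    traces: Sequence,
    threshold: float,
    cfg: SieveConfig | None = None,
) -> SievedModel:
    """Greedily sieve correspondences until pooled RMSD <= threshold.

    Each round re-superposes the ensemble over the retained columns
    (warm-started from the previous consensus so every recorded step is a
    least-squares improvement), then removes the `cfg.batch` columns with the
    largest consensus deviation.  Stops at the threshold, or flags
    `floor_reached` when min_ncore (and, without structure dropping,
    min_structures) prevents further removal.
    """
    cfg = cfg or SieveConfig()
    if threshold <= 0:
        raise SieveError(f"threshold must be positive, got {threshold}")
    struct_ids = list(msa.structure_ids)
    sub_msa = msa
    cols = [int(c) for c in msa.fully_aligned_columns()]
    if len(cols) < cfg.min_ncore:
        raise SieveError(
            f"only {len(cols)} fully aligned columns; need at least {cfg.min_ncore}"
        )
    ncore_unsieved = len(cols)

    trace = []
    step = 0
    floor = False
    sup = superpose_ensemble(_trace_subset(traces, struct_ids), sub_msa, cols)
    while sup.pooled_rmsd > threshold:
        removable = len(cols) - cfg.min_ncore
        if removable > 0:
            nrem = min(cfg.batch, removable)
            ranked = sorted(cols, key=lambda c: (-sup.per_column_dev[c], c))
            removed = ranked[:nrem]
            removed_set = set(removed)
            keep_pos = [i for i, c in enumerate(cols) if c not in removed_set]
            warm = sup.consensus[keep_pos]
            cols = [cols[i] for i in keep_pos]
            sup = superpose_ensemble(
                _trace_subset(traces, struct_ids), sub_msa, cols, init_consensus=warm
            )
            for c in sorted(removed):
                step += 1
                trace.append(RemovalStep(step, "column", c, sup.pooled_rmsd))
        elif cfg.drop_structures and len(struct_ids) > cfg.min_structures:
            worst = max(struct_ids, key=lambda s: sup.per_structure_rmsd[s])
            struct_ids.remove(worst)
            sub_msa = msa.subset_structures(struct_ids)
            cols = [int(c) for c in sub_msa.fully_aligned_columns()]
            if len(cols) < cfg.min_ncore:
                floor = True
                step += 1
                trace.append(RemovalStep(step, "structure", worst, math.nan))
                break
            sup = superpose_ensemble(_trace_subset(traces, struct_ids), sub_msa, cols)
            step += 1
            trace.append(RemovalStep(step, "structure", worst, sup.pooled_rmsd))
        else:
            floor = True
            break

    restricted = msa.subset_structures(struct_ids).restrict(cols)
    return SievedModel(
        threshold=float(threshold),
        retained_columns=tuple(sorted(cols)),
        retained_structures=tuple(struct_ids),
        superposition=sup,
        alignment=restricted,
        ncore_unsieved=ncore_unsieved,
        removal_trace=tuple(trace),
        floor_reached=floor,
    )


def default_threshold_grid(msa, traces, start: float = 0.2, step: float = 0.1):
    """The default sweep grid: `start` up to the unsieved RMSD, rounded up.

    Mirrors the conventional 0.2-2.7 Å / 0.1 Å grid for ensembles whose
    unsieved superposition sits near 2.7 Å, and generalises to any input.
    """
    sup = superpose_ensemble(traces, msa)
    top = max(start, math.ceil(sup.pooled_rmsd * 10.0) / 10.0)
    n = int(round((top - start) / step)) + 1
    return [round(start + i * step, 10) for i in range(n)]


def sieve_sweep(
    msa: MultipleAlignment,
    traces: Sequence,
    thresholds=None,
    cfg: SieveConfig | None = None,
) -> list:
    """One SievedModel per threshold, each computed from the full alignment.

    Thresholds must be strictly increasing; when omitted the default grid is
    used.  Every model is a pure function of (alignment, threshold) — the
    sweep shares no removal trajectory.
    """
    if thresholds is None:
        thresholds = default_threshold_grid(msa, traces)
    thresholds = [float(t) for t in thresholds]
    if not thresholds:
        raise SieveError("threshold list is empty")
    if any(t <= 0 for t in thresholds):
        raise SieveError("thresholds must be positive")
    if any(b <= a for a, b in zip(thresholds, thresholds[1:])):
        raise SieveError("thresholds must be strictly increasing")
    return [sieve_to_threshold(msa, traces, t, cfg) for t in thresholds]


def sieve_cardinality_sweep(
    msa: MultipleAlignment,
    traces: Sequence,
    threshold: float,
    cfg: SieveConfig | None = None,
) -> list:
    """Sieved models at ensemble sizes K, K-1, ..., min_structures.

    At each cardinality the current ensemble is sieved from scratch at the
    given threshold, then the structure with the largest per-structure RMSD in
    that model is eliminated before the next round.
    """
    cfg = cfg or SieveConfig()
    ids = list(msa.structure_ids)
    if len(ids) < 2:
        raise SieveError("need at least 2 structures")
    if len(ids) < cfg.min_structures + 1:
        raise SieveError(
            f"cardinality sweep needs more than min_structures={cfg.min_structures} inputs"
        )
    models = []
    while len(ids) >= cfg.min_structures:
        sub = msa.subset_structures(ids)
        model = sieve_to_threshold(sub, _trace_subset(traces, ids), threshold, cfg)
        models.append(model)
        if len(ids) == cfg.min_structures:
            break
        worst = max(ids, key=lambda s: model.superposition.per_structure_rmsd[s])
        ids.remove(worst)
    return models


def write_removal_trace_tsv(model: SievedModel, path) -> None:
    """Removal trace as TSV: step, kind, identity, rmsd_after."""
    lines = ["step\tkind\tidentity\trmsd_after"]
    for s in model.removal_trace:
        lines.append(f"{s.step}\t{s.kind}\t{s.identity}\t{s.rmsd_after:.6f}")
    Path(path).write_text("\n".join(lines) + "\n")
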