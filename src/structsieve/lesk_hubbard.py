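"""Lesk-Hubbard curves: correspondence count (NCORE) versus RMSD.

Across a sieve sweep, the retained correspondence count plotted against the
superposition RMSD is flat-to-linear over the conserved core and rises
steeply once divergent regions enter the superposition.  This module builds
the pooled and per-structure curves from a sweep, estimates the
linear-regime limit with an objective two-segment piecewise-linear fit, and
answers standardized-comparison queries (NCORE at a given RMSD, or RMSD at a
given NCORE).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple

import numpy as np

__all__ = [
    "LHCurveError",
    "LHCurve",
    "KneeResult",
    "lh_curves",
    "detect_core_limit",
    "standardized_comparison",
    "write_lh_tsv",
    "plot_lh",
]


class LHCurveError(ValueError):
    """Raised for malformed curves or inconsistent sweep inputs."""


@dataclass(frozen=True)
class LHCurve:
    """Ordered (rmsd, ncore) points for one series across a sweep.

    Points are sorted by RMSD, duplicates collapsed.  For the pooled series
    NCORE is guaranteed non-decreasing along the curve (the sieve's retained
    sets are nested and its removal trace is monotone) and a violation raises.
    Per-structure RMSD — distance of one structure to the consensus — can
    invert very slightly when a column enters the superposition, so
    per-structure curves are built with ``strict=False`` and tolerate small
    local inversions.
    """

    series_id: str
    points: tuple
    ncore_unsieved: int
    strict: bool = True

    def __post_init__(self) -> None:
        pts = sorted({(float(r), int(n)) for r, n in self.points})
        if not pts:
            raise LHCurveError(f"curve {self.series_id!r} has no points")
        ncores = [n for _, n in pts]
        if self.strict and any(b < a for a, b in zip(ncores, ncores[1:])):
            raise LHCurveError(
                f"curve {self.series_id!r}: NCORE decreases along increasing RMSD"
            )
        if max(ncores) > self.ncore_unsieved:
            raise LHCurveError(
                f"curve {self.series_id!r}: NCORE exceeds the unsieved count"
            )
        object.__setattr__(self, "points", tuple(pts))

    @property
    def rmsds(self) -> np.ndarray:
        return np.array([r for r, _ in self.points])

    @property
    def ncores(self) -> np.ndarray:
        return np.array([n for _, n in self.points])


class KneeResult(NamedTuple):
    rmsd_knee: float
    ncore_core: int
    degenerate: bool


def lh_curves(sweep, per_structure: bool = False) -> dict:
    """Build LH curves from a sieve sweep.

    The "pooled" curve uses each model's (pooled_rmsd, ncore).  With
    `per_structure=True`, one curve per structure uses that structure's
    per-structure RMSD; models from which a structure was eliminated
    contribute no point to its curve.
    """
    models = list(sweep)
    if not models:
        raise LHCurveError("sweep is empty")
    unsieved = {m.ncore_unsieved for m in models}
    if len(unsieved) != 1:
        raise LHCurveError("sweep models do not come from one input alignment")
    ncore_unsieved = unsieved.pop()
    all_ids = set().union(*(m.retained_structures for m in models))

    curves = {
        "pooled": LHCurve(
            "pooled",
            tuple((m.rmsd, m.ncore) for m in models),
            ncore_unsieved,
        )
    }
    if per_structure:
        for sid in sorted(all_ids):
            pts = [
                (m.superposition.per_structure_rmsd[sid], m.ncore)
                for m in models
                if sid in m.retained_structures
            ]
            curves[sid] = LHCurve(sid, tuple(pts), ncore_unsieved, strict=False)
    return curves


def _segment_sse(x: np.ndarray, y: np.ndarray) -> float:
    """Residual sum of squares of the least-squares line through (x, y)."""
    if len(x) < 3:
        return 0.0
    A = np.column_stack([x, np.ones_like(x)])
    _, res, rank, _ = np.linalg.lstsq(A, y, rcond=None)
    if res.size:
        return float(res[0])
    yhat = A @ np.linalg.lstsq(A, y, rcond=None)[0]
    return float(np.sum((y - yhat) ** 2))


def detect_core_limit(curve: LHCurve) -> KneeResult:
    """Two-segment piecewise-linear breakpoint of NCORE versus RMSD.

    Every interior point is tried as the shared breakpoint of two
    independently fitted segments; the breakpoint minimising the total squared
    error is returned (ties to the smaller RMSD).  When every candidate has
    the same error — e.g. a perfectly straight curve — the result is flagged
    degenerate and the last candidate is reported.
    """
    x = curve.rmsds
    y = curve.ncores.astype(float)
    n = len(x)
    if n < 5:
        raise LHCurveError(f"need at least 5 points, got {n}")
    candidates = range(1, n - 1)
    errs = np.array(
        [_segment_sse(x[: b + 1], y[: b + 1]) + _segment_sse(x[b:], y[b:]) for b in candidates]
    )
    if np.allclose(errs, errs[0], atol=1e-9):
        b = n - 2
        return KneeResult(float(x[b]), int(y[b]), True)
    b = list(candidates)[int(np.argmin(errs))]
    return KneeResult(float(x[b]), int(y[b]), False)


def standardized_comparison(curves, at_rmsd: float | None = None, at_ncore: int | None = None) -> dict:
    """Per-series value at a common abscissa, for standardized comparisons.

    With `at_rmsd`, returns each series' NCORE at that RMSD (stepwise-constant
    interpolation: the last point at or below the query).  With `at_ncore`,
    returns the smallest RMSD at which the series reaches that NCORE.
    Queries outside a series' range map to None for that series.
    """
    if (at_rmsd is None) == (at_ncore is None):
        raise LHCurveError("specify exactly one of at_rmsd / at_ncore")
    if not isinstance(curves, dict):
        curves = {c.series_id: c for c in curves}
    out = {}
    for sid, c in curves.items():
        r = c.rmsds
        n = c.ncores
        if at_rmsd is not None:
            if at_rmsd < r[0] or at_rmsd > r[-1]:
                out[sid] = None
            else:
                out[sid] = int(n[np.searchsorted(r, at_rmsd, side="right") - 1])
        else:
            if at_ncore > n[-1]:
                out[sid] = None
            else:
                out[sid] = float(r[int(np.searchsorted(n, at_ncore, side="left"))])
    return out


def write_lh_tsv(curves: dict, path) -> None:
    """Curves as TSV: series_id, rmsd, ncore, ncore_ratio."""
    lines = ["series_id\trmsd\tncore\tncore_ratio"]
    for sid in sorted(curves, key=lambda s: (s != "pooled", s)):
        c = curves[sid]
        for r, n in c.points:
            lines.append(f"{sid}\t{r:.6f}\t{n}\t{n / c.ncore_unsieved:.6f}")
    Path(path).write_text("\n".join(lines) + "\n")


def plot_lh(curves: dict, path, show_knee: bool = True) -> None:
    """Scatter of NCORE vs RMSD per series, optionally with the fitted knee."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4.5))
    for sid, c in sorted(curves.items()):
        ax.plot(c.rmsds, c.ncores, marker="o", ms=3, lw=1, label=sid)
        if show_knee and len(c.points) >= 5:
            knee = detect_core_limit(c)
            if not knee.degenerate:
                ax.axvline(knee.rmsd_knee, color="grey", lw=0.5, ls="--")
    ax.set_xlabel("RMSD (Å)")
    ax.set_ylabel("NCORE (aligned residue correspondences)")
    if len(curves) <= 10:
        ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
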