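"""Alignment-accuracy metrics against a reference multiple alignment.

The Q score is the fraction of the reference alignment's residue pairs that a
test alignment reproduces: a pair is (structure a, residue i) aligned to
(structure b, residue j) within one column, counted over every ordered
structure pair a < b, gapped columns included.  The reference fixes the
denominator, so Q is deliberately asymmetric.  `benchmark_series` scores each
model of a sieve sweep against the reference on the standardized
NCORE/NCORE_unsieved abscissa.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

__all__ = ["MetricsError", "QResult", "q_score", "benchmark_series", "write_benchmark_tsv"]


class MetricsError(ValueError):
    """Raised when alignments are not comparable."""


@dataclass(frozen=True)
class QResult:
    """Q score with the pair counts behind it."""

    q: float
    shared_pairs: int
    reference_pairs: int
    empty_reference: bool = False


def _pair_set(msa) -> set:
    """All within-column residue pairs, keyed by structure id (a < b)."""
    pairs = set()
    ids = msa.structure_ids
    M = msa.index_matrix
    K = len(ids)
    for c in range(M.shape[1]):
        col = M[:, c]
        present = [k for k in range(K) if col[k] >= 0]
        for a, b in itertools.combinations(present, 2):
            ia, ib = ids[a], ids[b]
            if ia <= ib:
                pairs.add((ia, int(col[a]), ib, int(col[b])))
            else:
                pairs.add((ib, int(col[b]), ia, int(col[a])))
    return pairs


def q_score(test, reference) -> QResult:
    """Fraction of reference residue pairs present in the test alignment."""
    if set(test.structure_ids) != set(reference.structure_ids):
        raise MetricsError(
            "test and reference alignments cover different structure sets"
        )
    ref_pairs = _pair_set(reference)
    if not ref_pairs:
        return QResult(q=0.0, shared_pairs=0, reference_pairs=0, empty_reference=True)
    shared = len(ref_pairs & _pair_set(test))
    return QResult(
        q=shared / len(ref_pairs),
        shared_pairs=shared,
        reference_pairs=len(ref_pairs),
    )


def benchmark_series(sweep, reference) -> pd.DataFrame:
    """Score every sieved model of a sweep against a reference alignment.

    Each model's restricted alignment (retained columns only) is Q-scored
    against the reference.  Returns a table with one row per model —
    threshold, ncore, ncore_ratio, q — ordered by ncore_ratio.
    """
    rows = []
    for m in sweep:
        res = q_score(m.alignment, reference)
        rows.append(
            {
                "threshold": m.threshold,
                "ncore": m.ncore,
                "ncore_ratio": m.ncore_ratio,
                "q": res.q,
            }
        )
    return (
        pd.DataFrame(rows, columns=["threshold", "ncore", "ncore_ratio", "q"])
        .sort_values("ncore_ratio", kind="stable")
        .reset_index(drop=True)
    )


def write_benchmark_tsv(table: pd.DataFrame, path) -> None:
    table.to_csv(Path(path), sep="\t", index=False, float_format="%.6f")
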