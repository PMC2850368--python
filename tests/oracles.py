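"""Independent reference implementations used only to check the package.

These deliberately use different algorithms from the implementation under
test: the quaternion (Horn) eigenvalue method for optimal-superposition RMSD,
and exhaustive enumeration for the optimal sieved column subset.
"""

import itertools

import numpy as np


def quaternion_rmsd(P: np.ndarray, Q: np.ndarray) -> float:
    """Minimal RMSD of Q onto P over proper rigid motions, via the largest
    eigenvalue of Horn's 4x4 quaternion matrix (no SVD, no rotation built)."""
    P = np.asarray(P, float)
    Q = np.asarray(Q, float)
    n = len(P)
    P0 = P - P.mean(axis=0)
    Q0 = Q - Q.mean(axis=0)
    S = Q0.T @ P0  # S[a, b] = sum_i q_ia * p_ib
    Sxx, Sxy, Sxz = S[0]
    Syx, Syy, Syz = S[1]
    Szx, Szy, Szz = S[2]
    K = np.array(
        [
            [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
            [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
            [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
            [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz],
        ]
    )
    lam = np.linalg.eigvalsh(K)[-1]
    msd = (np.sum(P0 * P0) + np.sum(Q0 * Q0) - 2.0 * lam) / n
    return float(np.sqrt(max(msd, 0.0)))


def brute_force_optimal_ncore(msa, traces, threshold, min_size=3):
    """Largest column subset whose consensus superposition meets the threshold,
    found by exhaustive enumeration (for small column counts only)."""
    from structsieve.superposition import superpose_ensemble

    cols = list(msa.fully_aligned_columns())
    for r in range(len(cols), min_size - 1, -1):
        for sub in itertools.combinations(cols, r):
            if superpose_ensemble(traces, msa, sub).pooled_rmsd <= threshold:
                return r
    return 0


def best_merge_first_tree(D: np.ndarray, ids):
    """Naive best-merge-first (UPGMA) reference: repeatedly join the two
    clusters with the smallest mean leaf-to-leaf distance."""
    clusters = [(i,) for i in ids]
    merges = []
    idx = {i: k for k, i in enumerate(ids)}
    while len(clusters) > 1:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                d = np.mean(
                    [[D[idx[x], idx[y]] for y in clusters[b]] for x in clusters[a]]
                )
                key = (d, min(min(clusters[a]), min(clusters[b])),
                       max(min(clusters[a]), min(clusters[b])))
                if best is None or key < best[0]:
                    best = (key, a, b)
        _, a, b = best
        ca, cb = clusters[a], clusters[b]
        if min(cb) < min(ca):
            ca, cb = cb, ca
        merges.append((ca, cb))
        clusters = [c for k, c in enumerate(clusters) if k not in (a, b)] + [ca + cb]
    return merges
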