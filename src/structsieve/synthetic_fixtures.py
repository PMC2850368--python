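"""Seeded synthetic Cα ensembles with known ground truth.

The generator emulates the situation the sieve is built for: a family of
structures sharing a conserved rigid core and divergent loop regions.  Each
ensemble member is a common template perturbed by isotropic Gaussian
coordinate noise — small in the core, large in the loops — then moved by a
random rigid transformation (rotation uniform over SO(3) via unit
quaternions, translation uniform in a 50 Å cube).  Gaussian coordinate noise
keeps the expected superposition statistics analytically tractable: with K
members at per-coordinate noise sd σ, the expected squared column deviation
is 3 σ² (K − 1) / K.

Because the members are indexed copies of one template, the true alignment is
the identity mapping and the core/loop mask is exact, giving ground truth for
precision/recall of sieved cores, outlier elimination order, and gap handling
(via injected insertions).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .msa_engine import MultipleAlignment
from .structure_io import CaTrace

__all__ = [
    "SyntheticEnsemble",
    "make_template",
    "make_core_loop_ensemble",
    "default_core_mask",
    "inject_insertion",
    "random_rigid_motion",
]

CA_STEP = 3.8  # Å, consecutive Cα spacing enforced by all geometries


@dataclass(frozen=True)
class SyntheticEnsemble:
    """K noisy copies of a template plus the generating ground truth."""

    traces: tuple
    core_mask: np.ndarray
    true_alignment: MultipleAlignment
    outlier_ids: tuple
    params: dict = field(default_factory=dict)


def _helix_coords(n: int, rise: float, twist_deg: float) -> np.ndarray:
    """Ideal helix with radius solved so consecutive Cα are CA_STEP apart."""
    twist = math.radians(twist_deg)
    radius = math.sqrt((CA_STEP**2 - rise**2) / (4.0 * math.sin(twist / 2.0) ** 2))
    i = np.arange(n)
    return np.column_stack(
        [radius * np.cos(i * twist), radius * np.sin(i * twist), rise * i]
    )


def make_template(n: int, geometry: str = "helix", seed: int = 0) -> CaTrace:
    """Deterministic template trace of n >= 8 residues.

    "helix" uses ideal α-helix parameters (1.5 Å rise, 100° twist);
    "extended" a β-strand-like twist (3.3 Å rise, 170° twist); "random-walk"
    fixed 3.8 Å steps with turn angles bounded by 60°.  In every geometry the
    consecutive Cα spacing is exactly 3.8 Å.
    """
    if n < 8:
        raise ValueError(f"template needs at least 8 residues, got {n}")
    if geometry == "helix":
        coords = _helix_coords(n, rise=1.5, twist_deg=100.0)
    elif geometry == "extended":
        coords = _helix_coords(n, rise=3.3, twist_deg=170.0)
    elif geometry == "random-walk":
        rng = np.random.default_rng(seed)
        coords = np.zeros((n, 3))
        d = rng.normal(size=3)
        d /= np.linalg.norm(d)
        for i in range(1, n):
            coords[i] = coords[i - 1] + CA_STEP * d
            # bounded random turn for the next step
            axis = np.cross(d, rng.normal(size=3))
            axis /= np.linalg.norm(axis)
            angle = rng.uniform(0.0, math.radians(60.0))
            d = d * math.cos(angle) + np.cross(axis, d) * math.sin(angle)
            d /= np.linalg.norm(d)
    else:
        raise ValueError(f"unknown geometry {geometry!r}")
    labels = [("ALA", i + 1, "") for i in range(n)]
    return CaTrace(
        structure_id=f"tmpl-{geometry}-n{n}-s{seed}", coords=coords, labels=labels
    )


def random_rigid_motion(rng: np.random.Generator, box: float = 50.0):
    """Uniform random rotation (quaternion method) + translation in a cube."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    R = np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )
    t = rng.uniform(-box / 2.0, box / 2.0, size=3)
    return R, t


def default_core_mask(core_len: int, loop_lens=(10, 10)) -> np.ndarray:
    """Core split evenly around the loops: core/loop/core/loop/.../core."""
    n_loops = len(loop_lens)
    seg = core_len // (n_loops + 1)
    mask = []
    remaining = core_len
    for ll in loop_lens:
        mask += [True] * seg
        remaining -= seg
        mask += [False] * ll
    mask += [True] * remaining
    return np.array(mask, dtype=bool)


def make_core_loop_ensemble(
    K: int,
    template: CaTrace,
    core_mask,
    core_noise_sd: float,
    loop_noise_sd: float,
    outliers: int = 0,
    outlier_noise_sd: float = 5.0,
    seed: int = 0,
) -> SyntheticEnsemble:
    """K noisy rigid copies of a template with core/loop noise regimes.

    Per-structure: isotropic Gaussian noise with per-residue sd taken from
    `core_noise_sd` (mask True) or `loop_noise_sd` (mask False), followed by
    an independent random rigid motion.  The last `outliers` structures get
    `outlier_noise_sd` everywhere instead.  Everything is reproducible from
    `seed`.
    """
    if K < 2:
        raise ValueError("need at least 2 structures")
    mask = np.asarray(core_mask, dtype=bool)
    n = len(template.coords)
    if mask.shape != (n,):
        raise ValueError("core_mask length must equal template length")
    if core_noise_sd < 0 or loop_noise_sd < core_noise_sd:
        raise ValueError("expect 0 <= core_noise_sd <= loop_noise_sd")
    if not 0 <= outliers < K:
        raise ValueError("outliers must be in [0, K)")

    rng = np.random.default_rng(seed)
    sd = np.where(mask, core_noise_sd, loop_noise_sd)
    traces = []
    outlier_ids = []
    for k in range(K):
        is_outlier = k >= K - outliers
        sd_k = np.full(n, outlier_noise_sd) if is_outlier else sd
        noisy = template.coords + rng.normal(size=(n, 3)) * sd_k[:, None]
        R, t = random_rigid_motion(rng)
        moved = noisy @ R.T + t
        sid = f"{template.structure_id}-m{k}"
        if is_outlier:
            outlier_ids.append(sid)
        traces.append(CaTrace(structure_id=sid, coords=moved, labels=list(template.labels)))

    identity = np.tile(np.arange(n, dtype=int), (K, 1))
    true_alignment = MultipleAlignment(
        tuple(t.structure_id for t in traces), identity
    )
    return SyntheticEnsemble(
        traces=tuple(traces),
        core_mask=mask,
        true_alignment=true_alignment,
        outlier_ids=tuple(outlier_ids),
        params={
            "K": K,
            "template": template.structure_id,
            "core_noise_sd": core_noise_sd,
            "loop_noise_sd": loop_noise_sd,
            "outliers": outliers,
            "outlier_noise_sd": outlier_noise_sd,
            "seed": seed,
        },
    )


def inject_insertion(trace: CaTrace, position: int, length: int, seed: int = 0) -> CaTrace:
    """Insert a `length`-residue bulge before residue `position`.

    The inserted residues are placed on a circular arc between the flanking
    residues, in a randomly oriented plane, with every consecutive spacing
    equal to 3.8 Å — so chain connectivity is preserved exactly at both
    junctions.  Residues outside the insertion keep their coordinates;
    sequence numbers are renumbered consecutively.
    """
    n = len(trace.coords)
    if not 0 < position < n:
        raise ValueError(f"position must be inside the trace (0 < p < {n})")
    if length == 0:
        return CaTrace(trace.structure_id, trace.coords.copy(), list(trace.labels))
    if length < 0:
        raise ValueError("length must be non-negative")

    rng = np.random.default_rng(seed)
    A = trace.coords[position - 1]
    B = trace.coords[position]
    ab = B - A
    dist = float(np.linalg.norm(ab))
    m = length + 1  # chord count on the arc A -> B
    # solve per-chord angle phi: sin(m*phi/2) / sin(phi/2) = |AB| / 3.8,
    # taking the long-way branch so the arc bulges away from the chord
    from scipy.optimize import brentq

    def f(phi):
        return math.sin(m * phi / 2.0) / math.sin(phi / 2.0) - dist / CA_STEP

    hi = 2.0 * math.pi / m - 1e-12
    lo = 1e-9
    # long-way branch: m*phi/2 in (pi/2, pi); restrict accordingly
    lo = max(lo, math.pi / m)
    phi = brentq(f, lo, hi, xtol=1e-13)
    R = CA_STEP / (2.0 * math.sin(phi / 2.0))

    u = ab / dist
    v = rng.normal(size=3)
    v -= (v @ u) * u
    v /= np.linalg.norm(v)
    half = dist / 2.0
    h = math.sqrt(max(R * R - half * half, 0.0))
    centre = (A + B) / 2.0 + h * v
    normal = np.cross(u, v)
    normal /= np.linalg.norm(normal)

    def rotate(p, angle):
        rel = p - centre
        return (
            centre
            + rel * math.cos(angle)
            + np.cross(normal, rel) * math.sin(angle)
            + normal * (normal @ rel) * (1.0 - math.cos(angle))
        )

    for sign in (1.0, -1.0):
        pts = [rotate(A, sign * phi * k) for k in range(1, m)]
        if np.linalg.norm(rotate(A, sign * phi * m) - B) < 1e-6:
            break
    else:  # pragma: no cover - defensive
        raise RuntimeError("arc construction failed to close")

    coords = np.vstack([trace.coords[:position], pts, trace.coords[position:]])
    labels = [
        (trace.labels[i][0] if i < position else ("GLY" if i < position + length else trace.labels[i - length][0]),
         i + 1,
         "")
        for i in range(n + length)
    ]
    return CaTrace(structure_id=trace.structure_id, coords=coords, labels=labels)
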