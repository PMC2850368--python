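# Methods

This note documents the models, algorithms, parameters and design choices
behind structsieve, and what the synthetic test conditions do and do not
establish about behaviour on real data.

## Superposition model and RMSD definitions

All superpositions are least-squares rigid fits of Cα coordinates.

**Pairwise (Kabsch).** Given point sets P, Q (n ≥ 3) and optional
non-negative weights, the proper rotation R and translation t minimising
Σ w_i ‖R q_i + t − p_i‖² are obtained from the SVD of the weighted
cross-covariance, with the usual determinant sign correction so reflections
are never returned. The implementation is cross-checked in the test suite
against an independent quaternion-eigenvalue (Horn) oracle to 1e-6 Å on
random point sets.

**Ensemble (consensus).** K ≥ 2 structures are superposed over a common set
of aligned columns by alternating least squares: (a) fit each structure onto
the current consensus with Kabsch, (b) recompute the consensus as the
per-column mean of the transformed coordinates. Both half-steps are
least-squares improvements, so the pooled RMSD is non-increasing; iteration
stops when it changes by < 1e-6 Å (cap 100 rounds; typical ensembles converge
in < 10). The consensus is initialised from the first structure and the final
frame is centred at the consensus centroid.

Ensemble RMSD is defined as the RMS deviation from the consensus, pooled over
structures and columns. There is no unique convention for multi-structure
RMSD; the consensus definition was chosen because it makes the pooled,
per-structure and per-column statistics satisfy exact conservation
identities,

    pooled² = mean_k per_structure_k² = mean_c column_dev_c²,

so the number used to stop the sieve, the per-structure curves and the
per-correspondence removal criterion are all facets of one quantity.
Average-pairwise RMSD, the other common convention, is larger by a factor
approaching √(2K/(K−1)) and would not decompose this way.

## Multiple structural alignment

The built-in aligner is a conventional progressive scheme; it is deliberately
simple and is *not* a reimplementation of any particular published aligner.
For exact reproduction of another program's correspondences, an external
aligned-FASTA can be imported verbatim (`import_alignment`, CLI
`--engine import:`), and every downstream statistic (NCORE, RMSD, sieving,
curves, Q scores) is then computed on those correspondences.

**Pairwise stage.** Iterative superpose–score–realign on Cα traces:

- *Seeding.* Every diagonal offset is scanned with 15-residue gapless
  windows (stride 3, final position always included), superposed by batched
  SVD. Offsets are ranked by how many full-overlap residues fall within the
  8 Å pair cutoff under the best window's transform, ties broken by window
  RMSD. The refinement loop is run from the best window of each of the top 5
  offsets and the highest-scoring result kept. The overlap-count ranking and
  the multi-seed restart are both needed for internally periodic folds
  (helices, repeat proteins), where shifted registers superpose locally as
  well as the true one and a single seed can trap the iteration in a
  register shifted by one or two positions.
- *Iteration.* Kabsch on the current pairs; similarity matrix
  S(i,j) = 1 / (1 + (d_ij/d0)²) with d0 = 3.0 Å on the superposed distances;
  global affine-gap dynamic programming (gap open 4.0, extend 0.5, a gap of
  length L costs 4.0 + 0.5·(L−1)); new pairs are the matched DP cells with
  d_ij ≤ 8 Å. The loop stops when the pair set repeats or after 30 rounds.
  d0, the gap costs, the cutoff and the window size are conventional values
  for Cα aligners and are exposed as keyword arguments.

**Guide tree.** UPGMA on distance 1 − (pairwise score normalised by the
larger off-diagonal score), ties broken by the lexicographically smallest
pair of cluster representatives, so the tree — and hence the whole alignment
— is deterministic.

**Progressive merge.** A merged group is represented by the consensus
coordinates of its fully aligned columns; group–group alignment uses the same
pairwise engine on the consensus traces, and unmatched columns are interleaved
(first group's columns first) preserving per-row residue order. Consensus
representation of profiles loses within-group variance information; this is a
known simplification relative to all-pairs profile scoring.

## Sieving

`sieve_to_threshold` is greedy worst-first removal with refitting: superpose
over the retained columns; if pooled RMSD ≤ t stop; otherwise delete the
`batch` (default 1) columns with the largest consensus deviation (ties to the
lower column index, for determinism) and repeat. Each re-superposition is
warm-started from the previous consensus restricted to the surviving columns;
together with the fact that the removed column's squared deviation is at
least the pooled mean, this makes the recorded RMSD after every removal
provably non-increasing. A cold restart could, in rare geometries, converge
to a slightly different alternating-least-squares fixed point and break that
monotonicity.

The column floor is `min_ncore` = 3, the minimum for a defined rigid
superposition. With `drop_structures` enabled, a sieve stalled at the floor
above threshold eliminates the structure with the largest per-structure RMSD
(one at a time, down to `min_structures` = 2), restores every column fully
aligned in the reduced ensemble, and restarts column sieving. Structure
elimination is deliberately conservative — only at the floor, never eagerly.

Threshold sweeps compute every model independently from the full alignment,
so each sieved model is a pure function of (alignment, threshold) rather than
of a shared trajectory; because the greedy removal order does not depend on
the threshold, the retained sets are nested and NCORE is non-decreasing in t.
The default grid runs from 0.2 Å to the unsieved RMSD rounded up, in 0.1 Å
steps. The cardinality sweep sieves at fixed t, eliminates the
worst-fitting structure of the resulting model, and recomputes from scratch
at each ensemble size.

Greedy quality: on small ensembles where exhaustive search over all column
subsets is feasible (≤ 8 columns), the greedy terminal NCORE is within one
column of the optimum (asserted over 200 random instances in the test suite).

## Lesk–Hubbard curves and the core limit

The pooled curve plots each sweep model's (pooled RMSD, NCORE); per-structure
curves use the structure's own RMSD to the consensus. Because retained sets
are nested and the removal trace monotone, the pooled curve is monotone by
construction and the curve container enforces this. Per-structure RMSD can
invert very slightly when a column enters the fit, so per-structure series
are stored without the strict monotonicity check.

The core limit is estimated objectively by a two-segment piecewise-linear
least-squares fit of NCORE against RMSD: every interior point is tried as the
shared breakpoint of two independently fitted segments and the total squared
error is minimised (ties to the smaller RMSD). A perfectly straight curve
makes every breakpoint equivalent; that case is flagged degenerate and the
last candidate reported. Interpolation for standardized comparisons
("NCORE at a given RMSD", "RMSD at a given NCORE") is stepwise-constant,
since NCORE is a count.

## Q score

A residue pair is (structure a, residue i) aligned with (structure b,
residue j), a < b, within one column; pairs are counted over all structure
pairs including partially gapped columns. Q = shared pairs / reference pairs.
The reference fixes the denominator, so Q is asymmetric by design; an empty
reference yields Q = 0 with an explicit flag. Note that restricting an
alignment to its fully aligned columns removes pairs exactly proportionally
to NCORE only when every reference pair lies in a fully aligned column (e.g.
two-structure alignments); with K > 2 and gapped columns the sieved Q is
systematically below the NCORE ratio.

## Synthetic ensembles and what the tests show

The generator emulates the target use case — a conserved rigid core plus
divergent loops — as a common template with per-region isotropic Gaussian
coordinate noise followed by a random rigid motion (rotation uniform via unit
quaternions, translation in a 50 Å cube). Gaussian coordinate noise was
chosen over dihedral perturbation because its superposition statistics are
exact: with K members at noise sd σ, E[column deviation²] = 3σ²(K−1)/K, which
the tests verify by Monte Carlo. Templates (ideal helix: 1.5 Å rise, 100°
twist; extended: 3.3 Å rise, 170° twist; bounded-turn random walk) all have
exactly 3.8 Å consecutive Cα spacing — the helix radius (≈2.279 Å) is solved
from the rise and twist to make that spacing exact. Insertions for gap-handling
tests are placed on a circular arc between the flanking residues in a
seed-randomised plane, preserving the 3.8 Å spacing exactly at both junctions.

The standard study conditions used throughout the tests and the acceptance
script are: K = 6, 60-residue core at 0.2 Å noise, two 10-residue loops at
3.0 Å noise, sieve threshold 0.6 Å, 20 replicate seeds. Under these
conditions the full pipeline (generate → align → sieve) recovers the true
core columns with mean precision ≈ 0.98 and recall 1.0, and the knee
estimator localises the core size to within a few residues. Outlier
structures (5 Å noise everywhere) are eliminated first by the cardinality
sweep in every replicate.

What this does *not* show: the generator produces no sequence signal, no
correlated (hinge or shear) motions, no alternative conformations, and its
loops are noisy copies of one template rather than topologically different
segments. Results on real, divergent protein families — where alignment
errors, not superposition noise, dominate — are therefore expected to be
weaker than the synthetic figures, and benchmarks on real ensembles should
use an imported alignment from a dedicated structural aligner when exact
parity with that aligner matters.

## Numerical and degenerate-input conventions

- Ensemble convergence tolerance 1e-6 Å, cap 100 iterations.
- All tie-breaks are fully specified (column index, lexicographic ids), so
  identical inputs and configuration give byte-identical outputs.
- Collinear point sets are superposed (the rotation is then not unique; any
  minimiser is returned).
- PDB altLoc duplicates resolve to the highest occupancy, ties by file
  order; waters and residues without a carbon Cα are excluded (this keeps
  selenomethionine, drops ligands and metal ions); multi-model files default
  to model 1; residue order is file order, and insertion codes are part of
  residue identity.
- Mixed models truncate non-conserved residues to {N, CA, C, O, CB} and
  rename them ALA; glycines are left unchanged (no CB is fabricated).

## Known limitations

- The progressive aligner is linear (order-preserving) only; circular
  permutations and non-sequential equivalences are out of scope.
- Consensus-based profile representation can mis-register extremely
  divergent members; the multi-seed restart mitigates but cannot eliminate
  this on self-similar folds.
- The knee estimator assumes a single linear-to-steep transition; multi-core
  architectures (several plateaus) report only the best single breakpoint.
- Per-structure Lesk–Hubbard curves are not guaranteed monotone (see above).
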