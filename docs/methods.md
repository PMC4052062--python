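# Methods

This note documents the models, algorithms, numerical choices and known
limitations of the `semirigid` package in one place.

## Pair-distance fluctuation matrix

For atoms i, j and a trajectory of F frames, the package computes

    S_ij = sqrt( F/(F-1) * mean_t( (d_ij(t) - mean_t d_ij)^2 ) ),

the unbiased sample standard deviation of the inter-atomic distance, in
nm. The Bessel factor uses the number of *frames*: a per-pair variance
estimator's small-sample correction must depend on the number of
observations entering it, and each pair contributes one observation per
frame. With hundreds of frames the factor is within 1% of 1 either way.
The estimate is two-pass (mean first, then squared deviations) for
numerical robustness; per-frame distance matrices come from
`scipy.spatial.distance.pdist`.

Because pair distances are invariant under rigid motion, S is exactly
zero for a rigid structure under arbitrary per-frame rotation and
translation — the property that makes the whole approach fitting-free.
In float64 the residual is ~1e-15 nm (round-off in the rotations), which
is why "exact zero" assertions in the tests carry 1e-12…1e-9 tolerances.

The default atom selection is the backbone alpha carbons (`"CA"`):
side chains fluctuate far more than the backbone and would blur domain
boundaries. For production use the second half of the trajectory is the
recommended input span (see *Equilibration* below); the CLI exposes this
as `--half-trajectory`.

## Target function and crispness

Clustering minimizes q(c) = tr(c^T S c) over crisp one-cluster-per-atom
memberships for a preselected cluster count K. q sums S_ij over *ordered*
within-cluster pairs, so each unordered pair counts twice; all per-pair
averages reported by the package (within/between tables) divide by
unordered-pair counts. The cluster count is a user choice by design — the
package deliberately offers no automatic selection, since the useful K
depends on what the decomposition is for (a fitting reference wants few,
large, rigid clusters).

The fuzzy relaxation of the problem (row-stochastic weights on the
simplex product Ω) cannot do better: with S symmetric, nonnegative and
zero-diagonal, q is *linear* in each atom's weight row when the other
rows are fixed (the quadratic self-term vanishes with S_ii = 0), so
row-wise minimization always reaches a simplex vertex and the global
minimizer over Ω is crisp. `semirigid.theory` ships this as verification
tooling rather than trusting it:

* `uniform_stationary` returns the unique interior critical point
  (uniform weights 1/K, multipliers λ_i = -(2/K) Σ_j S_ij) and
  `stationarity_residual` confirms the Lagrangian gradient vanishes there.
* `lagrange_system_matrix` assembles the stationarity system — K copies
  of S on the block diagonal, identity blocks coupling to the
  multipliers. Its determinant, by the Schur complement
  det(M) = det(S)^K · det(-K·S^{-1}), is

      det(M) = (-K)^N · det(S)^(K-1).

  Treating the blocks as scalars during elimination would suggest the
  constant -K instead of (-K)^N; that shortcut is valid only at N = 1.
  `lagrange_system_det` returns the true determinant and the test suite
  checks the closed form to 1e-8 relative. What matters for the theory is
  only that det(M) ≠ 0 exactly when det(S) ≠ 0: the interior critical
  point is then unique, so the minimum must lie on the boundary of Ω —
  the first step of the crispness argument.
* `lemma_probe` samples memberships row-wise from a symmetric
  Dirichlet(1) — uniform on each atom's simplex; the probing distribution
  is otherwise a free choice — and counts samples with q below the
  enumerated crisp ground state, with a 1e-12 guard so vertex-adjacent
  round-off cannot register as a violation. Expected count: zero, and the
  acceptance suite confirms it over 10^5 samples across 50 matrices.

The uniform stationary point is *not* asserted to be the global maximum
of q over Ω (the all-in-one-cluster vertex has q = Σ S_ij, which is K
times larger); only its stationarity and uniqueness as an interior
critical point are claimed and tested.

## Two-stage Monte Carlo search

Each restart draws a uniformly random assignment, then:

1. **Random stage** — for K_sweeps = N·K sweeps, each atom is proposed,
   with probability P = 1/N, into a uniformly random *other* cluster;
   accepted iff q strictly decreases.
2. **Exhaustive stage** — repeated passes over all (atom, target-cluster)
   single moves, taking any strictly improving move, until none exists.
   The result is a minimum constellation: single-move local minimal,
   certified in the tests by full recomputation of all N·(K-1) moves.

Both stages use the incremental identity Δq(i: a→b) =
2·(Σ_{j∈b} S_ij − Σ_{j∈a} S_ij), maintained via per-atom cluster sums, so
a move costs O(N) instead of O(N²); the returned q is recomputed from
scratch at the end to discard accumulation drift. "Strict decrease" is
implemented as Δq < −1e-12: the epsilon stops round-off in the
incremental bookkeeping from accepting an equal-q move, which could cycle;
since every accepted move lowers q by more than the epsilon and q ≥ 0,
termination is guaranteed. Equal-q (neutral) moves are therefore never
taken.

The default is 100 restarts; restart r seeds its own generator with
`seed + r`, and the lowest-q result wins with first-found tie-breaking,
so a fixed seed gives a fixed answer. Empty clusters are allowed (the
optimizer may effectively use fewer than K clusters; a warning is
emitted) — forbidding them would need a repair step with no principled
definition. On unstructured (random or scrambled) matrices many local
minima lie within ~1e-3 of the ground state; single restarts then miss
the absolute optimum a few percent of the time, which is why the restart
count should not be cut far below the default on such inputs. Structured
matrices reach their ground state in a handful of restarts.

`brute_force_ground_state` enumerates all K^N label vectors (chunked,
vectorized; refused above 10^7) and is the oracle the stochastic search
is tested against — 200 random instances at N ≤ 8 in the acceptance
suite, all reaching the enumerated optimum.

Canonical labeling (`relabel_by_size`): clusters renumbered by decreasing
size, ties broken by the smallest contained atom index, so label 0 is
always the largest cluster and results are comparable across runs.

## Cluster summaries

`within_between_table` reports mean STDDV over unordered pairs within
each cluster (diagonal) and across each cluster pair (off-diagonal);
entries involving singleton or empty clusters are NaN rather than a
sentinel value. `normalized_summary` reports per-cluster normalized size
(size·K/N, so 1 = average size), normalized within-STDDV (within mean
× K, comparable across K), and the captured-STDDV fraction q(c)/q(single
cluster) — the share of total pair variability still inside clusters.

## Window stability

`split_windows` cuts the frame range into contiguous near-equal windows
(remainder to the earliest). Each window is clustered from its own STDDV
matrix with the same search configuration; the first window is
canonicalized by size and every later window is relabeled by the
permutation minimizing the number of atoms disagreeing with the *first*
window (not chained window-to-window, which would accumulate drift).
The permutation is found as a linear assignment on the label-agreement
contingency table (`scipy.optimize.linear_sum_assignment`) — minimizing
migrations is exactly maximizing the permuted table trace — with a greedy
refinement that returns the lexicographically smallest optimal
permutation for deterministic ties; an exhaustive-permutation oracle
certifies it in the tests for K ≤ 6. Using one master seed for all
windows means identical window matrices yield identical clusterings, so
a static trajectory shows zero migrations by construction.

From the aligned series: `migration_series` counts label changes between
consecutive windows; `net_migrations` compares first to last (large
consecutive counts with a near-zero net count is the signature of
reversible excursions); `membership_probabilities` gives p_im as the
fraction of windows with label m; and

    KLD_i = Σ_m p_im · log10( p_im / (1/K) ),   0·log 0 := 0,

bounded by [0, log10 K], equal to 0 exactly at a uniform row and to
log10 K exactly at an indicator row. Base 10 is the default (a natural-log
base can be passed). Note the ceiling is log10 K regardless of the number
of windows: with W windows an atom that never migrates attains exactly
log10 K, not log10 W — the number of windows only sets the resolution of
the p_im estimates. `stiff_kernel` returns atoms with at most
`max_changes` consecutive-window label changes (default 0).

## Equilibration trend

`two_segment_trend` fits ordinary least-squares lines to the per-window
mean-STDDV series over the first (split + overlap) span and the last
(1 − split + overlap) span (defaults 0.5 and 0.1, i.e. 0–60% and
40–100% of the windows). A clearly negative first slope with a flat
second slope indicates the early trajectory still remembers its start
configuration; the recommended remedy, applied by the CLI's
`--half-trajectory` flag before final clustering, is to analyse only the
second half. The windowed stability analysis itself always uses the full
analysed span.

## Synthetic data

`generate_domain_trajectory` emulates the statistical structure real
multi-domain trajectories leave in S, not the physics: each domain is a
fixed random point cloud (sd 0.3 nm around centres spaced 2 nm apart);
per frame each domain receives an independent random rigid motion —
translation components i.i.d. N(0, inter_domain_motion_sd), rotation
with isotropic random axis and angle sd = inter_domain_motion_sd / 0.3 nm
(so the surface displacement matches the translation scale, and zero
motion amplitude means no rotation, keeping the zero-motion ⇒ zero-STDDV
contract exact) — plus i.i.d. per-atom jitter of internal_noise_sd.
Optional linker atoms jitter independently with linker_noise_sd,
emulating flexible loops. Defaults (three domains of 10 atoms, 0.01 nm
internal noise, 0.5 nm inter-domain motion, 200 frames) give a clearly
separable but non-trivial reference condition under which 3-cluster
recovery of the ground truth succeeds in ≥ 19/20 seeds.

What the generator does **not** emulate: bonded-chain connectivity,
secondary structure, anisotropic or correlated thermal motion, slow
conformational transitions, and solvent effects. Passing tests on it
therefore demonstrate the correctness of the machinery (matrix, optimizer,
alignment, profiles) under block-structured S, not performance on any
particular protein; on real trajectories domain boundaries are fuzzy
and window-to-window migration is substantial.

`generate_block_matrix` plants blocks directly in S (uniform draws in a
within range and a between range), `generate_random_matrix` is the
structure-free control, and `randomize_matrix` scrambles an existing
matrix's pair values while preserving their multiset exactly — clustering
a scrambled matrix yields near-equal cluster sizes and much smaller
captured-STDDV reduction than the structured original, the package's
operational test for "is there real structure here?".

## Files and conventions

Internal units are nm; PDB files (Å) are scaled by 0.1 on read and 10 on
write. XYZ defaults to nm with an Å option. Atom indices and cluster
labels are 1-based in all written files (PDB convention) and 0-based in
the Python API. Matrix files are tab-delimited with a label header
row/column, written at 9 significant digits; the reader enforces
symmetry to 1e-8 and a zero diagonal and reports the offending line on
malformed input. All tabular outputs embed provenance comments (tool
version, command line, seed, input checksum). Binary MD formats
(XTC/DCD) are out of scope; convert to multi-frame PDB first.

## Problem sizes

The implementation is pure Python/numpy with an O(N) incremental move
cost; matrices up to a few thousand atoms cluster comfortably. The test
and acceptance suites run at N ≤ 30 with enumeration oracles at N ≤ 8 —
sizes chosen so every stochastic result can be certified against an
exact, independently computed optimum.
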