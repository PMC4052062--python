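"""Verification tooling for the crispness lemma.

The clustering target q(c) = tr(c^T S c) could in principle be minimized
over *fuzzy* memberships — row-stochastic nonnegative weight matrices w on
the product of simplices Omega.  The crispness lemma states that for a
symmetric nonnegative S (zero diagonal) the minimizer is always crisp
(every weight 0 or 1), so the search space can be restricted to label
vectors without loss.  The underlying reason is simple: because S_ii = 0,
q is *linear* in each atom's weight row when the others are held fixed, so
the row-wise minimum sits at a simplex vertex.

This module provides the machinery to check the lemma numerically:

* the Lagrange stationary point of the relaxed problem (uniform weights
  1/N_clust with multipliers lambda_i = -(2/N_clust) * sum_j S_ij),
* the assembled block linear system whose nonsingularity makes that
  stationary point unique, together with its determinant in closed form,
* a Monte Carlo probe that samples fuzzy memberships from Omega and counts
  (expected: zero) samples falling below the enumerated crisp ground state.

A note on the determinant: the block system has N_clust copies of S on the
diagonal coupled by identity blocks to the multipliers.  Naively reducing
the blocks as if they were scalars suggests det = -N_clust *
det(S)^(N_clust - 1); the exact value, by the Schur complement
det(M) = det(S)^K * det(-K S^{-1}), is

    det(M) = (-N_clust)^N * det(S)^(N_clust - 1),

which coincides with the naive reduction only for N = 1.  Either way the
system is nonsingular exactly when det(S) != 0, which is what the
uniqueness argument needs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .cluster import ClusterAssignment, brute_force_ground_state, target_q
from .exceptions import DimensionMismatchError, ParameterError, SemirigidError
from .matrix import STDDVMatrix

#: Tolerated violation of the row-sum-one constraint on fuzzy memberships.
ROW_SUM_ATOL = 1e-8


def validate_membership(w: np.ndarray, n_atoms: int) -> np.ndarray:
    w = np.asarray(w, dtype=float)
    if w.ndim != 2 or w.shape[0] != n_atoms:
        raise DimensionMismatchError(
            f"membership must have {n_atoms} rows, got shape {w.shape}"
        )
    if w.min() < -ROW_SUM_ATOL:
        raise SemirigidError("membership weights must be nonnegative")
    if np.abs(w.sum(axis=1) - 1.0).max() > ROW_SUM_ATOL:
        raise SemirigidError("membership rows must sum to 1")
    return w


def fuzzy_q(s: STDDVMatrix, w: np.ndarray) -> float:
    """q evaluated at a fuzzy membership w: tr(w^T S w).

    Reduces exactly to :func:`semirigid.cluster.target_q` when w is a crisp
    indicator matrix; at the uniform membership it equals
    ``(1 / n_clust) * sum_ij S_ij``.
    """
    w = validate_membership(w, s.n_atoms)
    return float(np.einsum("ik,ij,jk->", w, s.values, w))


@dataclass
class LagrangeSolution:
    """The unique stationary point of the relaxed problem.

    ``membership`` is uniform at 1/n_clust; ``multipliers`` holds the
    lambda_i enforcing the row-sum constraints.
    """

    membership: np.ndarray
    multipliers: np.ndarray


def uniform_stationary(s: STDDVMatrix, n_clust: int) -> LagrangeSolution:
    """Stationary point: c_im = 1/n_clust, lambda_i = -(2/n_clust) sum_j S_ij.

    At this point the Lagrangian gradient 2 S c_m + lambda vanishes for
    every cluster m (see :func:`stationarity_residual`).  It is a saddle /
    interior critical point, not the minimum: the minimum lies on the
    boundary of the simplex product and is crisp.
    """
    if n_clust < 1:
        raise ParameterError("n_clust must be positive")
    n = s.n_atoms
    membership = np.full((n, n_clust), 1.0 / n_clust)
    multipliers = -(2.0 / n_clust) * s.values.sum(axis=1)
    return LagrangeSolution(membership=membership, multipliers=multipliers)


def stationarity_residual(s: STDDVMatrix, sol: LagrangeSolution) -> float:
    """Max norm of the Lagrangian gradient at ``sol``.

    Checks 2 (S c_m)_i + lambda_i = 0 for all i, m and the row-sum
    constraints; exactly zero (up to round-off) at the uniform stationary
    point.
    """
    w = sol.membership
    grad = 2.0 * s.values @ w + sol.multipliers[:, None]
    constraint = w.sum(axis=1) - 1.0
    return float(max(np.abs(grad).max(), np.abs(constraint).max()))


def lagrange_system_matrix(s: STDDVMatrix, n_clust: int) -> np.ndarray:
    """Assembled block system of the stationarity conditions.

    ``n_clust`` copies of S on the block diagonal, identity blocks coupling
    each membership block to the multipliers, and a zero lower-right block;
    size N * (n_clust + 1).
    """
    if n_clust < 1:
        raise ParameterError("n_clust must be positive")
    n = s.n_atoms
    size = n * (n_clust + 1)
    m = np.zeros((size, size))
    eye = np.eye(n)
    for b in range(n_clust):
        sl = slice(b * n, (b + 1) * n)
        m[sl, sl] = s.values
        m[sl, n_clust * n:] = eye
        m[n_clust * n:, sl] = eye
    return m


def lagrange_system_det(
    s: STDDVMatrix, n_clust: int, size_cap: int = 2000
) -> float:
    """Determinant of the assembled block system.

    Equals ``(-n_clust)**N * det(S)**(n_clust - 1)`` (see module notes; the
    naive scalar-block reduction ``-n_clust * det(S)**(n_clust - 1)`` only
    matches at N = 1).  Nonzero exactly when det(S) != 0, which makes the
    uniform stationary point the unique interior critical point.
    """
    if s.n_atoms * (n_clust + 1) > size_cap:
        raise ParameterError(
            f"system size {s.n_atoms * (n_clust + 1)} exceeds cap {size_cap}"
        )
    return float(np.linalg.det(lagrange_system_matrix(s, n_clust)))


def lagrange_det_closed_form(s: STDDVMatrix, n_clust: int) -> float:
    """Closed form (-n_clust)**N * det(S)**(n_clust - 1)."""
    det_s = float(np.linalg.det(s.values))
    return float((-float(n_clust)) ** s.n_atoms * det_s ** (n_clust - 1))


@dataclass
class LemmaProbeReport:
    """Outcome of a Monte Carlo probe of the fuzzy solution space."""

    n_samples: int
    n_clust: int
    ground_q: float
    ground_state: ClusterAssignment
    min_fuzzy_q: float
    max_fuzzy_q: float
    n_violations: int
    witness: Optional[np.ndarray]

    def to_dict(self) -> dict:
        return {
            "n_samples": self.n_samples,
            "n_clust": self.n_clust,
            "ground_q": self.ground_q,
            "min_fuzzy_q": self.min_fuzzy_q,
            "max_fuzzy_q": self.max_fuzzy_q,
            "n_violations": self.n_violations,
        }


def lemma_probe(
    s: STDDVMatrix,
    n_clust: int,
    n_samples: int,
    seed: int,
    batch: int = 4096,
) -> LemmaProbeReport:
    """Sample fuzzy memberships and count any falling below the crisp optimum.

    Memberships are drawn row-wise from a symmetric Dirichlet(1), i.e.
    uniformly on each atom's simplex.  The crisp ground state is obtained
    by exhaustive enumeration, so a sample with q strictly below it (beyond
    a 1e-12 round-off guard) would be a genuine counterexample to the
    crispness lemma; the expected violation count is zero.
    """
    if n_samples < 1:
        raise ParameterError("n_samples must be positive")
    ground = brute_force_ground_state(s, n_clust)
    ground_q = target_q(s, ground)
    rng = np.random.default_rng(seed)
    min_q = np.inf
    max_q = -np.inf
    violations = 0
    witness = None
    remaining = n_samples
    while remaining > 0:
        b = min(batch, remaining)
        remaining -= b
        w = rng.gamma(1.0, size=(b, s.n_atoms, n_clust))
        w /= w.sum(axis=2, keepdims=True)
        qs = np.einsum("bik,ij,bjk->b", w, s.values, w)
        min_q = min(min_q, float(qs.min()))
        max_q = max(max_q, float(qs.max()))
        bad = qs < ground_q - 1e-12
        if bad.any():
            violations += int(bad.sum())
            if witness is None:
                witness = w[np.argmax(bad)].copy()
    return LemmaProbeReport(
        n_samples=n_samples,
        n_clust=n_clust,
        ground_q=ground_q,
        ground_state=ground,
        min_fuzzy_q=min_q,
        max_fuzzy_q=max_q,
        n_violations=violations,
        witness=witness,
    )
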