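"""Crisp domain decomposition by minimizing the within-cluster STDDV.

Given an STDDV matrix S and a preselected cluster count K, the method
minimizes the target function

    q(c) = sum_m sum_i sum_j c_im c_jm S_ij = tr(c^T S c)

over crisp memberships c_im in {0, 1} with one cluster per atom.  q sums
S_ij over all *ordered* pairs sharing a cluster (each unordered pair counts
twice); per-pair averages reported by :func:`within_between_table` divide by
unordered-pair counts, so users reconciling the two should expect a factor
of 2.

The crispness lemma (see :mod:`semirigid.theory`) guarantees that relaxing
the memberships to the fuzzy simplex cannot lower the optimum, so the search
may be restricted to the finite space of label vectors.  The optimizer is a
two-stage Monte Carlo search: random single-atom moves accepted on strict
improvement, followed by an exhaustive pass over all single-atom moves until
none improves — the result is a "minimum constellation" that no single move
can better.  Multiple restarts from random assignments are taken and the
lowest-q result (the ground state over the restarts) is returned.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .exceptions import DimensionMismatchError, ParameterError, SemirigidError
from .matrix import STDDVMatrix

#: Moves must lower q by more than this to be accepted.  Strict decrease
#: guarantees termination; the epsilon keeps round-off in the incremental
#: bookkeeping from turning an equal-q move into an accepted one (which
#: could cycle).
STRICT_DECREASE_EPS = 1e-12


@dataclass
class SearchConfig:
    """Monte Carlo search parameters.

    ``move_probability`` (P) and ``iterations`` (K) default to 1/N and
    N * n_clust respectively when left as ``None`` — rudimentary
    benchmarking shows these are reasonable; ``restarts`` defaults to 100
    independent attempts.  Each restart r draws its randomness from an
    independent stream seeded with ``seed + r``.
    """

    move_probability: Optional[float] = None
    iterations: Optional[int] = None
    restarts: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.move_probability is not None and not (
            0.0 < self.move_probability <= 1.0
        ):
            raise ParameterError("move_probability must be in (0, 1]")
        if self.iterations is not None and self.iterations < 1:
            raise ParameterError("iterations must be positive")
        if self.restarts < 1:
            raise ParameterError("restarts must be positive")

    def resolved(self, n_atoms: int, n_clust: int) -> tuple[float, int]:
        """Concrete (P, K) for a given problem size."""
        p = self.move_probability if self.move_probability is not None else 1.0 / n_atoms
        k = self.iterations if self.iterations is not None else n_atoms * n_clust
        return p, k


@dataclass
class ClusterAssignment:
    """Crisp atom-to-cluster labeling.

    ``labels`` holds one integer in ``0..n_clust-1`` per atom (0-based, as
    in scikit-learn; files written by :mod:`semirigid.io` use 1-based labels
    per PDB convention).  Clusters may be empty: the optimizer is free to
    use fewer than ``n_clust`` effective clusters.  ``q`` is the achieved
    target-function value when produced by an optimizer.
    """

    labels: np.ndarray
    n_clust: int
    q: Optional[float] = field(default=None, compare=False)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.ndim != 1 or self.labels.size < 1:
            raise SemirigidError("labels must be a non-empty 1-D array")
        if self.n_clust < 1:
            raise ParameterError("n_clust must be positive")
        if self.labels.min() < 0 or self.labels.max() >= self.n_clust:
            raise SemirigidError(
                f"labels must lie in 0..{self.n_clust - 1}"
            )

    @property
    def n_atoms(self) -> int:
        return self.labels.size

    @property
    def sizes(self) -> np.ndarray:
        """Atom count per cluster (length ``n_clust``; empty clusters are 0)."""
        return np.bincount(self.labels, minlength=self.n_clust)

    def membership_matrix(self) -> np.ndarray:
        """Crisp indicator matrix c of shape ``(n_atoms, n_clust)``."""
        c = np.zeros((self.n_atoms, self.n_clust))
        c[np.arange(self.n_atoms), self.labels] = 1.0
        return c


def _check_dims(s: STDDVMatrix, c: ClusterAssignment) -> None:
    if c.n_atoms != s.n_atoms:
        raise DimensionMismatchError(
            f"assignment covers {c.n_atoms} atoms, matrix has {s.n_atoms}"
        )


def target_q(s: STDDVMatrix, c: ClusterAssignment) -> float:
    """Target function q(c) = tr(c^T S c), over ordered within-cluster pairs."""
    _check_dims(s, c)
    q = 0.0
    for m in range(c.n_clust):
        idx = np.flatnonzero(c.labels == m)
        if idx.size > 1:
            q += s.values[np.ix_(idx, idx)].sum()
    return float(q)


def _cluster_sums(s_values: np.ndarray, labels: np.ndarray, n_clust: int) -> np.ndarray:
    """T[i, m] = sum of S_ij over atoms j currently in cluster m."""
    t = np.zeros((labels.size, n_clust))
    for m in range(n_clust):
        idx = np.flatnonzero(labels == m)
        if idx.size:
            t[:, m] = s_values[:, idx].sum(axis=1)
    return t


def move_delta_q(s: STDDVMatrix, c: ClusterAssignment, atom: int, target: int) -> float:
    """Exact change in q for moving ``atom`` to cluster ``target``.

    Moving atom i from cluster a to b changes q by
    ``2 * (sum_{j in b} S_ij - sum_{j in a, j != i} S_ij)`` — the identity
    the incremental search relies on.
    """
    _check_dims(s, c)
    a = c.labels[atom]
    if target == a:
        return 0.0
    in_a = np.flatnonzero(c.labels == a)
    in_b = np.flatnonzero(c.labels == target)
    return float(
        2.0 * (s.values[atom, in_b].sum() - s.values[atom, in_a].sum())
    )  # S[atom, atom] = 0, so no j != i correction needed


def random_search(
    s: STDDVMatrix,
    c0: ClusterAssignment,
    cfg: SearchConfig,
    rng: np.random.Generator,
    trace: Optional[list] = None,
) -> ClusterAssignment:
    """Stage one: K sweeps of random single-atom moves, kept on strict decrease.

    In each sweep every atom is, with probability P, proposed to a uniformly
    random *other* cluster; the proposal is accepted iff it strictly lowers
    q.  Equal-q moves are rejected, which guarantees a non-increasing q
    trace.
    """
    _check_dims(s, c0)
    k_clust = c0.n_clust
    labels = c0.labels.copy()
    if k_clust == 1:
        return ClusterAssignment(labels, k_clust, q=target_q(s, c0))
    p, sweeps = cfg.resolved(c0.n_atoms, k_clust)
    sv = s.values
    t = _cluster_sums(sv, labels, k_clust)
    q = float(t[np.arange(labels.size), labels].sum())
    for _ in range(sweeps):
        movers = np.flatnonzero(rng.random(labels.size) < p)
        for i in movers:
            a = labels[i]
            b = int(rng.integers(k_clust - 1))
            if b >= a:
                b += 1
            dq = 2.0 * (t[i, b] - t[i, a])
            if dq < -STRICT_DECREASE_EPS:
                labels[i] = b
                t[:, a] -= sv[:, i]
                t[:, b] += sv[:, i]
                q += dq
                if trace is not None:
                    trace.append(q)
    return ClusterAssignment(labels, k_clust, q=target_q(s, ClusterAssignment(labels, k_clust)))


def exhaustive_local_search(
    s: STDDVMatrix, c: ClusterAssignment, trace: Optional[list] = None
) -> ClusterAssignment:
    """Stage two: repeated passes over all single-atom moves until none improves.

    The result is a minimum constellation: no move of a single atom to any
    other cluster strictly decreases q.  Termination is guaranteed because
    only strictly decreasing moves are taken over a finite state space.
    """
    _check_dims(s, c)
    k_clust = c.n_clust
    labels = c.labels.copy()
    if k_clust == 1:
        return ClusterAssignment(labels, k_clust, q=target_q(s, c))
    sv = s.values
    t = _cluster_sums(sv, labels, k_clust)
    q = float(t[np.arange(labels.size), labels].sum())
    improved = True
    while improved:
        improved = False
        for i in range(labels.size):
            a = labels[i]
            deltas = t[i] - t[i, a]
            b = int(np.argmin(deltas))
            if 2.0 * deltas[b] < -STRICT_DECREASE_EPS:
                labels[i] = b
                t[:, a] -= sv[:, i]
                t[:, b] += sv[:, i]
                q += 2.0 * deltas[b]
                improved = True
                if trace is not None:
                    trace.append(q)
    return ClusterAssignment(labels, k_clust, q=target_q(s, ClusterAssignment(labels, k_clust)))


def is_local_minimum(s: STDDVMatrix, c: ClusterAssignment) -> bool:
    """Certify (by full recomputation) that no single-atom move lowers q."""
    base = target_q(s, c)
    for i in range(c.n_atoms):
        for m in range(c.n_clust):
            if m == c.labels[i]:
                continue
            trial = c.labels.copy()
            trial[i] = m
            if target_q(s, ClusterAssignment(trial, c.n_clust)) < base - STRICT_DECREASE_EPS:
                return False
    return True


def mc_cluster(
    s: STDDVMatrix, n_clust: int, cfg: Optional[SearchConfig] = None
) -> ClusterAssignment:
    """Two-stage Monte Carlo clustering with independent restarts.

    Each restart assigns every atom to a uniformly random cluster, runs
    :func:`random_search` then :func:`exhaustive_local_search`, and the
    lowest-q minimum constellation over all restarts is returned (first
    found wins ties, so a fixed seed yields a fixed result).  The result is
    canonicalized by :func:`relabel_by_size`.
    """
    if cfg is None:
        cfg = SearchConfig()
    if not (1 <= n_clust <= s.n_atoms):
        raise ParameterError(
            f"n_clust must be in 1..{s.n_atoms}, got {n_clust}"
        )
    best: Optional[ClusterAssignment] = None
    for r in range(cfg.restarts):
        rng = np.random.default_rng(cfg.seed + r)
        start = ClusterAssignment(rng.integers(0, n_clust, s.n_atoms), n_clust)
        trial = exhaustive_local_search(s, random_search(s, start, cfg, rng))
        if best is None or trial.q < best.q:
            best = trial
    assert best is not None
    if np.any(best.sizes == 0):
        warnings.warn(
            f"optimizer left {int(np.sum(best.sizes == 0))} of {n_clust} "
            "clusters empty",
            stacklevel=2,
        )
    return relabel_by_size(best)


def brute_force_ground_state(
    s: STDDVMatrix, n_clust: int, cap: int = 10**7
) -> ClusterAssignment:
    """Global minimizer of q by exhaustive enumeration of label vectors.

    Serves as the independent oracle for the stochastic optimizer on small
    instances.  Refuses when ``n_clust ** n_atoms`` exceeds ``cap``.  Among
    equally optimal label vectors the lexicographically smallest is taken
    before canonicalization.
    """
    if not (1 <= n_clust <= s.n_atoms):
        raise ParameterError(f"n_clust must be in 1..{s.n_atoms}, got {n_clust}")
    n = s.n_atoms
    total = n_clust**n
    if total > cap:
        raise ParameterError(
            f"enumeration of {total} assignments exceeds cap {cap}"
        )
    best_q = np.inf
    best_labels = None
    chunk = 4096
    shape = (n_clust,) * n
    for start in range(0, total, chunk):
        idx = np.arange(start, min(start + chunk, total))
        labels = np.stack(np.unravel_index(idx, shape), axis=1)
        same = labels[:, :, None] == labels[:, None, :]
        qs = (same * s.values).sum(axis=(1, 2))
        j = int(np.argmin(qs))
        if qs[j] < best_q:
            best_q = float(qs[j])
            best_labels = labels[j]
    return relabel_by_size(
        ClusterAssignment(best_labels, n_clust, q=best_q)
    )


def relabel_by_size(c: ClusterAssignment) -> ClusterAssignment:
    """Canonical label order: largest cluster first.

    Clusters are renumbered by decreasing atom count; among equal sizes the
    cluster containing the smallest atom index gets the smaller label, so
    the canonical form is deterministic.  q is unchanged.
    """
    sizes = c.sizes
    first_atom = np.full(c.n_clust, c.n_atoms)
    for m in range(c.n_clust):
        idx = np.flatnonzero(c.labels == m)
        if idx.size:
            first_atom[m] = idx[0]
    order = sorted(range(c.n_clust), key=lambda m: (-sizes[m], first_atom[m], m))
    mapping = np.empty(c.n_clust, dtype=int)
    for new, old in enumerate(order):
        mapping[old] = new
    return ClusterAssignment(mapping[c.labels], c.n_clust, q=c.q)


def within_between_table(s: STDDVMatrix, c: ClusterAssignment) -> np.ndarray:
    """Mean STDDV within (diagonal) and between (off-diagonal) clusters [nm].

    Entry (m, m) averages S_ij over unordered pairs inside cluster m; entry
    (m, m') averages over all cross pairs.  Entries involving singleton or
    empty clusters are NaN (no pair to average).
    """
    _check_dims(s, c)
    k = c.n_clust
    table = np.full((k, k), np.nan)
    members = [np.flatnonzero(c.labels == m) for m in range(k)]
    for m in range(k):
        im = members[m]
        if im.size > 1:
            table[m, m] = s.values[np.ix_(im, im)].sum() / (im.size * (im.size - 1))
        for mp in range(m + 1, k):
            imp = members[mp]
            if im.size and imp.size:
                val = s.values[np.ix_(im, imp)].sum() / (im.size * imp.size)
                table[m, mp] = table[mp, m] = val
    return table


@dataclass
class ClusterSummary:
    """Normalized per-cluster metrics plus the captured-STDDV fraction.

    ``per_cluster`` has one row per cluster with
    ``size``, ``normalized_size`` (= size * n_clust / N, so 1 means the
    cluster exactly matches the average size N / n_clust),
    ``within_mean`` (mean within-cluster STDDV, NaN for singletons) and
    ``normalized_within`` (= within_mean * n_clust, comparable across
    different cluster counts).  ``captured_fraction`` is q(c) relative to
    the single-cluster case, i.e. the fraction of the total pair
    variability still retained inside clusters.
    """

    per_cluster: pd.DataFrame
    captured_fraction: float


def normalized_summary(s: STDDVMatrix, c: ClusterAssignment) -> ClusterSummary:
    """Per-cluster normalized sizes / within-STDDVs and captured fraction."""
    _check_dims(s, c)
    k = c.n_clust
    table = within_between_table(s, c)
    sizes = c.sizes
    records = pd.DataFrame(
        {
            "cluster": np.arange(k),
            "size": sizes,
            "normalized_size": sizes * k / c.n_atoms,
            "within_mean": np.diag(table),
            "normalized_within": np.diag(table) * k,
        }
    )
    total = s.values.sum()  # q of the single-cluster assignment
    q = target_q(s, c)
    captured = q / total if total > 0 else float("nan")
    return ClusterSummary(per_cluster=records, captured_fraction=float(captured))


def enumerate_assignments(n_atoms: int, n_clust: int):
    """Iterate over all label vectors (testing helper)."""
    return itertools.product(range(n_clust), repeat=n_atoms)


__all__ = [
    "SearchConfig",
    "ClusterAssignment",
    "ClusterSummary",
    "target_q",
    "move_delta_q",
    "random_search",
    "exhaustive_local_search",
    "is_local_minimum",
    "mc_cluster",
    "brute_force_ground_state",
    "relabel_by_size",
    "within_between_table",
    "normalized_summary",
]
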