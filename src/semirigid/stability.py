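"""Cluster stability across sub-trajectory windows.

Clustering different stretches of an MD trajectory gives different domain
decompositions; this module quantifies how different.  The trajectory is
split into contiguous windows, each window is clustered independently, and
the window labelings are made comparable by permuting each one's cluster
labels to minimize the number of atoms that disagree with the *first*
window's clustering (the minimum-migration permutation).  On the aligned
series one can then count migrations between consecutive windows, estimate
per-atom membership probabilities p_im (the fraction of windows in which
atom i carries label m), and condense them into a per-atom Kullback-Leibler
distance from the uniform background 1/N_clust:

    KLD_i = sum_m p_im * log( p_im / (1/N_clust) ),

which ranges from 0 (atom hops randomly between clusters) to
log(N_clust) (atom never leaves one cluster).  Atoms that (almost) never
change clusters form the "stiff kernel" — the trustworthy core of the
domain decomposition.  A two-segment linear trend on per-window mean STDDV
flags a non-equilibrated initial phase of the simulation.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import NamedTuple, Optional, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from .cluster import ClusterAssignment, SearchConfig, mc_cluster, relabel_by_size
from .exceptions import DimensionMismatchError, ParameterError, SemirigidError
from .matrix import STDDVMatrix, compute_stddv
from .trajectory import Trajectory


def split_windows(frame_count: int, n_windows: int) -> list[tuple[int, int]]:
    """Contiguous half-open frame ranges of near-equal length.

    Covers all frames; lengths differ by at most one, the remainder going
    to the earliest windows (e.g. 10 frames in 3 windows -> 4, 3, 3).
    """
    if n_windows < 1:
        raise ParameterError("n_windows must be positive")
    if frame_count < 2 * n_windows:
        raise ParameterError(
            f"{frame_count} frames are too few for {n_windows} windows "
            "(need at least 2 per window)"
        )
    base, rem = divmod(frame_count, n_windows)
    ranges = []
    start = 0
    for w in range(n_windows):
        length = base + (1 if w < rem else 0)
        ranges.append((start, start + length))
        start += length
    return ranges


@dataclass
class Window:
    """One sub-trajectory window: frame range, its STDDV matrix, assignment."""

    frame_range: tuple[int, int]
    matrix: STDDVMatrix
    assignment: ClusterAssignment


@dataclass
class WindowSeries:
    """Per-window clusterings, label-aligned to the first window."""

    windows: list[Window]
    n_clust: int

    def __post_init__(self) -> None:
        if not self.windows:
            raise SemirigidError("a WindowSeries needs at least one window")
        n = self.windows[0].assignment.n_atoms
        for w in self.windows:
            if w.assignment.n_atoms != n or w.assignment.n_clust != self.n_clust:
                raise DimensionMismatchError(
                    "all windows must share n_atoms and n_clust"
                )

    @property
    def n_windows(self) -> int:
        return len(self.windows)

    @property
    def n_atoms(self) -> int:
        return self.windows[0].assignment.n_atoms

    def labels_matrix(self) -> np.ndarray:
        """Aligned labels as an ``(n_windows, n_atoms)`` array."""
        return np.stack([w.assignment.labels for w in self.windows])


# -- label alignment --------------------------------------------------------

def _contingency(reference: np.ndarray, candidate: np.ndarray, k: int) -> np.ndarray:
    """C[r, c] = number of atoms with reference label r and candidate label c."""
    c = np.zeros((k, k), dtype=int)
    np.add.at(c, (reference, candidate), 1)
    return c


def _optimal_agreement(table: np.ndarray, fixed: dict[int, int]) -> int:
    """Best achievable agreement sum_c C[perm[c], c] with some entries fixed."""
    k = table.shape[0]
    free_cols = [c for c in range(k) if c not in fixed]
    used = set(fixed.values())
    free_rows = [r for r in range(k) if r not in used]
    total = sum(table[r, c] for c, r in fixed.items())
    if free_cols:
        sub = table[np.ix_(free_rows, free_cols)]
        ri, ci = linear_sum_assignment(-sub)
        total += int(sub[ri, ci].sum())
    return int(total)


def best_label_permutation(
    reference: ClusterAssignment, candidate: ClusterAssignment
) -> np.ndarray:
    """Permutation ``perm`` minimizing migrations of ``perm[candidate]`` vs reference.

    Solved as a linear assignment on the label-agreement (contingency)
    table: minimizing the number of disagreeing atoms is the same as
    maximizing the trace of the permuted table.  Among equally good
    permutations the lexicographically smallest is returned, so alignment
    is deterministic.
    """
    if reference.n_atoms != candidate.n_atoms:
        raise DimensionMismatchError("assignments cover different atom counts")
    if reference.n_clust != candidate.n_clust:
        raise DimensionMismatchError("assignments have different n_clust")
    k = reference.n_clust
    table = _contingency(reference.labels, candidate.labels, k)
    best = _optimal_agreement(table, {})
    fixed: dict[int, int] = {}
    for c in range(k):
        for r in range(k):
            if r in fixed.values():
                continue
            trial = dict(fixed)
            trial[c] = r
            if _optimal_agreement(table, trial) == best:
                fixed[c] = r
                break
    perm = np.array([fixed[c] for c in range(k)], dtype=int)
    return perm


def align_labels(
    reference: ClusterAssignment, candidate: ClusterAssignment
) -> ClusterAssignment:
    """Relabel ``candidate`` to agree maximally with ``reference``.

    Pure relabeling: cluster contents and q are unchanged, only the label
    numbers move.
    """
    perm = best_label_permutation(reference, candidate)
    return ClusterAssignment(perm[candidate.labels], candidate.n_clust, q=candidate.q)


def count_migrations(a: ClusterAssignment, b: ClusterAssignment) -> int:
    """Number of atoms whose label differs between two (aligned) assignments."""
    if a.n_atoms != b.n_atoms:
        raise DimensionMismatchError("assignments cover different atom counts")
    return int(np.sum(a.labels != b.labels))


def exhaustive_best_permutation(
    reference: ClusterAssignment, candidate: ClusterAssignment
) -> np.ndarray:
    """Brute-force minimum-migration permutation (oracle; n_clust <= 8).

    Enumerates all label permutations in lexicographic order and keeps the
    first one attaining the minimum migration count; used to certify
    :func:`best_label_permutation`.
    """
    k = reference.n_clust
    if k > 8:
        raise ParameterError("exhaustive permutation search limited to n_clust <= 8")
    best_perm = None
    best_count = None
    for perm in itertools.permutations(range(k)):
        p = np.array(perm)
        cnt = int(np.sum(p[candidate.labels] != reference.labels))
        if best_count is None or cnt < best_count:
            best_count = cnt
            best_perm = p
    return best_perm


# -- windowed clustering ----------------------------------------------------

def cluster_windows(
    traj: Trajectory,
    n_clust: int,
    n_windows: int,
    cfg: Optional[SearchConfig] = None,
    selection=None,
) -> WindowSeries:
    """Cluster each window of a trajectory and align labels to the first.

    Each window's STDDV matrix is computed from that window's frames only;
    the first window's assignment is canonicalized by size (largest cluster
    = label 0) and every later window is aligned to it by the
    minimum-migration permutation.  Every window searches with the same
    master seed, so identical window matrices yield identical clusterings
    and the whole series is reproducible.
    """
    if cfg is None:
        cfg = SearchConfig()
    sub = traj.select(selection)
    ranges = split_windows(sub.n_frames, n_windows)
    windows: list[Window] = []
    reference: Optional[ClusterAssignment] = None
    for start, stop in ranges:
        s = compute_stddv(sub.slice_frames(start, stop), selection=None)
        assign = mc_cluster(s, n_clust, cfg)
        if reference is None:
            assign = relabel_by_size(assign)
            reference = assign
        else:
            assign = align_labels(reference, assign)
        windows.append(Window((start, stop), s, assign))
    return WindowSeries(windows=windows, n_clust=n_clust)


# -- stability metrics ------------------------------------------------------

def migration_series(series: WindowSeries) -> np.ndarray:
    """Migrations between consecutive aligned windows (length n_windows - 1)."""
    if series.n_windows < 2:
        raise ParameterError("migration series needs at least 2 windows")
    labels = series.labels_matrix()
    return (labels[1:] != labels[:-1]).sum(axis=1)


def net_migrations(series: WindowSeries) -> int:
    """Atoms whose aligned label differs between the first and last window.

    Consecutive migrations can be large yet almost reversible — atoms
    wander off and return; a small net count against window 1 is the
    signature of that reversibility.
    """
    labels = series.labels_matrix()
    return int(np.sum(labels[0] != labels[-1]))


def membership_probabilities(series: WindowSeries) -> np.ndarray:
    """p_im: fraction of windows in which atom i carries aligned label m."""
    labels = series.labels_matrix()
    n_w, n = labels.shape
    p = np.zeros((n, series.n_clust))
    for m in range(series.n_clust):
        p[:, m] = (labels == m).sum(axis=0)
    return p / n_w


def kld_profile(
    p: np.ndarray, n_clust: int, log_base: float = 10.0
) -> np.ndarray:
    """Per-atom Kullback-Leibler distance from the uniform background.

    ``KLD_i = sum_m p_im * log_base(p_im / (1/n_clust))`` with the
    convention 0 * log 0 = 0.  Bounded by [0, log_base(n_clust)]; 0 at a
    uniform row (random hopping), the maximum at an indicator row (atom
    pinned to one cluster).  Base 10 by default; pass ``np.e`` for nats.
    """
    if log_base <= 1.0:
        raise ParameterError("log_base must exceed 1")
    p = np.asarray(p, dtype=float)
    if p.ndim != 2 or p.shape[1] != n_clust:
        raise DimensionMismatchError(
            f"probability matrix must have {n_clust} columns, got {p.shape}"
        )
    if p.min() < 0 or np.abs(p.sum(axis=1) - 1.0).max() > 1e-8:
        raise SemirigidError("probability rows must be nonnegative and sum to 1")
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log(p * n_clust), 0.0)
    return terms.sum(axis=1) / np.log(log_base)


@dataclass
class StabilityProfile:
    """Membership probabilities and KLD profile for a window series."""

    probabilities: np.ndarray
    kld: np.ndarray
    log_base: float


def stability_profile(series: WindowSeries, log_base: float = 10.0) -> StabilityProfile:
    p = membership_probabilities(series)
    return StabilityProfile(
        probabilities=p,
        kld=kld_profile(p, series.n_clust, log_base),
        log_base=log_base,
    )


def label_change_counts(series: WindowSeries) -> np.ndarray:
    """Per-atom number of label changes between consecutive windows."""
    if series.n_windows < 2:
        raise ParameterError("change counts need at least 2 windows")
    labels = series.labels_matrix()
    return (labels[1:] != labels[:-1]).sum(axis=0)


def stiff_kernel(series: WindowSeries, max_changes: int = 0) -> np.ndarray:
    """Atoms changing cluster at most ``max_changes`` times across windows.

    With the default ``max_changes = 0`` these are the atoms that never
    migrate — the stiff kernel on which the decomposition can be trusted.
    """
    return np.flatnonzero(label_change_counts(series) <= max_changes)


class LineFit(NamedTuple):
    slope: float
    intercept: float


def two_segment_trend(
    values: Sequence[float],
    split_fraction: float = 0.5,
    overlap_fraction: float = 0.1,
) -> tuple[LineFit, LineFit]:
    """Two overlapping straight-line fits through a per-window series.

    Ordinary least squares over the first ``split + overlap`` span and the
    last ``(1 - split) + overlap`` span of the series (x = window index).
    A clearly negative first slope with a near-zero second slope flags a
    non-equilibrated initial phase of the simulation, suggesting the early
    windows be discarded (the common remedy: keep the second half).
    """
    y = np.asarray(values, dtype=float)
    n = y.size
    if n < 4:
        raise ParameterError("trend fit needs at least 4 points")
    if not (0.0 < split_fraction < 1.0) or overlap_fraction < 0.0:
        raise ParameterError("invalid split/overlap fractions")
    x = np.arange(n, dtype=float)
    first_stop = min(n, max(2, int(round(n * (split_fraction + overlap_fraction)))))
    second_start = max(0, min(n - 2, int(round(n * (split_fraction - overlap_fraction)))))
    s1, i1 = np.polyfit(x[:first_stop], y[:first_stop], 1)
    s2, i2 = np.polyfit(x[second_start:], y[second_start:], 1)
    return LineFit(float(s1), float(i1)), LineFit(float(s2), float(i2))
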