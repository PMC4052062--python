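import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from semirigid import (
    ClusterAssignment,
    DomainSpec,
    SearchConfig,
    STDDVMatrix,
    Window,
    WindowSeries,
    align_labels,
    best_label_permutation,
    cluster_windows,
    count_migrations,
    generate_domain_trajectory,
    kld_profile,
    label_change_counts,
    membership_probabilities,
    migration_series,
    net_migrations,
    split_windows,
    stability_profile,
    stiff_kernel,
    two_segment_trend,
)
from semirigid.stability import exhaustive_best_permutation
from semirigid.exceptions import ParameterError, SemirigidError


def make_series(label_rows, n_clust):
    """WindowSeries from bare label vectors (matrices are placeholders)."""
    n = len(label_rows[0])
    dummy = STDDVMatrix(np.zeros((n, n)))
    windows = [
        Window((i, i + 1), dummy, ClusterAssignment(row, n_clust))
        for i, row in enumerate(label_rows)
    ]
    return WindowSeries(windows, n_clust)


class TestSplitWindows:
    def test_even_split(self):
        ranges = split_windows(5000, 50)
        assert len(ranges) == 50
        assert all(stop - start == 100 for start, stop in ranges)
        assert ranges[0] == (0, 100) and ranges[-1] == (4900, 5000)

    def test_single_window(self):
        assert split_windows(10, 1) == [(0, 10)]

    def test_remainder_to_earliest(self):
        ranges = split_windows(10, 3)
        assert [stop - start for start, stop in ranges] == [4, 3, 3]

    def test_contiguous_cover(self):
        ranges = split_windows(103, 7)
        assert ranges[0][0] == 0 and ranges[-1][1] == 103
        assert all(a[1] == b[0] for a, b in zip(ranges, ranges[1:]))

    def test_too_few_frames(self):
        with pytest.raises(ParameterError):
            split_windows(5, 3)


class TestAlignLabels:
    def test_pure_relabeling_gives_zero_migrations(self):
        ref = ClusterAssignment([0, 0, 1, 1], 2)
        cand = ClusterAssignment([1, 1, 0, 0], 2)
        aligned = align_labels(ref, cand)
        assert np.array_equal(aligned.labels, ref.labels)
        assert count_migrations(ref, aligned) == 0

    def test_best_permutation_leaves_two_migrations(self):
        ref = ClusterAssignment([0, 0, 1, 1], 2)
        cand = ClusterAssignment([0, 1, 1, 0], 2)
        aligned = align_labels(ref, cand)
        assert count_migrations(ref, aligned) == 2

    def test_identity_on_identical_assignments(self):
        ref = ClusterAssignment([0, 1, 2, 0], 3)
        aligned = align_labels(ref, ref)
        assert np.array_equal(aligned.labels, ref.labels)

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(seed=st.integers(0, 100_000), k=st.integers(2, 6))
    def test_matches_exhaustive_permutation_oracle(self, seed, k):
        rng = np.random.default_rng(seed)
        n = 12
        ref = ClusterAssignment(rng.integers(0, k, n), k)
        cand = ClusterAssignment(rng.integers(0, k, n), k)
        perm = best_label_permutation(ref, cand)
        oracle = exhaustive_best_permutation(ref, cand)
        assert np.array_equal(perm, oracle)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(seed=st.integers(0, 100_000))
    def test_min_migrations_equals_max_contingency_trace(self, seed):
        rng = np.random.default_rng(seed)
        k, n = 4, 15
        ref = ClusterAssignment(rng.integers(0, k, n), k)
        cand = ClusterAssignment(rng.integers(0, k, n), k)
        perm = best_label_permutation(ref, cand)
        table = np.zeros((k, k), dtype=int)
        np.add.at(table, (ref.labels, cand.labels), 1)
        agreement = sum(table[perm[c], c] for c in range(k))
        assert n - agreement == count_migrations(ref, align_labels(ref, cand))

    def test_dimension_mismatch(self):
        with pytest.raises(SemirigidError):
            align_labels(ClusterAssignment([0, 1], 2), ClusterAssignment([0, 1, 0], 2))


class TestMigrationSeries:
    def test_identical_windows_give_zeros(self):
        series = make_series([[0, 0, 1, 1]] * 4, 2)
        assert np.array_equal(migration_series(series), [0, 0, 0])

    def test_single_flip(self):
        series = make_series([[0, 0, 1], [0, 0, 1], [0, 1, 1]], 2)
        assert np.array_equal(migration_series(series), [0, 1])

    def test_reversible_excursion_has_zero_net_migration(self):
        # middle windows wander, the last returns to the first clustering
        base = [0, 0, 0, 1, 1, 1]
        excursion = [0, 0, 1, 1, 0, 1]
        series = make_series([base, excursion, excursion, base], 2)
        migr = migration_series(series)
        assert migr[0] > 0 and migr[-1] > 0
        assert net_migrations(series) == 0

    def test_single_window_errors(self):
        with pytest.raises(ParameterError):
            migration_series(make_series([[0, 1]], 2))


class TestMembershipProbabilities:
    def test_constant_atom_gets_indicator_row(self):
        series = make_series([[2, 0, 1]] * 5, 3)
        p = membership_probabilities(series)
        assert np.array_equal(p[0], [0, 0, 1])

    def test_half_half_split(self):
        rows = [[0, 0]] * 3 + [[1, 0]] * 3
        p = membership_probabilities(make_series(rows, 2))
        assert np.allclose(p[0], [0.5, 0.5])
        assert np.allclose(p.sum(axis=1), 1.0)

    def test_column_sums_count_average_cluster_sizes(self):
        rng = np.random.default_rng(0)
        rows = [rng.integers(0, 3, 10).tolist() for _ in range(6)]
        series = make_series(rows, 3)
        p = membership_probabilities(series)
        avg_sizes = np.mean([np.bincount(r, minlength=3) for r in rows], axis=0)
        assert np.allclose(p.sum(axis=0), avg_sizes)


class TestKldProfile:
    def test_uniform_row_gives_zero(self):
        p = np.full((1, 5), 0.2)
        assert kld_profile(p, 5)[0] == pytest.approx(0.0, abs=1e-12)

    def test_indicator_row_attains_log_n_clust(self):
        p = np.array([[0, 0, 1, 0, 0.0]])
        assert kld_profile(p, 5)[0] == pytest.approx(np.log10(5))

    def test_half_half_row(self):
        p = np.array([[0.5, 0.5, 0, 0, 0.0]])
        assert kld_profile(p, 5)[0] == pytest.approx(0.39794, abs=1e-5)

    def test_natural_log_base(self):
        p = np.array([[0, 1.0, 0]])
        assert kld_profile(p, 3, log_base=np.e)[0] == pytest.approx(np.log(3))

    def test_rejects_bad_rows(self):
        with pytest.raises(SemirigidError):
            kld_profile(np.array([[0.5, 0.4]]), 2)

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(seed=st.integers(0, 100_000), k=st.integers(2, 6))
    def test_bounds_hold_for_random_rows(self, seed, k):
        rng = np.random.default_rng(seed)
        p = rng.dirichlet(np.ones(k), size=5)
        kld = kld_profile(p, k)
        assert np.all(kld >= -1e-12)
        assert np.all(kld <= np.log10(k) + 1e-12)


class TestStiffKernel:
    def test_all_stable_includes_everyone(self):
        series = make_series([[0, 1, 1, 0]] * 3, 2)
        assert np.array_equal(stiff_kernel(series), [0, 1, 2, 3])

    def test_flip_flopper_excluded_then_included(self):
        rows = [[0, 0], [1, 0], [0, 0]]
        series = make_series(rows, 2)
        assert np.array_equal(stiff_kernel(series, max_changes=0), [1])
        assert np.array_equal(stiff_kernel(series, max_changes=2), [0, 1])

    def test_zero_changes_matches_maximal_kld(self):
        rows = [[0, 0, 1], [0, 1, 1], [0, 0, 1], [0, 1, 1]]
        series = make_series(rows, 2)
        kernel = set(stiff_kernel(series).tolist())
        kld = kld_profile(membership_probabilities(series), 2)
        maximal = set(np.flatnonzero(np.isclose(kld, np.log10(2))).tolist())
        assert kernel == maximal


class TestTwoSegmentTrend:
    def test_constant_series(self):
        first, second = two_segment_trend([1.0] * 10)
        assert first.slope == pytest.approx(0.0, abs=1e-12)
        assert second.slope == pytest.approx(0.0, abs=1e-12)

    def test_exact_line_recovered(self):
        y = 0.4 - 0.03 * np.arange(20)
        first, second = two_segment_trend(y)
        for fit in (first, second):
            assert fit.slope == pytest.approx(-0.03, abs=1e-10)
            assert fit.intercept == pytest.approx(0.4, abs=1e-10)

    def test_decline_then_plateau(self):
        y = np.concatenate([np.linspace(1.0, 0.5, 10), np.full(10, 0.5)])
        first, second = two_segment_trend(y)
        assert first.slope < -0.01
        assert abs(second.slope) < abs(first.slope) / 3

    def test_too_few_points(self):
        with pytest.raises(ParameterError):
            two_segment_trend([1.0, 2.0, 3.0])


class TestClusterWindows:
    @pytest.fixture(scope="class")
    @staticmethod
    def stable_series():
        spec = DomainSpec(domain_sizes=(8, 8, 8), n_frames=120, seed=5)
        traj, labels = generate_domain_trajectory(spec)
        cfg = SearchConfig(restarts=10, seed=0)
        return cluster_windows(traj, 3, 4, cfg), labels

    def test_windows_recover_same_partition(self, stable_series):
        series, _ = stable_series
        assert np.array_equal(migration_series(series), [0, 0, 0])
        assert len(stiff_kernel(series)) == series.n_atoms

    def test_first_window_canonical_and_matches_truth(self, stable_series):
        series, labels = stable_series
        first = series.windows[0].assignment
        sizes = first.sizes
        assert np.all(sizes[:-1] >= sizes[1:])
        for d in range(3):
            assert len(set(first.labels[labels == d])) == 1

    def test_deterministic_under_seed(self):
        spec = DomainSpec(domain_sizes=(6, 6), n_frames=60, seed=2)
        traj, _ = generate_domain_trajectory(spec)
        cfg = SearchConfig(restarts=5, seed=9)
        a = cluster_windows(traj, 2, 3, cfg)
        b = cluster_windows(traj, 2, 3, cfg)
        assert np.array_equal(a.labels_matrix(), b.labels_matrix())

    def test_static_trajectory_all_zero_matrices(self, static_trajectory):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # empty clusters are fine here
            series = cluster_windows(
                static_trajectory, 2, 3, SearchConfig(restarts=3, seed=0)
            )
        assert all(
            np.allclose(w.matrix.values, 0.0, atol=1e-12) for w in series.windows
        )
        assert np.array_equal(migration_series(series), [0, 0])


class TestStabilityProfile:
    def test_profile_combines_probabilities_and_kld(self):
        rows = [[0, 1], [0, 1], [1, 1], [0, 1]]
        prof = stability_profile(make_series(rows, 2))
        assert prof.probabilities[1, 1] == 1.0
        assert prof.kld[1] == pytest.approx(np.log10(2))
        assert prof.kld[0] < np.log10(2)
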