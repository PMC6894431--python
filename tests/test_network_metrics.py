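import itertools
import math

import numpy as np
import pytest

from oxynet.network_metrics import (
    connectance,
    dprime_hosts,
    greedy_min_entropy,
    h2prime,
    host_degrees,
    interaction_diversity,
    network_metrics,
    wnodf,
)

from .conftest import make_matrix, random_count_matrix


class TestConnectanceAndDegree:
    def test_checkerboard_half_filled(self, checkerboard):
        assert connectance(checkerboard) == pytest.approx(0.5)

    def test_full_matrix(self):
        assert connectance(make_matrix(np.ones((3, 4), int))) == 1.0

    def test_degree_counts_positive_cells(self):
        m = make_matrix([[2, 0], [0, 0], [1, 0]])
        assert list(host_degrees(m)) == [2, 0]

    def test_mean_degree_identity(self, rng):
        # connectance == mean host degree / n_species, exactly, on any input
        for _ in range(25):
            m = random_count_matrix(rng)
            assert host_degrees(m).mean() / m.n_species == pytest.approx(
                connectance(m), abs=1e-12
            )

    def test_empty_matrix_errors(self):
        with pytest.raises(ValueError):
            connectance(make_matrix(np.zeros((2, 2), int)))


class TestInteractionDiversity:
    def test_single_link_has_no_diversity(self):
        assert interaction_diversity(make_matrix([[5]])) == 0.0

    def test_equal_shares(self):
        m = make_matrix([[1, 1], [1, 1]])
        assert interaction_diversity(m) == pytest.approx(math.log(4))

    def test_bounded_by_log_links(self, rng):
        for _ in range(10):
            m = random_count_matrix(rng)
            n_links = (m.counts > 0).sum()
            assert interaction_diversity(m) <= math.log(n_links) + 1e-12

    def test_log2_switch(self):
        m = make_matrix([[1, 1], [1, 1]])
        assert interaction_diversity(m, base=2) == pytest.approx(2.0)


class TestWnodf:
    def test_perfectly_nested_scores_100(self, nested_matrix):
        assert wnodf(nested_matrix) == pytest.approx(100.0)

    def test_checkerboard_scores_0(self, checkerboard):
        assert wnodf(checkerboard) == 0.0

    def test_tied_marginals_score_zero(self):
        # decreasing-fill condition: equal totals contribute nothing
        m = make_matrix([[2, 1], [1, 2]])
        assert wnodf(m) == 0.0

    def test_permutation_invariance(self, rng):
        for _ in range(10):
            m = random_count_matrix(rng, n_rows=5, n_cols=6)
            perm = m.counts[rng.permutation(5)][:, rng.permutation(6)]
            assert wnodf(make_matrix(perm)) == pytest.approx(wnodf(m))

    def test_scaling_invariance(self, rng):
        for _ in range(10):
            m = random_count_matrix(rng)
            try:
                w = wnodf(m)
            except ValueError:
                continue
            assert wnodf(make_matrix(m.counts * 7)) == pytest.approx(w)

    def test_degenerate_both_axes_errors(self):
        with pytest.raises(ValueError, match="degenerate"):
            wnodf(make_matrix([[3]]))

    def test_single_row_axis_contributes_zero_pairs(self):
        # only the column axis can score: 1x3 strictly decreasing row
        m = make_matrix([[3, 2, 1]])
        assert wnodf(m) == pytest.approx(100.0)  # 3 column pairs, all nested

    def test_strictly_nested_random_sizes(self, rng):
        # strictly decreasing weights on a full lower-left template
        a = np.zeros((4, 5), dtype=int)
        vals = iter(range(100, 0, -1))
        for i in range(4):
            for j in range(5 - i):
                a[i, j] = next(vals)
        # make weights decrease along both axes
        a = np.sort(a, axis=1)[:, ::-1]
        assert wnodf(make_matrix(a)) == pytest.approx(100.0)


def _enumerate_matrices(row_totals, col_totals):
    """All non-negative integer matrices with the given marginals."""
    n_rows, n_cols = len(row_totals), len(col_totals)

    def rows(remaining_cols, row_idx):
        if row_idx == n_rows:
            if all(c == 0 for c in remaining_cols):
                yield []
            return
        target = row_totals[row_idx]
        for combo in itertools.product(
            *(range(min(target, c) + 1) for c in remaining_cols)
        ):
            if sum(combo) != target:
                continue
            rest = tuple(c - x for c, x in zip(remaining_cols, combo))
            for tail in rows(rest, row_idx + 1):
                yield [combo] + tail

    for mat in rows(tuple(col_totals), 0):
        yield np.array(mat)


def _entropy(mat):
    p = mat[mat > 0] / mat.sum()
    return float(-(p * np.log(p)).sum())


class TestH2Prime:
    def test_diagonal_equal_margins_is_maximal(self):
        m = make_matrix(np.eye(4, dtype=int) * 3)
        assert h2prime(m) == pytest.approx(1.0)

    def test_outer_product_is_independent(self):
        m = make_matrix(np.outer([4, 2, 2], [4, 2, 2]) // 4)
        assert h2prime(m) == pytest.approx(0.0, abs=1e-12)

    def test_bounds_on_random_matrices(self, rng):
        for _ in range(25):
            m = random_count_matrix(rng)
            counts = m.counts
            counts = counts[counts.sum(axis=1) > 0][:, counts.sum(axis=0) > 0]
            if counts.shape[0] < 2 or counts.shape[1] < 2:
                continue
            h2 = _entropy(counts)
            r = counts.sum(axis=1) / counts.sum()
            c = counts.sum(axis=0) / counts.sum()
            h2max = _entropy(np.outer(r, c) * counts.sum())
            h2min = greedy_min_entropy(counts.sum(axis=1), counts.sum(axis=0))
            assert h2min <= h2 + 1e-9
            assert h2 <= h2max + 1e-9

    @pytest.mark.parametrize("shape", [(2, 2), (2, 3)])
    def test_greedy_min_entropy_is_true_minimum(self, shape):
        """Exhaustive check on all small integer marginals up to total 6."""
        n_rows, n_cols = shape
        total_max = 6
        checked = 0
        for total in range(2, total_max + 1):
            for rt in itertools.product(range(1, total + 1), repeat=n_rows):
                if sum(rt) != total:
                    continue
                for ct in itertools.product(range(1, total + 1), repeat=n_cols):
                    if sum(ct) != total:
                        continue
                    brute = min(
                        _entropy(mat) for mat in _enumerate_matrices(rt, ct)
                    )
                    greedy = greedy_min_entropy(np.array(rt), np.array(ct))
                    assert greedy == pytest.approx(brute, abs=1e-9), (rt, ct)
                    checked += 1
        assert checked > 20

    def test_scaling_invariance(self, rng):
        for _ in range(10):
            m = random_count_matrix(rng, n_rows=4, n_cols=4)
            assert h2prime(make_matrix(m.counts * 5)) == pytest.approx(
                h2prime(m), abs=1e-9
            )


class TestDPrime:
    def test_exclusive_partners_score_one(self):
        m = make_matrix(np.eye(3, dtype=int) * 4)
        assert dprime_hosts(m) == pytest.approx(np.ones(3))

    def test_proportional_use_scores_zero(self):
        m = make_matrix(np.outer([4, 2, 2], [4, 2, 2]) // 4)
        assert dprime_hosts(m) == pytest.approx(np.zeros(3), abs=1e-12)

    def test_zero_burden_host_is_nan_with_warning(self):
        m = make_matrix([[1, 0], [1, 0]])
        with pytest.warns(UserWarning, match="zero burden"):
            d = dprime_hosts(m)
        assert np.isnan(d[1]) and not np.isnan(d[0])

    def test_range_and_scaling(self, rng):
        import warnings

        for _ in range(10):
            m = random_count_matrix(rng, n_rows=4, n_cols=5)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", UserWarning)
                d = dprime_hosts(m)
            ok = ~np.isnan(d)
            assert np.all((d[ok] >= 0) & (d[ok] <= 1))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", UserWarning)
                d2 = dprime_hosts(make_matrix(m.counts * 3))
            assert d2[ok] == pytest.approx(d[ok], abs=1e-9)


def test_network_metrics_bundle(nested_matrix):
    nm = network_metrics(nested_matrix)
    assert nm.wnodf == pytest.approx(100.0)
    assert nm.n_hosts == 3 and nm.n_species == 3
    assert nm.n_links == 6
    assert nm.connectance == pytest.approx(6 / 9)
    assert 0 <= nm.h2prime <= 1
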