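"""Group-comparison statistics against hand computations and brute-force oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cfosmap.stats import (
    bh_fdr,
    coefficient_of_variation,
    compare_groups,
    correlation_map,
    counts_matrix,
    relative_zscore,
    signed_fold_change,
    spearman,
    student_ttest,
    volcano_classify,
)


def brute_force_bh(p):
    """Step-up definition: q_(i) = min_{j>=i} p_(j) * m / j, clipped at 1."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    q_sorted = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        running = min(running, p[order[rank - 1]] * m / rank)
        q_sorted[rank - 1] = min(running, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


class TestTTest:
    def test_hand_computed_pooled_t(self):
        t, p = student_ttest((1, 2, 3), (2, 3, 4))
        assert t == pytest.approx(-1.2247, abs=1e-4)
        assert p == pytest.approx(0.2879, abs=1e-4)

    def test_identical_samples_give_t_zero_p_one(self):
        t, p = student_ttest((1, 2, 3), (1, 2, 3))
        assert t == 0.0
        assert p == pytest.approx(1.0)

    def test_swapping_flips_sign_only(self):
        t1, p1 = student_ttest((1, 2, 3), (2, 3, 5))
        t2, p2 = student_ttest((2, 3, 5), (1, 2, 3))
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)

    def test_degenerate_variance_raises(self):
        with pytest.raises(ValueError, match="degenerate variance"):
            student_ttest((1.0, 1.0), (2.0, 2.0))

    def test_small_samples_rejected(self):
        with pytest.raises(ValueError):
            student_ttest((1.0,), (2.0, 3.0))


class TestBHFDR:
    def test_hand_computed_step_up(self):
        q = bh_fdr([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04], atol=1e-12)

    def test_single_p_unchanged(self):
        assert bh_fdr([0.2])[0] == pytest.approx(0.2)

    def test_all_equal_ps_unchanged(self):
        np.testing.assert_allclose(bh_fdr([0.3] * 5), [0.3] * 5, atol=1e-12)

    def test_matches_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(99)
        for _ in range(200):
            p = rng.random(rng.integers(1, 40))
            np.testing.assert_allclose(bh_fdr(p), brute_force_bh(p), atol=1e-12)

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_monotone_in_p(self, ps):
        q = bh_fdr(ps)
        order = np.argsort(ps, kind="mergesort")
        assert np.all(np.diff(q[order]) >= -1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])


class TestFoldChange:
    def test_signed_convention(self):
        assert signed_fold_change(2, 1, epsilon=1e-12) == pytest.approx(2.0)
        assert signed_fold_change(1, 2, epsilon=1e-12) == pytest.approx(-2.0)
        assert signed_fold_change(3, 3) == pytest.approx(1.0)

    def test_epsilon_guards_zero_means(self):
        fc = signed_fold_change(0.0, 0.0, epsilon=0.5)
        assert fc == pytest.approx(1.0)

    def test_volcano_classification_boundaries(self):
        table = pd.DataFrame(
            {
                "signed_fold_change": [1.5, 1.4, -2.0, -1.5, 2.0],
                "q": [0.01, 0.01, 0.2, 0.04, 0.05],
            }
        )
        out = volcano_classify(table, fc_cut=1.4, q_cut=0.05)
        assert list(out["significance_class"]) == ["up", "ns", "ns", "down", "ns"]


class TestZScoreAndCV:
    def test_three_point_column(self):
        z, flags = relative_zscore(pd.DataFrame({"r": [1.0, 2.0, 3.0]}))
        np.testing.assert_allclose(z["r"], [-1, 0, 1])
        assert not flags["r"]

    def test_constant_column_flagged_zero(self):
        z, flags = relative_zscore(pd.DataFrame({"r": [2.0, 2.0, 2.0]}))
        np.testing.assert_allclose(z["r"], 0.0)
        assert bool(flags["r"])

    def test_columns_normalised(self, rng):
        counts = pd.DataFrame(rng.lognormal(5, 0.5, size=(12, 6)))
        z, flags = relative_zscore(counts)
        np.testing.assert_allclose(z.mean(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(z.std(axis=0, ddof=1), 1.0, atol=1e-12)

    def test_control_baseline_switch(self):
        counts = pd.DataFrame({"r": [1.0, 3.0, 10.0, 20.0]})
        groups = pd.Series(["ctrl", "ctrl", "stress", "stress"])
        z, _ = relative_zscore(counts, groups=groups, baseline="ctrl")
        # ctrl mean 2, sample SD sqrt(2)
        np.testing.assert_allclose(z["r"], (counts["r"] - 2) / np.sqrt(2))

    def test_cv_hand_value_and_scale_invariance(self, rng):
        assert coefficient_of_variation([2, 4, 6]) == pytest.approx(0.5)
        assert coefficient_of_variation([5, 5, 5]) == 0.0
        x = rng.lognormal(3, 0.4, size=8)
        assert coefficient_of_variation(7.3 * x) == pytest.approx(
            coefficient_of_variation(x), rel=1e-12
        )

    def test_cv_zero_mean_rejected(self):
        with pytest.raises(ValueError):
            coefficient_of_variation([-1.0, 1.0])


def rank_with_ties(x):
    x = np.asarray(x, dtype=float)
    ranks = np.empty(len(x))
    for i, v in enumerate(x):
        less = np.sum(x < v)
        equal = np.sum(x == v)
        ranks[i] = less + (equal + 1) / 2.0
    return ranks


class TestSpearman:
    def test_monotone_pairs(self):
        assert spearman([1, 2, 3, 4], [10, 20, 30, 40])[0] == pytest.approx(1.0)
        assert spearman([1, 2, 3, 4], [5, 4, 3, 2])[0] == pytest.approx(-1.0)

    def test_matches_rank_pearson_oracle_with_ties(self):
        x, y = [1, 2, 2, 4], [1, 3, 2, 4]
        rho, _ = spearman(x, y)
        rx, ry = rank_with_ties(x), rank_with_ties(y)
        expected = np.corrcoef(rx, ry)[0, 1]
        assert rho == pytest.approx(expected, abs=1e-12)

    def test_constant_vector_flagged(self):
        with pytest.raises(ValueError, match="constant"):
            spearman([1, 1, 1], [1, 2, 3])


class TestCorrelationMap:
    def test_perfectly_correlated_pair_are_mutual_best_partners(self):
        counts = pd.DataFrame(
            {"A": [1, 2, 3, 4, 6], "B": [2, 4, 6, 8, 12], "C": [5, 1, 4, 2, 3]}
        )
        cmap = correlation_map(counts)
        assert cmap.rho.loc["A", "B"] == pytest.approx(1.0)
        assert cmap.best_partner["A"] == "B"
        assert cmap.best_partner["B"] == "A"

    def test_matrix_symmetric_with_nan_diagonal(self, rng):
        counts = pd.DataFrame(rng.lognormal(4, 0.5, size=(6, 5)))
        cmap = correlation_map(counts)
        r = cmap.rho.to_numpy()
        np.testing.assert_allclose(r, r.T, atol=1e-12)
        assert np.isnan(np.diag(r)).all()

    def test_planted_negative_correlation_recovered(self):
        rng = np.random.default_rng(17)
        a = rng.lognormal(4, 0.3, size=8)
        counts = pd.DataFrame(
            {"up": a, "down": 1000.0 / a, "noise": rng.lognormal(4, 0.3, size=8)}
        )
        cmap = correlation_map(counts)
        assert cmap.rho.loc["up", "down"] == pytest.approx(-1.0)


class TestCompareGroups:
    def _counts(self, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for group, factor in (("ctrl", 1.0), ("stress", 3.0)):
            for a in range(6):
                for region in ("R1", "R2"):
                    f = factor if region == "R1" else 1.0
                    rows.append(
                        {
                            "animal": f"{group}{a}",
                            "group": group,
                            "region": region,
                            "count": rng.lognormal(np.log(200 * f), 0.1),
                        }
                    )
        return pd.DataFrame(rows)

    def test_planted_region_called_up_and_sorted_by_q(self):
        table = compare_groups(self._counts(), "stress", "ctrl")
        assert list(table["q"]) == sorted(table["q"])
        r1 = table.set_index("region").loc["R1"]
        assert r1["significance_class"] == "up"
        assert r1["signed_fold_change"] > 2

    def test_class_partition_is_exhaustive(self):
        table = compare_groups(self._counts(3), "stress", "ctrl")
        n = (table["significance_class"].isin(["up", "down", "ns"])).sum()
        assert n == len(table)

    def test_counts_matrix_pivot(self):
        mat = counts_matrix(self._counts(), "ctrl")
        assert mat.shape == (6, 2)
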