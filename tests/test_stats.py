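"""Spearman with exact permutation p, ANOVA/Tukey, fold checks."""

import numpy as np
import pytest

from abframe.stats import (
    VariantSummary,
    anova_tukey,
    fold_check,
    spearman_correlation,
    spearman_tm_titer,
)

# reported affinity panel: variant name -> KD (M)
TABLE2_KD = {
    "1-DIQMAQ": 2.6e-9, "2-DIQMAQ-K": 3.0e-9, "3-EIVLAQ": 1.5e-9,
    "4-DIQMGQ": 4.3e-9, "5-DIQMAE": 2.5e-9, "6-EIVLGQ": 2.7e-9,
    "7-EIVLAE": 2.4e-9, "8-DIQMGE": 4.2e-9, "9-EIVLGE": 1.4e-9,
}


class TestSpearman:
    def test_monotone_n4_exact_p_is_1_over_24(self):
        result = spearman_correlation([1, 2, 3, 4], [10, 20, 30, 40])
        assert result.rho == pytest.approx(1.0)
        assert result.p_value == pytest.approx(1 / 24)
        assert result.p_method == "exact-permutation"

    def test_anti_monotone_gives_rho_minus_1(self):
        result = spearman_correlation([1, 2, 3, 4, 5], [9, 7, 5, 3, 1],
                                      alternative="less")
        assert result.rho == pytest.approx(-1.0)
        assert result.p_value == pytest.approx(1 / 120)

    def test_exact_matches_t_approximation_at_n10(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=10)
        y = 0.5 * x + rng.normal(size=10)
        exact = spearman_correlation(x, y, method="exact-permutation")
        approx = spearman_correlation(x, y, method="t-approximation")
        assert exact.rho == pytest.approx(approx.rho)
        assert abs(exact.p_value - approx.p_value) < 0.02

    def test_two_sided_doubles_one_sided_without_ties(self):
        x = [1, 2, 3, 4, 5]
        y = [2, 1, 4, 3, 5]
        one = spearman_correlation(x, y, alternative="greater")
        two = spearman_correlation(x, y, alternative="two-sided")
        assert two.p_value == pytest.approx(2 * one.p_value)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            spearman_correlation([1, 1, 1, 1], [1, 2, 3, 4])

    def test_planted_tm_titer_coupling_detected_in_most_seeds(self):
        # 9-variant panel with the planted positive Tm-titer coupling:
        # lognormal titer replicates around fold-scaled means, Tm with
        # replicate-level measurement error
        tm_true = np.array([70.0, 70.0, 70.5, 70.7, 72.2, 74.1, 72.3, 72.4, 74.3])
        folds = np.array([1.0, 1.0, 1.3, 4.0, 1.2, 7.0, 1.4, 5.0, 10.0])
        hits = 0
        n_seeds = 20
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            tm = tm_true + rng.normal(0, 0.15, 9)
            titer = 100.0 * folds * rng.lognormal(0, 0.2 / np.sqrt(5), 9)
            result = spearman_correlation(tm, titer, alternative="greater")
            hits += result.p_value < 0.05
        assert hits > n_seeds / 2

    def test_tm_titer_wrapper_uses_replicate_means(self):
        summaries = [
            VariantSummary(f"v{i}", [10.0 * (i + 1)] * 3, 70.0 + i, 2e-9)
            for i in range(5)
        ]
        result = spearman_tm_titer(summaries)
        assert result.rho == pytest.approx(1.0)
        assert result.n == 5


class TestAnovaTukey:
    def test_equal_means_give_f_near_zero(self):
        base = [9.8, 10.1, 10.0, 9.9, 10.2]
        result = anova_tukey({"a": base, "b": list(base), "c": list(base)})
        assert result.f_statistic == pytest.approx(0.0, abs=1e-9)
        assert (result.tukey["p-adj"].astype(float) > 0.99).all()

    def test_five_fold_separation_detected_in_most_seeds(self):
        hits = 0
        n_seeds = 40
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            low = rng.normal(100, 15, 5)
            high = rng.normal(500, 75, 5)
            result = anova_tukey({"parental": low, "variant": high})
            hits += result.p_value < 0.05
        assert hits / n_seeds > 0.95

    def test_only_pairs_with_the_affected_group_are_significant(self):
        rng = np.random.default_rng(2)
        groups = {
            "a": rng.normal(100, 10, 6),
            "b": rng.normal(100, 10, 6),
            "c": rng.normal(400, 40, 6),
        }
        result = anova_tukey(groups)
        tk = result.tukey
        for _, row in tk.iterrows():
            significant = bool(row["reject"])
            involves_c = "c" in (row["group1"], row["group2"])
            assert significant == involves_c

    def test_normality_screen_reported_per_group(self):
        rng = np.random.default_rng(3)
        result = anova_tukey({"a": rng.normal(0, 1, 20) + 5,
                              "b": rng.normal(0, 1, 20) + 5})
        assert set(result.normality_p) == {"a", "b"}
        assert all(0 <= p <= 1 for p in result.normality_p.values())

    def test_singleton_group_rejected(self):
        with pytest.raises(ValueError):
            anova_tukey({"a": [1.0], "b": [1.0, 2.0]})


class TestFoldCheck:
    def test_reported_kd_panel_passes_factor_of_two(self):
        result = fold_check(TABLE2_KD, reference="1-DIQMAQ", bound=2.0)
        assert result.max_fold == pytest.approx(2.6 / 1.4, rel=1e-9)
        assert result.max_variant == "9-EIVLGE"
        assert result.passed

    def test_reference_fold_is_one(self):
        result = fold_check({"a": 3.0, "b": 3.0}, reference="a")
        assert result.folds["a"] == 1.0

    def test_exactly_twofold_passes_inclusive_bound(self):
        result = fold_check({"ref": 1.0, "v": 2.0}, reference="ref", bound=2.0)
        assert result.max_fold == 2.0
        assert result.passed

    def test_invariant_to_global_rescaling_and_relabeling(self):
        vals = {"r": 2.0, "x": 3.1, "y": 0.9}
        a = fold_check(vals, "r")
        b = fold_check({k: 7.3 * v for k, v in vals.items()}, "r")
        assert a.max_fold == pytest.approx(b.max_fold, rel=1e-12)

    def test_nonpositive_value_rejected(self):
        with pytest.raises(ValueError):
            fold_check({"r": 1.0, "v": -2.0}, reference="r")
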