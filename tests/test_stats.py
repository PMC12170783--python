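"""Propensity scoring, full matching, adjusted effects and plain tests."""

import numpy as np
import pandas as pd
import pytest

from sleepbai.core import ValidationError
from sleepbai.stats import (
    MatchResult,
    adjusted_effect,
    balance_table,
    bonferroni_threshold,
    estimate_propensity,
    full_match,
    linear_trend,
    paired_ttest,
    significance_label,
    spearman,
    welch_ttest,
)


def _confounded_cohort(n0=120, n1=30, seed=0, delta_age=12.0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame({
        "age": np.r_[rng.normal(50, 10, n0), rng.normal(50 - delta_age, 7, n1)].clip(18, 80),
        "sex": rng.choice(["F", "M"], n0 + n1),
        "education": rng.choice(["hs", "col", "grad"], n0 + n1),
        "race": rng.choice(["w", "a", "b", "o"], n0 + n1),
        "group": ["ref"] * n0 + ["med"] * n1,
    })


class TestPropensity:
    def test_identical_distributions_give_base_rate(self):
        cohort = _confounded_cohort(delta_age=0.0, seed=1)
        scores = estimate_propensity(cohort, "med")
        base = (cohort["group"] == "med").mean()
        assert abs(scores.mean() - base) < 0.05
        assert scores.between(0, 1, inclusive="neither").all()

    def test_confounded_groups_discriminable(self):
        from sklearn.metrics import roc_auc_score

        cohort = _confounded_cohort(seed=2)
        scores = estimate_propensity(cohort, "med")
        auc = roc_auc_score((cohort["group"] == "med").astype(int), scores)
        assert auc > 0.7

    def test_age_sex_only_subset(self):
        cohort = _confounded_cohort(seed=3)[["age", "sex", "group"]]
        scores = estimate_propensity(cohort, "med", confounders=("age", "sex"))
        assert len(scores) == len(cohort)

    def test_missing_confounders_excluded(self):
        cohort = _confounded_cohort(seed=4)
        cohort.loc[3, "age"] = np.nan
        with pytest.warns(UserWarning, match="missing"):
            scores = estimate_propensity(cohort, "med")
        assert 3 not in scores.index

    def test_two_groups_required(self):
        cohort = _confounded_cohort()
        cohort["group"] = "one"
        with pytest.raises(ValidationError):
            estimate_propensity(cohort, "one")


class TestFullMatch:
    def test_exact_pairs(self):
        match = full_match(np.array([0.2, 0.2, 0.8, 0.8]),
                           np.array([True, False, True, False]))
        assert match.n_subclasses == 2
        np.testing.assert_array_equal(match.weights, np.ones(4))

    def test_one_treated_three_controls(self):
        match = full_match(np.array([0.5, 0.49, 0.5, 0.51]),
                           np.array([True, False, False, False]))
        assert match.n_subclasses == 1
        assert match.weights[0] == 1.0
        assert match.weights[1:].sum() == pytest.approx(3.0)

    def test_weight_conservation_property(self):
        rng = np.random.default_rng(5)
        for trial in range(10):
            n0, n1 = rng.integers(5, 40), rng.integers(2, 10)
            scores = rng.random(n0 + n1)
            treated = np.r_[np.zeros(n0, bool), np.ones(n1, bool)]
            match = full_match(scores, treated)
            assert match.weights[treated].sum() == pytest.approx(n1, abs=1e-9)
            assert match.weights[~treated].sum() == pytest.approx(n0, abs=1e-9)
            comp = match.composition()
            assert (comp["n_treated"] >= 1).all()
            assert (comp["n_total"] - comp["n_treated"] >= 1).all()

    def test_empty_group_rejected(self):
        with pytest.raises(ValidationError):
            full_match(np.array([0.1, 0.2]), np.array([True, True]))

    def test_matching_balances_confounded_cohort(self):
        cohort = _confounded_cohort(seed=6)
        treated = (cohort["group"] == "med").to_numpy()
        scores = estimate_propensity(cohort, "med")
        match = full_match(scores.to_numpy(), treated)
        before = balance_table(cohort, treated)
        after = balance_table(cohort, treated, match.weights)
        assert abs(before["age"]) >= 0.5
        assert abs(after["age"]) < 0.1
        assert after.abs().sum() < before.abs().sum()


class TestBalance:
    def test_unit_weights_equal_unweighted_formula(self):
        cohort = _confounded_cohort(seed=7)
        treated = (cohort["group"] == "med").to_numpy()
        smd = balance_table(cohort, treated)
        age = cohort["age"].to_numpy()
        pooled = np.sqrt((age[treated].std(ddof=1) ** 2 + age[~treated].std(ddof=1) ** 2) / 2)
        expected = (age[treated].mean() - age[~treated].mean()) / pooled
        assert smd["age"] == pytest.approx(expected)

    def test_perfectly_balanced_sample_zero_smd(self):
        cohort = pd.DataFrame({"age": [30, 40, 30, 40], "group": ["a", "a", "b", "b"]})
        smd = balance_table(cohort, np.array([True, True, False, False]),
                            covariates=("age",))
        assert abs(smd["age"]) < 1e-12

    def test_zero_pooled_sd_flagged_as_zero(self):
        cohort = pd.DataFrame({"age": [40.0] * 4, "group": list("aabb")})
        smd = balance_table(cohort, np.array([True, True, False, False]),
                            covariates=("age",))
        assert smd["age"] == 0.0


class TestAdjustedEffect:
    def _unit_match(self, treated, pairs):
        return MatchResult(subclass=np.asarray(pairs), weights=np.ones(len(treated)),
                           scores=np.full(len(treated), 0.5),
                           treated=np.asarray(treated), index=np.arange(len(treated)))

    def test_identical_outcomes_null(self):
        treated = np.array([True, False, True, False, True, False])
        match = self._unit_match(treated, [0, 0, 1, 1, 2, 2])
        est = adjusted_effect(np.ones(6), treated, match)
        assert est.effect == pytest.approx(0.0, abs=1e-12)
        assert est.p_value > 0.99

    def test_unit_weights_reduce_to_mean_difference(self):
        rng = np.random.default_rng(8)
        treated = np.tile([True, False], 10)
        y = rng.normal(0, 1, 20) + treated * 2.0
        match = self._unit_match(treated, np.repeat(np.arange(10), 2))
        est = adjusted_effect(y, treated, match)
        assert est.effect == pytest.approx(y[treated].mean() - y[~treated].mean())
        assert est.ci_low < est.effect < est.ci_high

    def test_single_subclass_rejected(self):
        treated = np.array([True, False])
        match = self._unit_match(treated, [0, 0])
        with pytest.raises(ValidationError):
            adjusted_effect(np.array([1.0, 2.0]), treated, match)

    def test_consistency_on_unconfounded_data(self):
        # adjusted estimate ≈ unadjusted difference within 2×SE when
        # covariates carry no confounding
        rng = np.random.default_rng(9)
        cohort = _confounded_cohort(seed=10, delta_age=0.0)
        treated = (cohort["group"] == "med").to_numpy()
        y = rng.normal(0, 2, len(cohort)) - 3.0 * treated
        scores = estimate_propensity(cohort, "med")
        match = full_match(scores.to_numpy(), treated)
        est = adjusted_effect(y, treated, match)
        naive = y[treated].mean() - y[~treated].mean()
        assert abs(est.effect - naive) < 2 * est.se


class TestPlainTests:
    def test_paired_identical_is_null(self):
        res = paired_ttest([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_paired_constant_shift_degenerate(self):
        with pytest.raises(ValidationError):
            paired_ttest([1.0, 2.0, 3.0], [2.0, 3.0, 4.0])

    def test_welch_detects_unit_shift(self):
        rng = np.random.default_rng(11)
        res = welch_ttest(rng.normal(0, 1, 1000), rng.normal(1, 1, 1000))
        assert res.p_value < 0.001

    def test_spearman_monotone_and_reversed(self):
        x = np.array([0.1, 0.5, 1.2, 2.0, 3.3])
        rho, _ = spearman(x, np.exp(x))
        assert rho == pytest.approx(1.0)
        rho, _ = spearman(x, -x)
        assert rho == pytest.approx(-1.0)

    def test_spearman_null_small(self):
        rng = np.random.default_rng(12)
        hits = sum(abs(spearman(rng.random(1000), rng.random(1000))[0]) < 0.1
                   for _ in range(40))
        assert hits >= 38

    def test_spearman_constant_rejected(self):
        with pytest.raises(ValidationError):
            spearman([1, 1, 1, 1], [1, 2, 3, 4])

    def test_bonferroni_and_labels(self):
        assert bonferroni_threshold(0.05, 50) == pytest.approx(0.001)
        assert bonferroni_threshold(0.05, 1) == 0.05
        assert significance_label(0.0005) == "significant"
        assert significance_label(0.01) == "trend-level"
        assert significance_label(0.2) == "ns"


class TestTrend:
    def test_exact_line(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        fit = linear_trend(x, 2 * x + 1)
        assert fit.slope == pytest.approx(2.0)
        mean, lo, hi = fit.band(x)
        assert np.abs(hi - lo).max() < 1e-8

    def test_antisymmetry(self):
        rng = np.random.default_rng(13)
        x = rng.random(20)
        y = rng.random(20)
        assert linear_trend(x, y).slope == pytest.approx(-linear_trend(x, -y).slope)

    def test_null_slope_ci_coverage_at_study_n(self):
        # no-trend data at the study's n=29: slope CI covers 0 ≈ 95% of runs
        rng = np.random.default_rng(14)
        cover = 0
        reps = 300
        for _ in range(reps):
            x = rng.uniform(0, 30, 29)
            y = rng.normal(0, 5, 29)
            fit = linear_trend(x, y)
            cover += fit.slope_ci[0] <= 0 <= fit.slope_ci[1]
        assert cover / reps == pytest.approx(0.95, abs=0.03)

    def test_constant_predictor_rejected(self):
        with pytest.raises(ValidationError):
            linear_trend([1, 1, 1], [1, 2, 3])
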