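import numpy as np
import pandas as pd
import pytest

from mdsls.score import (MDSLikelihoodScore, PerformanceReport, compute_score,
                         evaluate, fit_score_model, score_cohort)
from mdsls.synth import default_cohort_spec, flip_effects, generate_cohort


@pytest.fixture(scope="module")
def planted_cohort(planted_names_module):
    return generate_cohort(default_cohort_spec(seed=21))


@pytest.fixture(scope="module")
def planted_names_module():
    from mdsls.synth import CRITICAL_PARAMETERS
    return sorted(CRITICAL_PARAMETERS)


@pytest.fixture(scope="module")
def fitted(planted_cohort, planted_names_module):
    return fit_score_model(planted_cohort, planted_names_module,
                           n_iterations=201, seed=5)


class TestFit:
    def test_split_accounting(self, fitted, planted_cohort):
        assert fitted.learn_size_ == 130
        assert len(planted_cohort) - fitted.learn_size_ == 59

    def test_learn_ratio_kept_for_other_cohort_sizes(self,
                                                     planted_names_module):
        cohort = generate_cohort(default_cohort_spec(n_mds=60, n_healthy=40,
                                                     seed=2))
        model = fit_score_model(cohort, planted_names_module,
                                n_iterations=11, seed=0)
        assert model.learn_size_ == round(100 * 130 / 189)

    def test_median_coefficients_match_draws(self, fitted):
        p = len(fitted.parameters_)
        np.testing.assert_allclose(
            fitted.coef_, np.median(fitted.coefficient_draws_[:, :p], axis=0),
            atol=1e-12)
        assert fitted.intercept_ == pytest.approx(
            np.median(fitted.coefficient_draws_[:, p]), abs=1e-12)

    def test_odd_iterations_make_each_coef_a_drawn_value(self, fitted):
        draws = fitted.coefficient_draws_
        for i, c in enumerate(fitted.coef_):
            assert np.isclose(draws[:, i], c).any()

    def test_efficiencies_in_unit_interval(self, fitted):
        assert len(fitted.efficiencies_) == 201
        assert ((fitted.efficiencies_ >= 0)
                & (fitted.efficiencies_ <= 1)).all()

    def test_seed_determinism(self, planted_cohort, planted_names_module):
        a = fit_score_model(planted_cohort, planted_names_module,
                            n_iterations=5, seed=9)
        b = fit_score_model(planted_cohort, planted_names_module,
                            n_iterations=5, seed=9)
        np.testing.assert_array_equal(a.coefficient_draws_,
                                      b.coefficient_draws_)
        assert a.intercept_ == b.intercept_

    def test_strong_separation_gives_high_efficiency(self,
                                                     planted_names_module):
        cohort = generate_cohort(default_cohort_spec(effect_d=3.0, seed=3))
        model = fit_score_model(cohort, planted_names_module,
                                n_iterations=200, seed=3)
        assert model.efficiencies_.mean() >= 0.99

    def test_permuted_labels_efficiency_at_chance(self, planted_cohort,
                                                  planted_names_module):
        """Null check: no residual signal once labels are shuffled."""
        rng = np.random.default_rng(17)
        permuted = planted_cohort.copy()
        permuted["group"] = rng.permutation(
            planted_cohort["group"].to_numpy())
        model = fit_score_model(permuted, planted_names_module,
                                n_iterations=200, seed=17)
        majority = max((permuted["group"] == "MDS").mean(),
                       (permuted["group"] == "HEALTHY").mean())
        se = np.sqrt(majority * (1 - majority) / 59)
        assert model.efficiencies_.mean() <= majority + 3 * se

    def test_orientation_antisymmetry(self, planted_names_module):
        """Reversing every planted effect reverses the score ranking."""
        spec = default_cohort_spec(seed=8)
        ca = generate_cohort(spec)
        cb = generate_cohort(flip_effects(spec))
        ma = fit_score_model(ca, planted_names_module, n_iterations=51,
                             seed=8)
        mb = fit_score_model(cb, planted_names_module, n_iterations=51,
                             seed=8)
        sa = score_cohort(ca, ma)
        sb = score_cohort(cb, mb)
        assert sa.loc[sa.group == "MDS", "mds_ls"].mean() < 0
        assert sb.loc[sb.group == "MDS", "mds_ls"].mean() < 0

    def test_single_group_rejected(self, planted_names_module):
        cohort = generate_cohort(default_cohort_spec(n_mds=0, n_healthy=30,
                                                     seed=1))
        with pytest.raises(ValueError, match="labels"):
            fit_score_model(cohort, planted_names_module, n_iterations=3)


class TestScoring:
    def test_group_score_signs(self, fitted, planted_cohort):
        scores = score_cohort(planted_cohort, fitted)
        assert scores.loc[scores.group == "MDS", "mds_ls"].mean() < 0
        assert scores.loc[scores.group == "HEALTHY", "mds_ls"].mean() > 0

    def test_degenerate_coefficients_hand_arithmetic(self):
        model = MDSLikelihoodScore.from_document({
            "parameters": [f"P{i}" for i in range(10)],
            "coefficients": [0.0] * 10, "intercept": 5.0})
        record = {f"P{i}": 1.0 for i in range(10)}
        result = compute_score(record, model)
        assert result.mds_ls == 5.0 and result.predicted_group == "HEALTHY"

    def test_single_coefficient_hand_arithmetic(self):
        model = MDSLikelihoodScore.from_document({
            "parameters": [f"P{i}" for i in range(10)],
            "coefficients": [1.0] + [0.0] * 9, "intercept": -2.0})
        record = {f"P{i}": 1.0 for i in range(10)}
        result = compute_score(record, model)
        assert result.mds_ls == -1.0 and result.predicted_group == "MDS"

    def test_zero_score_classified_mds(self):
        model = MDSLikelihoodScore.from_document({
            "parameters": ["P0"], "coefficients": [1.0], "intercept": -1.0})
        assert compute_score({"P0": 1.0}, model).predicted_group == "MDS"

    def test_missing_parameter_named(self, fitted):
        with pytest.raises(ValueError, match=fitted.parameters_[0]):
            compute_score({"bogus": 1.0}, fitted)

    def test_document_roundtrip(self, fitted, tmp_path):
        path = tmp_path / "model.json"
        fitted.save(path)
        restored = MDSLikelihoodScore.load(path)
        np.testing.assert_allclose(restored.coef_, fitted.coef_)
        assert restored.intercept_ == fitted.intercept_
        record = {p: 100.0 for p in fitted.parameters_}
        assert (compute_score(record, restored).mds_ls
                == pytest.approx(compute_score(record, fitted).mds_ls))


class TestEvaluate:
    def test_perfect_classification(self):
        report = PerformanceReport(tp=10, fn=0, tn=5, fp=0)
        assert report.sensitivity == 1.0 and report.specificity == 1.0

    def test_flag_everyone_closed_form(self):
        # classifier that calls everyone MDS
        report = PerformanceReport(tp=101, fn=0, tn=0, fp=88)
        assert report.sensitivity == 1.0
        assert report.specificity == 0.0
        assert report.ppv == pytest.approx(101 / 189)

    def test_empty_class_metric_undefined(self):
        report = PerformanceReport(tp=0, fn=0, tn=5, fp=1)
        assert report.sensitivity is None

    def test_counts_reconcile(self, fitted, planted_cohort):
        report = evaluate(planted_cohort, fitted)
        assert report.n == len(planted_cohort)
        assert report.tp + report.fn == 101
        assert report.tn + report.fp == 88

    def test_default_cohort_performance(self, fitted, planted_cohort):
        report = evaluate(planted_cohort, fitted)
        assert report.sensitivity >= 0.9 and report.specificity >= 0.9
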