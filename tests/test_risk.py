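"""Risk model, recalibration, thresholding, confusion metrics, test tradeoff."""

import json
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.special import expit
from sklearn.metrics import roc_auc_score

from pcspanel import SimulationConfig, simulate_cohort
from pcspanel.preprocess import default_pipeline_set
from pcspanel.risk import (
    CalibrationParams,
    ModelLockedError,
    RiskModel,
    ThresholdMetrics,
    clinical_metrics,
    fit_final_model,
    min_test_tradeoff,
    recalibrate,
    threshold_for_sensitivity,
)


@pytest.fixture(scope="module")
def fitted_model():
    cohort = simulate_cohort(SimulationConfig(
        n_samples=400, n_genes=9, block_size=3,
        signal_effects={"G01": 1.4, "G04": 1.0}, seed=21))
    pipe = default_pipeline_set()[0]
    model = fit_final_model(cohort, ["G01", "G04"], pipeline=pipe,
                            c_grid=[0.1, 1.0], seed=0)
    X = pd.concat(
        [pipe.fit_transform(cohort.ct)[model.panel_genes],
         cohort.clinical[model.clinical_vars].astype(float)], axis=1)
    return cohort, model, X


class TestFinalModel:
    def test_include_volume_adds_exactly_one_covariate(self):
        cohort = simulate_cohort(SimulationConfig(
            n_samples=200, n_genes=6, block_size=3, seed=1,
            signal_effects={"G01": 1.0}))
        pipe = default_pipeline_set()[0]
        without = fit_final_model(cohort, ["G01"], pipeline=pipe, c_grid=[1.0])
        with_vol = fit_final_model(cohort, ["G01"], pipeline=pipe, c_grid=[1.0],
                                   include_volume=True)
        assert set(with_vol.features) - set(without.features) == {"prostate_volume"}

    def test_refit_is_deterministic(self, fitted_model):
        cohort, model, _ = fitted_model
        again = fit_final_model(cohort, ["G01", "G04"],
                                pipeline=default_pipeline_set()[0],
                                c_grid=[0.1, 1.0], seed=0)
        assert model.coef == again.coef
        assert model.chosen_C == again.chosen_C

    def test_planted_sign_recovery_across_seeds(self):
        pipe = default_pipeline_set()[0]
        hits = 0
        for seed in range(10):
            cohort = simulate_cohort(SimulationConfig(
                n_samples=400, n_genes=9, block_size=3,
                signal_effects={"G01": 1.4, "G04": 1.0}, seed=seed))
            m = fit_final_model(cohort, ["G01", "G04"], pipeline=pipe,
                                c_grid=[1.0], seed=seed)
            hits += (m.coef["G01"] > 0) and (m.coef["G04"] > 0)
        assert hits >= 9

    def test_missing_panel_gene_rejected(self, fitted_model):
        cohort, _, _ = fitted_model
        with pytest.raises(KeyError):
            fit_final_model(cohort, ["NOT_A_GENE"],
                            pipeline=default_pipeline_set()[0])

    def test_json_round_trip_and_lock(self, fitted_model):
        _, model, X = fitted_model
        clone = RiskModel.from_json(model.to_json())
        np.testing.assert_allclose(clone.predict_risk(X), model.predict_risk(X))
        clone.lock()
        with pytest.raises(ModelLockedError):
            clone.set_calibration(CalibrationParams(0.1, 1.1))


class TestRecalibration:
    def test_self_recalibration_is_near_identity(self, fitted_model):
        cohort, model, X = fitted_model
        lp = model.linear_predictor(X)
        params = recalibrate(None, lp, cohort.outcome)
        assert params.intercept == pytest.approx(0.0, abs=0.15)
        assert params.slope == pytest.approx(1.0, abs=0.25)

    def test_parameter_recovery_on_simulated_link(self):
        rng = np.random.default_rng(0)
        lp = rng.normal(size=5000)
        y = rng.binomial(1, expit(0.5 + 2.0 * lp))
        params = recalibrate(None, lp, y)
        assert params.intercept == pytest.approx(0.5, abs=0.1)
        assert params.slope == pytest.approx(2.0, abs=0.1)

    def test_monotone_transform_preserves_auroc(self, fitted_model):
        cohort, model, X = fitted_model
        before = roc_auc_score(cohort.outcome, model.predict_risk(X))
        lp = model.linear_predictor(X)
        params = recalibrate(model, lp, cohort.outcome)
        assert params.slope > 0
        after = roc_auc_score(cohort.outcome, model.predict_risk(X))
        assert after == pytest.approx(before, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            recalibrate(None, np.zeros(10), np.zeros(10))


class TestThreshold:
    def test_target_one_captures_every_positive(self):
        rng = np.random.default_rng(1)
        scores = rng.uniform(size=200)
        labels = rng.binomial(1, 0.3, 200)
        thr = threshold_for_sensitivity(scores, labels, target=1.0)
        assert thr == scores[labels == 1].min()
        m = clinical_metrics(scores, labels, thr)
        assert m.fn == 0

    def test_perfect_separation_attains_full_specificity(self):
        scores = np.r_[np.zeros(50), np.ones(50)]
        labels = np.r_[np.zeros(50, int), np.ones(50, int)]
        for target in (0.5, 0.9, 1.0):
            thr = threshold_for_sensitivity(scores, labels, target)
            m = clinical_metrics(scores, labels, thr)
            assert m.specificity_pct == 100.0
            assert m.sensitivity_pct >= 100.0 * target

    def test_exhaustive_scan_oracle(self):
        """Floor holds, and any strictly larger threshold breaks it."""
        rng = np.random.default_rng(2)
        for _ in range(200):
            n = rng.integers(10, 60)
            scores = np.round(rng.uniform(size=n), 2)  # force ties
            labels = rng.binomial(1, 0.4, n)
            if labels.sum() == 0 or labels.sum() == n:
                continue
            target = rng.choice([0.8, 0.9, 0.95, 1.0])
            thr = threshold_for_sensitivity(scores, labels, target)
            pos = scores[labels == 1]
            sens = (pos >= thr).mean()
            assert sens >= target
            above = np.unique(scores[scores > thr])
            if above.size:
                assert (pos >= above.min()).mean() < target

    def test_invalid_target_rejected(self):
        with pytest.raises(ValueError):
            threshold_for_sensitivity(np.ones(4), np.array([0, 1, 0, 1]), 0.0)


class TestClinicalMetrics:
    @given(st.integers(0, 500), st.integers(0, 500),
           st.integers(0, 500), st.integers(0, 500))
    def test_identities_on_arbitrary_counts(self, tp, fp, tn, fn):
        m = ThresholdMetrics.from_counts(tp=tp, fp=fp, tn=tn, fn=fn)
        assert m.n == tp + fp + tn + fn
        if tp + fn:
            assert m.sensitivity_pct == pytest.approx(100 * tp / (tp + fn))
        else:
            assert m.sensitivity_pct is None
        if tn + fp:
            assert m.specificity_pct == pytest.approx(100 * tn / (tn + fp))
            assert m.biopsies_avoided_per_1000 == round(1000 * tn / (tn + fp))
        if tn + fn:
            assert m.npv_pct == pytest.approx(100 * tn / (tn + fn))
        if tp + fp:
            assert m.ppv_pct == pytest.approx(100 * tp / (tp + fp))

    def test_counts_match_brute_force_on_random_scores(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            scores = rng.uniform(size=40)
            labels = rng.binomial(1, 0.5, 40)
            thr = rng.uniform()
            m = clinical_metrics(scores, labels, thr)
            tp = sum(1 for s, l in zip(scores, labels) if s >= thr and l == 1)
            fp = sum(1 for s, l in zip(scores, labels) if s >= thr and l == 0)
            tn = sum(1 for s, l in zip(scores, labels) if s < thr and l == 0)
            fn = sum(1 for s, l in zip(scores, labels) if s < thr and l == 1)
            assert (m.tp, m.fp, m.tn, m.fn) == (tp, fp, tn, fn)

    def test_all_positive_degenerate_threshold(self):
        scores = np.array([0.2, 0.6, 0.9, 0.4])
        labels = np.array([0, 1, 1, 0])
        m = clinical_metrics(scores, labels, threshold=0.0)
        assert m.specificity_pct == 0.0
        assert m.sensitivity_pct == 100.0

    def test_report_is_human_readable(self):
        m = ThresholdMetrics.from_counts(tp=143, fp=404, tn=188, fn=8)
        text = m.report("demo")
        assert "31.8" in text and "95.9" in text and "318" in text


class TestTradeoff:
    def test_zero_gap_is_infinite(self):
        res = min_test_tradeoff(0.8, 0.8, prevalence=0.2)
        assert math.isinf(res.mtt)

    def test_doubling_gap_halves_default_mtt(self):
        a = min_test_tradeoff(0.82, 0.80, 0.2).mtt
        b = min_test_tradeoff(0.84, 0.80, 0.2).mtt
        assert a == pytest.approx(2 * b)

    def test_interval_endpoints_match_pointwise_evaluation(self):
        res = min_test_tradeoff(0.84, 0.80, 0.2, auc_uncertainty=0.01)
        lo = min_test_tradeoff(0.85, 0.80, 0.2).mtt
        hi = min_test_tradeoff(0.83, 0.80, 0.2).mtt
        assert res.mtt_range == pytest.approx((lo, hi))

    def test_monotone_in_gap_and_prevalence(self):
        assert (min_test_tradeoff(0.84, 0.80, 0.2).mtt
                < min_test_tradeoff(0.82, 0.80, 0.2).mtt)
        assert (min_test_tradeoff(0.84, 0.80, 0.3).mtt
                < min_test_tradeoff(0.84, 0.80, 0.2).mtt)

    def test_pluggable_formula(self):
        res = min_test_tradeoff(0.84, 0.80, 0.2,
                                formula=lambda gap, prev: 42.0)
        assert res.mtt == 42.0

    def test_invalid_arguments_rejected(self):
        with pytest.raises(ValueError):
            min_test_tradeoff(0.8, 0.9, 0.2)
        with pytest.raises(ValueError):
            min_test_tradeoff(0.9, 0.8, 0.0)
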