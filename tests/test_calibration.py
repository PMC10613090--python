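import math

import numpy as np
import pandas as pd
import pytest

from gacalib import (
    PredictorSpec,
    fit_calibration,
    predict_calibrated,
    theoretical_attenuation,
    trim_extreme_reference,
)
from gacalib.calibration import DEFAULT_Z_VARIABLES, CalibrationModel


def oracle_trim(values, lower_pct, upper_pct):
    """Independent nearest-rank oracle by exhaustive rank enumeration."""
    srt = sorted(values)
    n = len(srt)
    lo = srt[max(1, math.ceil(lower_pct / 100 * n)) - 1]
    hi = srt[max(1, math.ceil(upper_pct / 100 * n)) - 1]
    return [lo < v < hi for v in values], (lo, hi)


class TestTrimExtremeReference:
    def test_integers_1_to_1000(self):
        values = list(range(1, 1001))
        mask, (lo, hi) = trim_extreme_reference(values, 0.5, 99.5)
        # ranks ceil(0.005*1000)=5 and ceil(0.995*1000)=995; inclusive drops
        assert (lo, hi) == (5, 995)
        dropped = {v for v, keep in zip(values, mask) if not keep}
        assert dropped == set(range(1, 6)) | set(range(995, 1001))
        assert mask.sum() == 989

    def test_boundary_percentiles_0_100(self):
        mask, (lo, hi) = trim_extreme_reference([10, 20, 30], 0.0, 100.0)
        assert (lo, hi) == (10, 30)
        assert list(mask) == [False, True, False]

    def test_kept_values_strictly_inside_thresholds(self):
        rng = np.random.default_rng(0)
        values = rng.normal(38, 3, size=500)
        mask, (lo, hi) = trim_extreme_reference(values)
        kept = values[mask]
        assert (kept > lo).all() and (kept < hi).all()

    @pytest.mark.parametrize("lower,upper", [(0.5, 99.5), (1, 99), (5, 95), (0, 100), (2.5, 97.5)])
    def test_matches_rank_enumeration_oracle(self, lower, upper):
        rng = np.random.default_rng(7)
        for n in (10, 37, 250, 1000):
            values = rng.integers(0, 80, size=n).astype(float) + rng.random(n)
            mask, thresholds = trim_extreme_reference(values, lower, upper)
            exp_mask, exp_thresholds = oracle_trim(values, lower, upper)
            assert list(mask) == exp_mask
            assert thresholds == pytest.approx(exp_thresholds)

    def test_fewer_than_3_distinct_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            trim_extreme_reference([1.0, 1.0, 2.0, 2.0])

    def test_bad_percentiles_rejected(self):
        with pytest.raises(ValueError, match="percentile"):
            trim_extreme_reference([1, 2, 3], 60, 40)


def _frame(**cols):
    return pd.DataFrame(cols)


class TestFitCalibration:
    def test_identity_calibration(self):
        ga = np.linspace(30, 44, 40)
        cohort = _frame(ga_us=ga, ga_fh=ga)
        model = fit_calibration(cohort, PredictorSpec(q_measures=("fh",)), trim=False)
        assert model.intercept == pytest.approx(0.0, abs=1e-9)
        assert model.coefficients["ga_fh"] == pytest.approx(1.0, abs=1e-12)
        assert model.residual_sd == pytest.approx(0.0, abs=1e-9)

    def test_three_point_hand_solution(self):
        cohort = _frame(ga_us=[2.0, 4.0, 6.0], ga_fh=[1.0, 2.0, 3.0])
        model = fit_calibration(cohort, PredictorSpec(q_measures=("fh",)), trim=False)
        assert model.intercept == pytest.approx(0.0, abs=1e-10)
        assert model.coefficients["ga_fh"] == pytest.approx(2.0, rel=1e-12)
        assert model.n_fit == 3

    def test_attenuation_slope_on_synthetic(self, cohort_full_20k):
        model = fit_calibration(cohort_full_20k, PredictorSpec(q_measures=("fh",)), trim=False)
        expected = theoretical_attenuation(2.15, 1.2)
        assert expected == pytest.approx(0.7625, abs=1e-3)
        assert abs(model.coefficients["ga_fh"] - expected) < 0.02

    def test_matches_normal_equations_oracle_random_designs(self):
        rng = np.random.default_rng(123)
        for _ in range(20):
            n = int(rng.integers(12, 50))
            cohort = _frame(
                ga_us=rng.normal(38, 2, n),
                ga_fh=rng.normal(38, 2, n),
                ga_lmp=rng.normal(38, 3, n),
                maternal_age=rng.normal(25, 5, n),
                muac=rng.normal(27, 3, n),
                hb_enrol=rng.normal(11, 2, n),
            )
            spec = PredictorSpec(q_measures=("fh", "lmp"),
                                 z_variables=("maternal_age", "muac", "hb_enrol"))
            model = fit_calibration(cohort, spec, trim=False)
            X = np.column_stack([np.ones(n)] +
                                [cohort[c].to_numpy() for c in
                                 ("ga_fh", "ga_lmp", "maternal_age", "muac", "hb_enrol")])
            beta = np.linalg.solve(X.T @ X, X.T @ cohort.ga_us.to_numpy())
            got = np.array([model.intercept] + list(model.coefficients.values()))
            np.testing.assert_allclose(got, beta, rtol=1e-8)

    def test_categorical_encoding_first_level_reference(self):
        rng = np.random.default_rng(4)
        n = 200
        edu = rng.choice(["none", "primary", "secondary", "tertiary"], size=n)
        cohort = _frame(ga_us=rng.normal(38, 2, n), ga_fh=rng.normal(38, 2, n), education=edu)
        spec = PredictorSpec(q_measures=("fh",), z_variables=("education",))
        model = fit_calibration(cohort, spec, trim=False)
        assert set(model.coefficients) == {
            "ga_fh", "education[primary]", "education[secondary]", "education[tertiary]"}

    def test_insufficient_complete_cases_message(self):
        cohort = _frame(ga_us=[38.0, 39.0], ga_fh=[38.0, 39.0])
        with pytest.raises(ValueError, match="complete cases"):
            fit_calibration(cohort, PredictorSpec(q_measures=("fh",)), trim=False)

    def test_rank_deficiency_names_collinear_predictors(self):
        ga = np.linspace(30, 44, 30)
        cohort = _frame(ga_us=ga + 0.1, ga_fh=ga, ga_lmp=ga)  # fh == lmp
        with pytest.raises(ValueError, match="ga_lmp"):
            fit_calibration(cohort, PredictorSpec(q_measures=("fh", "lmp")), trim=False)

    def test_trimming_reduces_n_fit(self, cohort_full_20k):
        spec = PredictorSpec(q_measures=("fh",))
        trimmed = fit_calibration(cohort_full_20k, spec, trim=True)
        untrimmed = fit_calibration(cohort_full_20k, spec, trim=False)
        assert trimmed.n_fit < untrimmed.n_fit
        assert trimmed.n_trimmed > 0
        assert trimmed.trim_window is not None

    def test_in_sample_fitted_mean_equals_response_mean(self, cohort_full_20k):
        spec = PredictorSpec(q_measures=("fh",), z_variables=("maternal_age", "muac"))
        model = fit_calibration(cohort_full_20k, spec, trim=False)
        pred = predict_calibrated(model, cohort_full_20k)
        assert pred.mean() == pytest.approx(cohort_full_20k.ga_us.mean(), rel=1e-10)


class TestPredictCalibrated:
    def test_linear_arithmetic(self):
        model = CalibrationModel(
            predictor_spec=PredictorSpec(q_measures=("fh",)),
            intercept=5.0, coefficients={"ga_fh": 0.9}, residual_sd=1.0, n_fit=10)
        out = predict_calibrated(model, _frame(ga_fh=[40.0]))
        assert out.iloc[0] == pytest.approx(5.0 + 0.9 * 40.0)

    def test_missing_predictor_gives_missing_output(self):
        model = CalibrationModel(
            predictor_spec=PredictorSpec(q_measures=("fh",)),
            intercept=5.0, coefficients={"ga_fh": 0.9}, residual_sd=1.0, n_fit=10)
        out = predict_calibrated(model, _frame(ga_fh=[40.0, np.nan]))
        assert math.isnan(out.iloc[1])

    def test_predicts_records_without_ultrasound(self):
        cohort = _frame(ga_us=[38.0, 39.0, 40.0, 37.0, np.nan],
                        ga_fh=[38.0, 39.5, 40.0, 37.0, 41.0])
        model = fit_calibration(cohort, PredictorSpec(q_measures=("fh",)), trim=False)
        out = predict_calibrated(model, cohort)
        assert out.notna().all()

    def test_schema_mismatch_names_missing_columns(self):
        model = CalibrationModel(
            predictor_spec=PredictorSpec(q_measures=("fh",), z_variables=("muac",)),
            intercept=0.0, coefficients={"ga_fh": 1.0, "muac": 0.1}, residual_sd=1.0, n_fit=10)
        with pytest.raises(ValueError, match="muac"):
            predict_calibrated(model, _frame(ga_fh=[40.0]))

    def test_mean_prediction_equals_mean_response_over_fit_records(self, cohort_full_20k):
        # least-squares residuals sum to zero when an intercept is included
        spec = PredictorSpec(q_measures=("lmp",), z_variables=("maternal_age",))
        model = fit_calibration(cohort_full_20k, spec, trim=False)
        pred = predict_calibrated(model, cohort_full_20k)
        assert pred.mean() == pytest.approx(cohort_full_20k.ga_us.mean(), rel=1e-10)


class TestCalibrationInvariants:
    @pytest.fixture(scope="class")
    def fitted(self, cohort_full_20k):
        out = {}
        for name, qs in (("fh", ("fh",)), ("lmp", ("lmp",)), ("joint", ("fh", "lmp"))):
            spec = PredictorSpec(q_measures=qs, z_variables=DEFAULT_Z_VARIABLES)
            model = fit_calibration(cohort_full_20k, spec, trim=True)
            out[name] = predict_calibrated(model, cohort_full_20k)
        return out

    def test_variance_shrinkage(self, cohort_full_20k, fitted):
        assert fitted["fh"].std() <= cohort_full_20k.ga_fh.std()
        assert fitted["lmp"].std() <= cohort_full_20k.ga_lmp.std()

    def test_monotone_validity(self, cohort_full_20k, fitted):
        us = cohort_full_20k.ga_us
        rho_cal_fh = np.corrcoef(fitted["fh"], us)[0, 1]
        rho_cal_lmp = np.corrcoef(fitted["lmp"], us)[0, 1]
        rho_joint = np.corrcoef(fitted["joint"], us)[0, 1]
        assert rho_cal_fh >= abs(np.corrcoef(cohort_full_20k.ga_fh, us)[0, 1]) - 1e-3
        assert rho_cal_lmp >= abs(np.corrcoef(cohort_full_20k.ga_lmp, us)[0, 1]) - 1e-3
        assert rho_joint >= rho_cal_fh - 1e-3
        assert rho_joint >= rho_cal_lmp - 1e-3

    def test_parameter_recovery_slope_one(self, cohort_full_20k, fitted):
        # regressing the latent truth on calibrated GA gives slope ~ 1
        for name in ("fh", "lmp", "joint"):
            slope = np.polyfit(fitted[name], cohort_full_20k.T_true, 1)[0]
            assert slope == pytest.approx(1.0, abs=0.05)
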