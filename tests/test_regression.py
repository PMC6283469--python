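"""Design construction, candidate screening, stepwise and penalized fits."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vlab import (CohortSpec, FittedClusterModel, build_design,
                  cross_correlation_screen, fit_penalized, fit_stepwise_ml,
                  generate_cohort, predict_pain, validate_holdout)
from vlab.equations import CLUSTER_COEFFS, coeffs_by_column
from vlab.preprocess import interpolate_series


def series_frame(pid, pain, prsi, dose):
    T = len(pain) - 1
    return pd.DataFrame({
        "patient_id": pid, "week": range(T + 1), "pain": pain, "prsi": prsi,
        "dose_mg": dose, "feel_calm": 3.0, "feel_energy": 4.0, "feel_sad": 4.0,
        "observed": True})


def patient_row(pid, **kw):
    base = dict(patient_id=pid, source="RCT", gender="M", age_years=50,
                age_group="45-64", bmi=27.0, bmi_group="overweight", insulin=0,
                depression=0, gabapentin=0, monotherapy=1,
                pdpn_duration_group="0-5", baseline_pain=6.0, baseline_prsi=5.0,
                feel_calm=3, feel_energy=4, feel_sad=4, duration_weeks=6,
                true_cluster=1)
    base.update(kw)
    return base


class TestBuildDesign:
    def test_lag3_limits_rows_to_weeks_3_to_6(self):
        patients = pd.DataFrame([patient_row("A")])
        series = series_frame("A", [6, 5, 5, 4, 4, 3, 3], [5] * 7, [150] * 7)
        design = build_design(patients, series)
        assert sorted(design["week"]) == [3, 4, 5, 6]

    def test_dose_lag_lookup(self):
        dose = [150, 150, 300, 300, 300, 300, 300]
        patients = pd.DataFrame([patient_row("A")])
        series = series_frame("A", [6, 5, 5, 4, 4, 3, 3], [5] * 7, dose)
        design = build_design(patients, series).set_index("week")
        assert design.loc[5, "dose_lag3"] == 300  # dose at week 2
        assert design.loc[3, "dose_lag3"] == 150  # dose at week 0

    def test_row_values_match_hand_built_table(self):
        pain = [6.0, 5.5, 5.0, 4.5, 4.0, 3.5, 3.0]
        prsi = [5.0, 4.8, 4.6, 4.4, 4.2, 4.0, 3.8]
        patients = pd.DataFrame([patient_row("A", age_group="75+")])
        series = series_frame("A", pain, prsi, [150] * 7)
        row = build_design(patients, series).set_index("week").loc[4]
        assert row["pain_lag1"] == pytest.approx(4.5)
        assert row["prsi_lag0"] == pytest.approx(4.2)
        assert row["prsi_lag3"] == pytest.approx(4.8)
        assert row["age_75plus"] == 1.0
        assert row["feel_energy_t0"] == 4.0
        assert row["y"] == pytest.approx(4.0)


class TestScreen:
    def make_design(self, n=200, seed=0):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=n)
        noise = rng.normal(size=n)
        return pd.DataFrame({"y": x, "self": x, "noise": noise})

    def test_self_correlation_is_one(self):
        screen = cross_correlation_screen(self.make_design())
        assert screen.set_index("candidate").loc["self", "r"] == pytest.approx(1.0)

    def test_independent_noise_is_small(self):
        screen = cross_correlation_screen(self.make_design(n=2000))
        assert abs(screen.set_index("candidate").loc["noise", "r"]) < 0.1

    def test_ar1_lag_correlation_matches_closed_form(self):
        """For a stationary AR(1) with coefficient phi, corr(x_t, x_{t-1}) = phi."""
        rng = np.random.default_rng(3)
        phi, n = 0.7, 40_000
        x = np.empty(n)
        x[0] = rng.normal()
        for t in range(1, n):
            x[t] = phi * x[t - 1] + rng.normal() * np.sqrt(1 - phi ** 2)
        design = pd.DataFrame({"y": x[1:], "lag1": x[:-1]})
        screen = cross_correlation_screen(design)
        assert screen.set_index("candidate").loc["lag1", "r"] == pytest.approx(
            phi, abs=0.02)

    def test_constant_candidate_warns_zero(self):
        design = self.make_design()
        design["const"] = 1.0
        with pytest.warns(UserWarning, match="const"):
            screen = cross_correlation_screen(design)
        assert screen.set_index("candidate").loc["const", "r"] == 0.0


def synthetic_design(coeffs, n, noise_sd, seed):
    """Rows drawn from realistic predictor ranges; y from the given equation."""
    rng = np.random.default_rng(seed)
    design = pd.DataFrame({
        "pain_lag1": rng.uniform(0, 10, n),
        "prsi_lag0": rng.uniform(0, 10, n),
        "prsi_lag3": rng.uniform(0, 10, n),
        "dose_lag3": rng.choice([75, 150, 300, 600], n).astype(float),
        "age_75plus": (rng.random(n) < 0.065).astype(float),
        "feel_calm_t0": rng.integers(1, 7, n).astype(float),
        "feel_energy_t0": rng.integers(1, 7, n).astype(float),
    })
    y = np.zeros(n)
    for name, b in coeffs.items():
        y += b * design[name].to_numpy()
    design["y"] = y + rng.normal(0, noise_sd, n)
    return design


class TestStepwise:
    def test_recovers_single_true_predictor(self):
        rng = np.random.default_rng(4)
        n = 300
        design = pd.DataFrame({"x1": rng.uniform(0, 10, n),
                               "junk": rng.normal(size=n)})
        design["y"] = 0.7 * design["x1"] + rng.normal(0, 0.05, n)
        model = fit_stepwise_ml(design)
        assert set(model.coefficients) == {"x1"}
        assert model.coefficients["x1"] == pytest.approx(0.7, abs=0.05)

    def test_pure_noise_keeps_empty_model(self):
        rng = np.random.default_rng(5)
        n = 200
        design = pd.DataFrame({"a": rng.normal(size=n), "b": rng.normal(size=n)})
        design["y"] = rng.normal(size=n)
        model = fit_stepwise_ml(design, p_enter=0.01)
        assert model.coefficients == {} or all(
            abs(v) < 0.2 for v in model.coefficients.values())

    def test_cluster1_generator_selects_true_predictors(self):
        """Data from the cluster-1 equation at noise SD 0.5, n = 400: the
        selected set stays within the true support {x1, x2, x4, x6}."""
        design = synthetic_design(coeffs_by_column(1), 400, 0.5, seed=6)
        model = fit_stepwise_ml(design)
        true_support = {"pain_lag1", "prsi_lag0", "dose_lag3", "feel_calm_t0"}
        assert set(model.coefficients) <= true_support
        assert model.coefficients["pain_lag1"] == pytest.approx(0.6229, abs=0.05)


class TestPenalized:
    def test_total_shrinkage_at_huge_lambda(self):
        design = synthetic_design(coeffs_by_column(1), 200, 0.3, seed=7)
        model = fit_penalized(design, lambda_=1e6)
        assert model.coefficients == {}

    def test_lambda_zero_matches_ols(self):
        design = synthetic_design(coeffs_by_column(1), 200, 0.3, seed=8)
        model = fit_penalized(design, lambda_=0.0)
        X = design[list(model.coefficients)].to_numpy()
        beta_ols, *_ = np.linalg.lstsq(X, design["y"].to_numpy(), rcond=None)
        np.testing.assert_allclose(list(model.coefficients.values()), beta_ols,
                                   atol=1e-6)

    def test_three_penalties_agree_on_clean_fixture(self):
        """LASSO, adaptive LASSO, and elastic net land on near-identical
        coefficient vectors when the signal is strong."""
        design = synthetic_design(coeffs_by_column(1), 500, 0.3, seed=9)
        fits = {m: fit_penalized(design, method=m, random_state=0)
                for m in ("lasso", "adaptive_lasso", "elastic_net")}
        for name in ("pain_lag1", "prsi_lag0"):
            vals = [f.coefficients.get(name, 0.0) for f in fits.values()]
            assert max(vals) - min(vals) < 0.05

    def test_lasso_path_support_shrinks_with_lambda(self):
        design = synthetic_design(coeffs_by_column(1), 300, 0.4, seed=10)
        sizes = [len(fit_penalized(design, lambda_=lam).coefficients)
                 for lam in (0.001, 0.01, 0.1, 1.0, 10.0)]
        assert sizes == sorted(sizes, reverse=True)


class TestPredict:
    def test_no_intercept_null(self):
        model = FittedClusterModel(1, "ref", coeffs_by_column(1), 1.0, 0.0)
        values = {k: 0.0 for k in model.coefficients}
        assert predict_pain(model, values) == 0.0

    def test_printed_coefficient_arithmetic(self):
        model = FittedClusterModel(1, "ref", coeffs_by_column(1), 1.0, 0.0)
        values = {"pain_lag1": 6, "prsi_lag0": 5, "dose_lag3": 300,
                  "feel_calm_t0": 3}
        expected = 0.6229 * 6 + 0.2461 * 5 + 0.0002 * 300 + 0.0354 * 3
        assert predict_pain(model, values) == pytest.approx(expected)

    def test_cluster2_prsi_lag3_is_protective(self):
        """Raising PRSI(t-3) lowers predicted pain (negative coefficient)."""
        model = FittedClusterModel(2, "ref", coeffs_by_column(2), 1.0, 0.0)
        base = {"pain_lag1": 6, "prsi_lag0": 5, "prsi_lag3": 4,
                "dose_lag3": 300, "age_75plus": 0, "feel_calm_t0": 3}
        hi = dict(base, prsi_lag3=8)
        assert predict_pain(model, hi) < predict_pain(model, base)

    def test_missing_predictor_named(self):
        model = FittedClusterModel(1, "ref", coeffs_by_column(1), 1.0, 0.0)
        with pytest.raises(ValueError, match="prsi_lag0"):
            predict_pain(model, {"pain_lag1": 5})

    @settings(max_examples=30, deadline=None)
    @given(st.floats(-5, 5))
    def test_linear_in_inputs(self, a):
        model = FittedClusterModel(1, "ref", coeffs_by_column(1), 1.0, 0.0)
        v = {"pain_lag1": 6.0, "prsi_lag0": 5.0, "dose_lag3": 300.0,
             "feel_calm_t0": 3.0}
        scaled = {k: a * x for k, x in v.items()}
        assert predict_pain(model, scaled) == pytest.approx(
            a * predict_pain(model, v), rel=1e-9, abs=1e-9)


class TestValidation:
    def make_cohort(self, seed):
        weights = [0.0] * 6
        weights[0] = 1.0
        spec = CohortSpec(n_os=80, n_rct=0, seed=seed, noise_sd=0.4,
                          cluster_weights=tuple(weights))
        patients, series = generate_cohort(spec)
        return patients, interpolate_series(series)

    def test_perfect_predictions(self):
        patients, series = self.make_cohort(seed=31)
        model = FittedClusterModel(1, "ref", coeffs_by_column(1), 1.0, 0.0)
        # predictions from the generating equation on imputed data: high R2
        labels = pd.Series(1, index=patients["patient_id"])
        report = validate_holdout({1: model}, patients, series, labels)
        assert report[1]["r2"] >= 0.9
        assert report[1]["t_pvalue"] > 0.05

    def test_constant_shift_rejected_by_t_test(self):
        patients, series = self.make_cohort(seed=32)
        shifted = dict(coeffs_by_column(1))
        shifted["feel_calm_t0"] = shifted.get("feel_calm_t0", 0.0) + 2.0
        model = FittedClusterModel(1, "ref", shifted, 1.0, 0.0)
        labels = pd.Series(1, index=patients["patient_id"])
        report = validate_holdout({1: model}, patients, series, labels)
        assert report[1]["t_pvalue"] < 0.01

    def test_absent_cluster_skipped_with_warning(self):
        patients, series = self.make_cohort(seed=33)
        model = FittedClusterModel(9, "ref", coeffs_by_column(1), 1.0, 0.0)
        labels = pd.Series(1, index=patients["patient_id"])
        with pytest.warns(UserWarning, match="cluster 9"):
            report = validate_holdout({9: model}, patients, series, labels)
        assert report == {}
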