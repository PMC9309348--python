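"""Latent-trait bias/precision estimation: limits, exact cases, recovery."""

import numpy as np
import pandas as pd
import pytest
from sklearn.base import clone

from bpagree import (
    CohortData,
    SimConfig,
    TaffeEstimator,
    bias_plot_data,
    estimate_bias,
    estimate_precision,
    evaluate_bias,
    fit_reference_model,
    simulate_cohort,
)
from bpagree.taffe import BiasFit
from conftest import make_cohort


def _latent_trait_cohort(
    rng,
    n_patients=30,
    n_ref=40,
    n_test=20,
    alpha=10.0,
    beta=0.9,
    ref_sd=5.0,
    test_sd=7.0,
    test_sd_slope=0.0,
):
    """Cohort drawn from the estimator's own model: constant latent per patient."""
    rows = []
    t0 = pd.Timestamp("2022-03-01 08:00")
    for i in range(n_patients):
        x = 130 + 12 * rng.standard_normal()
        for j in range(n_ref):
            rows.append(
                (f"P{i:02d}", "reference", t0 + pd.Timedelta(minutes=15 * j),
                 x + ref_sd * rng.standard_normal())
            )
        sd = test_sd + test_sd_slope * (x - 130)
        for j in range(n_test):
            rows.append(
                (f"P{i:02d}", "test", t0 + pd.Timedelta(minutes=1 + 30 * j),
                 alpha + beta * x + max(sd, 0.5) * rng.standard_normal())
            )
    df = pd.DataFrame(rows, columns=["patient_id", "device", "time", "sbp"])
    df["dbp"] = 0.6 * df["sbp"]
    return CohortData(df)


class TestReferenceModel:
    def test_noiseless_reference_has_no_shrinkage(self):
        cohort = make_cohort(
            [
                ("A", "reference", "09:00", 120, 80),
                ("A", "reference", "09:15", 120, 80),
                ("B", "reference", "09:00", 140, 90),
                ("B", "reference", "09:15", 140, 90),
            ]
        )
        model = fit_reference_model(cohort, "sbp")
        assert model.sigma1_2 == 0.0
        assert (model.stats["lam"] == 1.0).all()
        np.testing.assert_allclose(model.blup, [120.0, 140.0])

    def test_identical_patients_shrink_fully(self):
        cohort = make_cohort(
            [
                ("A", "reference", "09:00", 130, 80),
                ("A", "reference", "09:15", 130, 80),
                ("B", "reference", "09:00", 130, 80),
                ("B", "reference", "09:15", 130, 80),
            ]
        )
        model = fit_reference_model(cohort, "sbp")
        assert model.tau2 == 0.0
        np.testing.assert_allclose(model.blup, model.mu)

    def test_blup_between_mu_and_patient_mean(self, rng):
        cohort = _latent_trait_cohort(rng)
        model = fit_reference_model(cohort, "sbp")
        lo = np.minimum(model.mu, model.stats["mean_ref"])
        hi = np.maximum(model.mu, model.stats["mean_ref"])
        assert ((model.blup >= lo - 1e-9) & (model.blup <= hi + 1e-9)).all()
        assert model.stats["lam"].between(0, 1).all()

    def test_single_reading_everywhere_unidentifiable(self):
        cohort = make_cohort(
            [("A", "reference", "09:00", 120, 80), ("B", "reference", "09:00", 140, 90)]
        )
        with pytest.raises(ValueError, match="unidentifiable"):
            fit_reference_model(cohort, "sbp")

    def test_variance_component_recovery(self):
        # method-of-moments recovery of the generator's variance components
        taus, sigmas = [], []
        for seed in range(5):
            cohort, _ = simulate_cohort(SimConfig(seed=100 + seed))
            model = fit_reference_model(cohort, "sbp")
            taus.append(np.sqrt(model.tau2))
            sigmas.append(np.sqrt(model.sigma1_2))
        assert abs(np.mean(taus) - 12.0) / 12.0 < 0.25
        # marginal within-patient SD: fluctuation + device noise + dip mixture
        expected = np.sqrt(19.1**2 + 4.0**2 + 0.2 * 0.8 * 12.0**2)
        assert abs(np.mean(sigmas) - expected) / expected < 0.05


class TestBiasEstimation:
    def test_exact_affine_device_recovered_exactly(self, affine_exact_cohort):
        cohort, _ = affine_exact_cohort
        model = fit_reference_model(cohort, "sbp")
        fit = estimate_bias(model, cohort, "sbp", n_boot=50, seed=0)
        assert fit.alpha == pytest.approx(20.0, abs=1e-8)
        assert fit.beta == pytest.approx(0.8, abs=1e-10)

    def test_identity_device_under_latent_trait_model(self, rng):
        cohort = _latent_trait_cohort(rng, alpha=0.0, beta=1.0, test_sd=4.0)
        model = fit_reference_model(cohort, "sbp")
        fit = estimate_bias(model, cohort, "sbp", n_boot=0)
        assert abs(fit.alpha) < 8.0
        assert abs(fit.beta - 1.0) < 0.06

    def test_bootstrap_ci_brackets_point_estimate(self, rng):
        cohort = _latent_trait_cohort(rng)
        model = fit_reference_model(cohort, "sbp")
        fit = estimate_bias(model, cohort, "sbp", n_boot=300, seed=2)
        assert fit.alpha_ci[0] <= fit.alpha <= fit.alpha_ci[1]
        assert fit.beta_ci[0] <= fit.beta <= fit.beta_ci[1]
        assert fit.n_boot_failed == 0

    def test_constant_blups_unidentifiable(self):
        cohort = make_cohort(
            [("A", "reference", "09:00", 130, 80), ("A", "reference", "09:15", 130, 80),
             ("B", "reference", "09:00", 130, 80), ("B", "reference", "09:15", 130, 80)]
            + [("A", "test", f"1{h}:01", 120, 78) for h in range(5)]
            + [("B", "test", f"1{h}:02", 125, 79) for h in range(5)]
        )
        model = fit_reference_model(cohort, "sbp")
        with pytest.raises(ValueError, match="unidentifiable"):
            estimate_bias(model, cohort, "sbp", n_boot=0)

    def test_equivariance_under_constant_shift(self, affine_exact_cohort):
        cohort, _ = affine_exact_cohort
        shift = 25.0
        shifted = cohort.frame.copy()
        shifted["sbp"] = shifted["sbp"] + shift
        shifted = CohortData(shifted)
        m0 = fit_reference_model(cohort, "sbp")
        m1 = fit_reference_model(shifted, "sbp")
        f0 = estimate_bias(m0, cohort, "sbp", n_boot=0)
        f1 = estimate_bias(m1, shifted, "sbp", n_boot=0)
        assert f1.beta == pytest.approx(f0.beta, abs=1e-9)
        assert f1.alpha == pytest.approx(f0.alpha + shift * (1 - f0.beta), abs=1e-7)


class TestBiasCurve:
    def _fit(self, alpha, beta):
        return BiasFit(
            variable="sbp", alpha=alpha, beta=beta,
            alpha_ci=(np.nan, np.nan), beta_ci=(np.nan, np.nan),
            n_test=100, blup_range=(80.0, 180.0),
            boot_alpha=np.empty(0), boot_beta=np.empty(0),
        )

    def test_identity_has_zero_bias(self):
        assert evaluate_bias(self._fit(0.0, 1.0), 137.0) == 0.0

    def test_anchored_systolic_bias_values(self):
        fit = self._fit(50.1, 0.65)
        assert evaluate_bias(fit, 112.0) == pytest.approx(10.9, abs=0.05)
        assert fit.zero_bias_point == pytest.approx(143.1, abs=0.1)
        assert evaluate_bias(fit, 156.0) == pytest.approx(-4.5, abs=0.1)

    def test_anchored_diastolic_overestimates_everywhere_observed(self):
        fit = self._fit(26.5, 0.76)
        assert evaluate_bias(fit, 80.0) == pytest.approx(7.3, abs=0.05)
        for x in (50.0, 70.0, 90.0, 110.0):
            assert fit.bias(x) > 0

    def test_extrapolation_warns(self):
        with pytest.warns(UserWarning, match="extrapolation"):
            evaluate_bias(self._fit(0.0, 1.0), 300.0)

    def test_bias_plot_table_contract(self, affine_exact_cohort):
        cohort, _ = affine_exact_cohort
        model = fit_reference_model(cohort, "sbp")
        fit = estimate_bias(model, cohort, "sbp", n_boot=50, seed=0)
        table = bias_plot_data(model, fit, grid_size=100)
        assert len(table) == 100
        assert table["x_blup"].is_monotonic_increasing
        np.testing.assert_allclose(table["identity"], table["x_blup"])
        # bias crosses zero at alpha / (1 - beta) = 20 / 0.2 = 100
        sign_change = np.sign(table["bias"]).diff().abs() > 0
        if sign_change.any():
            crossing = table.loc[sign_change, "x_blup"].iloc[0]
            assert abs(crossing - 100.0) < 2.0


class TestPrecision:
    def test_homoscedastic_recovery_within_tolerance(self):
        sd_ref, sd_test = [], []
        for seed in range(3):
            cohort = _latent_trait_cohort(np.random.default_rng(seed))
            model = fit_reference_model(cohort, "sbp")
            fit = estimate_bias(model, cohort, "sbp", n_boot=0)
            prec = estimate_precision(model, fit, cohort, "sbp")
            sd_ref.append(prec.grid["sd_ref"].mean())
            sd_test.append(prec.grid["sd_test"].mean())
        assert abs(np.mean(sd_ref) - 5.0) / 5.0 < 0.15
        assert abs(np.mean(sd_test) - 7.0) / 7.0 < 0.15

    def test_zero_noise_device_sd_is_floor_level(self, affine_exact_cohort):
        cohort, _ = affine_exact_cohort
        model = fit_reference_model(cohort, "sbp")
        fit = estimate_bias(model, cohort, "sbp", n_boot=0)
        prec = estimate_precision(model, fit, cohort, "sbp")
        assert (prec.grid["sd_test"] < 0.01).all()
        assert (prec.grid["sd_ref"] < 0.01).all()

    def test_heteroscedastic_slope_sign_recovered(self):
        signs = []
        for seed in range(3):
            cohort = _latent_trait_cohort(
                np.random.default_rng(50 + seed), test_sd=6.0, test_sd_slope=0.4
            )
            model = fit_reference_model(cohort, "sbp")
            fit = estimate_bias(model, cohort, "sbp", n_boot=0)
            prec = estimate_precision(model, fit, cohort, "sbp")
            signs.append(prec.coef["test"][1] > 0)
        assert all(signs)


class TestEstimatorAPI:
    def test_sklearn_conventions(self, affine_exact_cohort):
        cohort, _ = affine_exact_cohort
        est = TaffeEstimator(variable="sbp", n_boot=20, random_state=0)
        cloned = clone(est)
        assert cloned.get_params() == est.get_params()
        est.fit(cohort)
        assert hasattr(est, "alpha_") and hasattr(est, "beta_")
        assert est.predict(100.0) == pytest.approx(20.0 + 0.8 * 100.0, abs=1e-6)
        assert est.bias(100.0) == pytest.approx(0.0, abs=1e-6)
        assert len(est.precision_table()) == est.grid_size

    def test_set_params_roundtrip(self):
        est = TaffeEstimator().set_params(variable="dbp", n_boot=10)
        assert est.get_params()["variable"] == "dbp"
        assert est.get_params()["n_boot"] == 10
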