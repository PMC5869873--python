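"""Mixed-effects concentration-effect models: fitting, selection, bootstrap,
covariate screening, heart-rate model."""

import numpy as np
import pandas as pd
import pytest

from cqtpipe import exposure_response as er
from cqtpipe import fit_cqt, fit_hr_model, screen_covariates, select_model
from cqtpipe.errors import InsufficientDataError, ValidationError

from conftest import make_emax_cqt, make_null_cqt


class TestFitCqt:
    def test_noise_free_linear_recovered_exactly(self):
        rng = np.random.default_rng(0)
        rows = []
        for i in range(10):
            conc = rng.uniform(0, 3000, 8)
            rows.append(pd.DataFrame({"subject_id": f"S{i}", "conc_nM": conc,
                                      "value": 2.0 + 0.001 * conc}))
        fit = fit_cqt(pd.concat(rows, ignore_index=True), "linear", compute_se=False)
        assert fit.theta["intercept"] == pytest.approx(2.0, abs=1e-6)
        assert fit.theta["slope"] == pytest.approx(0.001, abs=1e-9)

    def test_nested_forms_never_fit_worse(self):
        """Richer nested models attain an OFV no larger than their parent."""
        obs = make_null_cqt(np.random.default_rng(1), n_subjects=30)
        fits = {f: fit_cqt(obs, f, compute_se=False) for f in er.FORMS}
        tol = 1e-4
        assert fits["linear"].ofv <= fits["no_effect"].ofv + tol
        assert fits["sigmoid_emax"].ofv <= fits["emax"].ofv + tol
        assert fits["emax"].ofv <= fits["no_effect"].ofv + tol

    def test_no_effect_moments_agree_with_method_of_moments(self):
        """Intercept ~ grand mean of subject means; omega ~ between-subject SD."""
        rng = np.random.default_rng(2)
        obs = make_null_cqt(rng, n_subjects=200, n_obs=10, omega=7.17, sigma=6.5,
                            intercept=1.5)
        fit = fit_cqt(obs, "no_effect", compute_se=False)
        sub_means = obs.groupby("subject_id")["value"].mean()
        assert fit.theta["intercept"] == pytest.approx(sub_means.mean(), abs=0.2)
        assert fit.omega == pytest.approx(7.17, rel=0.15)
        assert fit.sigma == pytest.approx(6.5, rel=0.1)

    def test_emax_parameters_recovered_within_20pct(self):
        """Median recovery over 100 simulated cohorts of 100 subjects."""
        emaxes, ec50s = [], []
        for seed in range(100):
            obs = make_emax_cqt(np.random.default_rng(10_000 + seed))
            f = fit_cqt(obs, "emax", compute_se=False)
            emaxes.append(f.theta["emax"])
            ec50s.append(f.theta["ec50"])
        assert np.median(emaxes) == pytest.approx(10.0, rel=0.20)
        assert np.median(ec50s) == pytest.approx(1000.0, rel=0.20)

    def test_single_subject_rejected(self):
        obs = pd.DataFrame({"subject_id": "S1", "conc_nM": [0.0, 1.0], "value": [0.0, 1.0]})
        with pytest.raises(InsufficientDataError):
            fit_cqt(obs, "no_effect")

    def test_standard_errors_are_finite_and_scaled(self):
        obs = make_null_cqt(np.random.default_rng(3))
        fit = fit_cqt(obs, "linear")
        assert np.isfinite(fit.se["slope"]) and fit.se["slope"] > 0
        assert np.isfinite(fit.se["intercept"])
        lo, hi = fit.wald_ci("slope")
        assert lo < fit.theta["slope"] < hi


class TestSelectModel:
    def test_identical_ofv_prefers_fewer_parameters(self):
        a = er.CqtModelFit(form="no_effect", ofv=100.0, converged=True)
        b = er.CqtModelFit(form="linear", ofv=100.0, converged=True)
        assert select_model([a, b]).form == "no_effect"

    def test_large_improvement_selects_richer_model(self):
        a = er.CqtModelFit(form="no_effect", ofv=100.0, converged=True)
        b = er.CqtModelFit(form="linear", ofv=90.0, converged=True)
        assert select_model([a, b]).form == "linear"

    def test_empty_candidate_list_rejected(self):
        with pytest.raises(ValidationError):
            select_model([])


class TestBootstrap:
    def test_single_replicate_ci_collapses(self):
        obs = make_null_cqt(np.random.default_rng(4), n_subjects=20)
        boot = er.bootstrap_cqt(obs, "linear", B=1, seed=9)
        p = boot["parameters"]
        assert (p["p5"] == p["median"]).all() and (p["p95"] == p["median"]).all()

    def test_median_tracks_point_estimate(self):
        rng = np.random.default_rng(5)
        obs = make_null_cqt(rng, n_subjects=40, slope=0.002)
        fit = fit_cqt(obs, "linear", compute_se=False)
        boot = er.bootstrap_cqt(obs, "linear", B=200, seed=6)
        reps = boot["replicates"]["slope"]
        boot_se = reps.std(ddof=1)
        assert abs(boot["parameters"].loc["slope", "median"] - fit.theta["slope"]) <= boot_se

    def test_deterministic_given_seed(self):
        obs = make_null_cqt(np.random.default_rng(6), n_subjects=15)
        b1 = er.bootstrap_cqt(obs, "linear", B=20, seed=3)
        b2 = er.bootstrap_cqt(obs, "linear", B=20, seed=3)
        pd.testing.assert_frame_equal(b1["parameters"], b2["parameters"])


class TestCovariateScreening:
    @staticmethod
    def _with_covariates(obs, rng, sex_shift=0.0):
        subjects = obs["subject_id"].unique()
        sex = pd.Series(rng.integers(0, 2, len(subjects)).astype(float), index=subjects)
        bmi = pd.Series(rng.normal(27, 4, len(subjects)), index=subjects)
        ecog = pd.Series(rng.integers(0, 2, len(subjects)).astype(float), index=subjects)
        out = obs.copy()
        out["sex"] = out["subject_id"].map(sex)
        out["bmi"] = out["subject_id"].map(bmi)
        out["ecog"] = out["subject_id"].map(ecog)
        out["value"] = out["value"] + sex_shift * out["sex"]
        return out

    def test_constant_covariate_skipped(self):
        obs = make_null_cqt(np.random.default_rng(7), n_subjects=20)
        obs["sex"] = 1.0  # all-female cohort
        obs["bmi"] = np.random.default_rng(1).normal(27, 4, len(obs))
        obs["ecog"] = 0.0
        res = screen_covariates(obs, form="no_effect")
        assert "sex" in res["skipped"] and "ecog" in res["skipped"]
        assert "sex" not in res["retained"]

    def test_injected_sex_shift_detected(self):
        rng = np.random.default_rng(8)
        obs = self._with_covariates(make_null_cqt(rng), rng, sex_shift=10.0)
        res = screen_covariates(obs, form="no_effect")
        assert "sex" in res["retained"]

    def test_null_covariates_rarely_retained(self):
        retained = 0
        for seed in range(20):
            rng = np.random.default_rng(900 + seed)
            obs = self._with_covariates(make_null_cqt(rng, n_subjects=30), rng)
            res = screen_covariates(obs, form="no_effect")
            retained += bool(res["retained"])
        assert retained <= 3  # ~1% per test under the null


class TestHrModel:
    def test_zero_variance_hr_exact_intercept(self):
        obs = pd.DataFrame({
            "subject_id": np.repeat([f"S{i}" for i in range(5)], 4),
            "conc_nM": np.tile([0.0, 100.0, 500.0, 1000.0], 5),
            "value": 75.0,
        })
        best, _ = fit_hr_model(obs)
        assert best.theta["intercept"] == pytest.approx(75.0, abs=1e-9)
        assert best.omega == pytest.approx(0.0, abs=1e-6)

    def test_population_heart_rate_recovered(self):
        """HR about 75 bpm with no drug effect: median intercept within 1 bpm."""
        ests = []
        for seed in range(10):
            rng = np.random.default_rng(30 + seed)
            obs = make_null_cqt(rng, n_subjects=50, omega=6.0, sigma=5.0, intercept=75.0)
            best, _ = fit_hr_model(obs)
            ests.append(best.theta["intercept"])
        assert np.median(ests) == pytest.approx(75.0, abs=1.0)

    def test_injected_concentration_effect_rejects_no_effect(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(60 + seed)
            obs = make_null_cqt(rng, n_subjects=50, omega=6.0, sigma=5.0,
                                intercept=75.0, slope=0.004)
            best, _ = fit_hr_model(obs)
            hits += best.form != "no_effect"
        assert hits >= 9
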