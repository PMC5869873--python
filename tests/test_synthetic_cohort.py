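"""Virtual-cohort generator: PK superposition, QT/RR physiology, determinism."""

import math

import numpy as np
import pandas as pd
import pytest

from cqtpipe import (
    CohortConfig,
    DrugEffectSpec,
    EcgPhysiology,
    PkParameters,
    StudyDesign,
    cmax_tmax,
    estimate_individual_exponent,
    generate_cohort,
    one_compartment_conc,
    simulate_ecg,
    simulate_pk_profile,
)
from cqtpipe.errors import ConfigError, DegenerateParameterError


class TestPkSimulation:
    def test_zero_dose_gives_zero_concentrations(self):
        params = PkParameters(dose_mg=0.0, bsv_cv=0.0)
        prof = simulate_pk_profile(params, StudyDesign(n_subjects=1), subject_seed=0)
        assert (prof["conc_nM"] == 0.0).all()

    def test_single_dose_auc_matches_dose_over_clearance(self):
        """AUC(0-inf) of the simulated curve equals F*Dose/CL (times the nM
        conversion) -- the closed-form one-compartment identity."""
        params = PkParameters(bsv_cv=0.0)
        t = np.linspace(0.0, 24.0 * 14, 20000)
        c = one_compartment_conc(t, [0.0], params.dose_mg, params.ka,
                                 params.CL_F, params.V_F, params.mw_scale)
        auc = np.trapezoid(c, t)
        expected = params.dose_mg / params.CL_F * params.mw_scale
        assert auc == pytest.approx(expected, rel=1e-3)

    def test_population_median_tmax_on_day1_grid_is_4h(self):
        """With calibrated defaults the median first-dose Tmax over 500
        subjects lands on the 4 h grid point."""
        params = PkParameters()
        design = StudyDesign(n_subjects=1)
        root = np.random.SeedSequence(42)
        tmaxes = []
        for ss in root.spawn(500):
            prof = simulate_pk_profile(params, design, ss)
            day1 = prof[prof["day"] == 1]
            _, tmax = cmax_tmax(day1["time_h"].to_numpy(), day1["conc_nM"].to_numpy())
            tmaxes.append(tmax)
        assert np.median(tmaxes) == 4.0

    def test_cmax_between_subject_cv_converges_to_target(self):
        """One shared log-normal deviate on CL and V scales the whole profile,
        so the Cmax CV converges to bsv_cv (n = 2000)."""
        params = PkParameters(bsv_cv=0.41)
        design = StudyDesign(n_subjects=1)
        root = np.random.SeedSequence(7)
        cmaxes = []
        for ss in root.spawn(2000):
            prof = simulate_pk_profile(params, design, ss)
            day1 = prof[prof["day"] == 1]
            cmaxes.append(day1["conc_nM"].max())
        cv = np.std(cmaxes, ddof=1) / np.mean(cmaxes)
        assert cv == pytest.approx(0.41, abs=0.04)

    def test_ka_equal_ke_rejected(self):
        with pytest.raises(DegenerateParameterError):
            PkParameters(ka=0.05, CL_F=1.0, V_F=20.0)  # ke = 0.05 == ka

    def test_empty_dosing_schedule_rejected(self):
        design = StudyDesign(n_subjects=1, dosing_schedule=[])
        with pytest.raises(ConfigError):
            simulate_pk_profile(PkParameters(), design, subject_seed=0)


class TestEcgSimulation:
    @staticmethod
    def _quiet_physio(**kw):
        base = dict(replicate_sd=0.0, residual_sd=0.0,
                    rr_timepoint_sd=0.0, rr_replicate_sd=0.0, pr_sd=0.0, qrs_sd=0.0,
                    exponent_b_sd=0.0)
        base.update(kw)
        return EcgPhysiology(**base)

    @staticmethod
    def _conc_map(design, value=0.0):
        return {(d, t): value for d in design.ecg_days if d != -1
                for t in design.ecg_times_h[d]}

    def test_noise_free_replicates_obey_power_law_exactly(self):
        design = StudyDesign(n_subjects=1)
        physio = self._quiet_physio(rr_timepoint_sd=0.05)
        ecg = simulate_ecg(physio, DrugEffectSpec(), self._conc_map(design), design, 3)
        b = ecg.attrs["exponent_b"]
        expected = physio.qt_intercept_a * ecg["rr_s"] ** b
        assert np.allclose(ecg["qt_ms"], expected, atol=1e-9)

    def test_no_circadian_no_noise_rr_constant(self):
        design = StudyDesign(n_subjects=1)
        physio = self._quiet_physio(rr_circadian_amp=0.0)
        ecg = simulate_ecg(physio, DrugEffectSpec(), self._conc_map(design), design, 1)
        assert np.allclose(ecg["rr_s"], physio.rr_mean)

    def test_linear_effect_shifts_drug_day_qt(self):
        """slope 0.002 ms/nM at 2760 nM shifts QT by exactly 5.52 ms."""
        design = StudyDesign(n_subjects=1)
        physio = self._quiet_physio()
        seed = 99
        base = simulate_ecg(physio, DrugEffectSpec(), self._conc_map(design), design, seed)
        shifted = simulate_ecg(physio, DrugEffectSpec(form="linear", slope=0.002),
                               self._conc_map(design, 2760.0), design, seed)
        drug = base["day"] != -1
        predose = (base["day"] == 1) & (base["time_h"] == 0.0)
        diff = shifted["qt_ms"] - base["qt_ms"]
        assert np.allclose(diff[drug & ~predose], 5.52, atol=1e-9)
        assert np.allclose(diff[~drug | predose], 0.0, atol=1e-9)

    def test_missing_drug_day_concentration_rejected(self):
        design = StudyDesign(n_subjects=1)
        with pytest.raises(ConfigError):
            simulate_ecg(self._quiet_physio(), DrugEffectSpec(), {}, design, 0)


class TestGenerateCohort:
    def test_same_seed_reproduces_byte_identical_tables(self, tmp_path):
        cfg = CohortConfig(design=StudyDesign(n_subjects=3, seed=123))
        a = generate_cohort(cfg)
        b = generate_cohort(cfg)
        pa = a.write(tmp_path / "a")
        pb = b.write(tmp_path / "b")
        for name in pa:
            assert pa[name].read_bytes() == pb[name].read_bytes()

    def test_zero_subjects_gives_empty_tables_with_headers(self):
        cohort = generate_cohort(CohortConfig(design=StudyDesign(n_subjects=0, seed=1)))
        assert len(cohort.ecg) == 0 and list(cohort.ecg.columns)[:4] == [
            "subject_id", "day", "time_h", "replicate"]
        assert len(cohort.pk) == 0 and "conc_nM" in cohort.pk.columns

    def test_missing_baseline_times_rejected(self):
        times = {-1: (0.0, 1.0), 1: (0.0, 1.0, 2.0), 10: (0.0, 1.0)}
        with pytest.raises(ConfigError):
            StudyDesign(n_subjects=1, ecg_times_h=times)

    def test_noise_free_generator_is_exactly_invertible(self, noise_free_cohort):
        """With all QT noise off, the log-log regression recovers every
        subject's simulated exponent to machine precision."""
        truth = noise_free_cohort.truth
        b_true = truth[truth["parameter"] == "exponent_b"].set_index("subject_id")["value"]
        for sid, g in noise_free_cohort.ecg.groupby("subject_id"):
            base = g[(g["day"] == -1) | ((g["day"] == 1) & (g["time_h"] == 0.0))]
            corr = estimate_individual_exponent(
                base["qt_ms"].to_numpy(), base["rr_s"].to_numpy(), sid)
            assert corr.exponent_b == pytest.approx(b_true[sid], abs=1e-10)

    def test_truth_sidecar_records_effect_and_covariates(self, small_cohort):
        params = set(small_cohort.truth["parameter"].unique())
        assert {"exponent_b", "CL_F", "V_F", "sex", "bmi", "ecog",
                "effect_form"} <= params
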