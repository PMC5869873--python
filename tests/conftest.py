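import numpy as np
import pandas as pd
import pytest

from cqtpipe import (
    CohortConfig,
    DrugEffectSpec,
    StudyDesign,
    apply_corrections,
    average_replicates_frame,
    estimate_exponents,
    generate_cohort,
    time_matched_delta,
    to_long_metrics,
)


def make_null_cqt(rng, n_subjects=50, n_obs=10, omega=7.17, sigma=6.5,
                  slope=0.0, intercept=0.0, conc_median=1200.0, conc_sd_log=0.5):
    """Concentration-response observations under a (possibly null) linear model.

    Each subject gets one drug-free record (conc 0) plus log-normal
    concentrations, a shared random intercept, and independent residuals.
    """
    rows = []
    for i in range(n_subjects):
        conc = np.concatenate([[0.0],
                               rng.lognormal(np.log(conc_median), conc_sd_log, n_obs - 1)])
        eta = rng.normal(0.0, omega)
        y = intercept + slope * conc + eta + rng.normal(0.0, sigma, n_obs)
        rows.append(pd.DataFrame({"subject_id": f"S{i:03d}", "conc_nM": conc, "value": y}))
    return pd.concat(rows, ignore_index=True)


def make_emax_cqt(rng, n_subjects=100, n_obs=10, emax=10.0, ec50=1000.0,
                  omega=3.0, sigma=5.0, conc_median=1000.0, conc_sd_log=0.8):
    """Observations under a saturating Emax concentration-effect model."""
    rows = []
    for i in range(n_subjects):
        conc = np.concatenate([[0.0],
                               rng.lognormal(np.log(conc_median), conc_sd_log, n_obs - 1)])
        eff = emax * conc / (ec50 + conc)
        eta = rng.normal(0.0, omega)
        y = eff + eta + rng.normal(0.0, sigma, n_obs)
        rows.append(pd.DataFrame({"subject_id": f"S{i:03d}", "conc_nM": conc, "value": y}))
    return pd.concat(rows, ignore_index=True)


@pytest.fixture(scope="session")
def small_cohort():
    """A 12-subject null-effect cohort used across integration-style tests."""
    cfg = CohortConfig(design=StudyDesign(n_subjects=12, seed=20240901))
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def cohort_tables(small_cohort):
    """Corrected points, long values and time-matched deltas for the cohort."""
    exponents = estimate_exponents(small_cohort.ecg)
    points = average_replicates_frame(small_cohort.ecg)
    points = apply_corrections(points, exponents)
    values = to_long_metrics(points)
    deltas = time_matched_delta(values)
    deltas = deltas[~((deltas["day"] == 1) & (deltas["time_h"] == 0.0))]
    return {"exponents": exponents, "points": points, "values": values, "deltas": deltas}


@pytest.fixture(scope="session")
def noise_free_cohort():
    """Cohort with every noise source switched off; the generator is then
    exactly the power law QT = a * RR**b plus deterministic PK."""
    from cqtpipe import EcgPhysiology

    # rr_replicate_sd = 0 so the triplicate shares one RR value: replicate
    # averaging then commutes with the power law exactly
    physio = EcgPhysiology(replicate_sd=0.0, residual_sd=0.0,
                           rr_timepoint_sd=0.05, rr_replicate_sd=0.0,
                           pr_sd=0.0, qrs_sd=0.0)
    cfg = CohortConfig(design=StudyDesign(n_subjects=6, seed=5),
                       physiology=physio, effect=DrugEffectSpec(form="none"))
    return generate_cohort(cfg)
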