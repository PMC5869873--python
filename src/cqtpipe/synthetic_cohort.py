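"""Virtual-cohort generator emulating a Holter + PK cardiodynamic study design.

The study design being emulated: ~50 oncology patients receive a single oral
dose on Day 1 and twice-daily (BID) dosing from Day 4 through the morning of
Day 10.  Triplicate Holter ECG extractions are taken on Days -1 (drug-free
baseline), 1 and 10 at nominal times matching the Day-1 PK sampling (up to
24 h on Days -1/1, up to 10 h on Day 10); plasma concentrations of the parent
drug and two metabolites are sampled 0-72 h after the Day-1 dose and 0-10 h
on Day 10.

Statistical structure:

* PK: one-compartment, first-order absorption, linear elimination; multiple
  dosing by superposition of single-dose terms.  One log-normal
  between-subject deviate scales CL/F and V/F jointly, so the elimination
  rate (and hence Tmax and t1/2) is preserved while the whole concentration
  profile scales log-normally -- the between-subject CV of any exposure
  metric then equals the log-normal CV implied by ``bsv_cv`` exactly.
  Metabolites are scaled copies of the parent with their own absorption and
  elimination rates (no mechanistic formation model).
* ECG: each subject obeys a power law QT = a * RR**b with a log-normally
  distributed subject exponent b; RR varies over the day as a circadian
  cosine around its mean plus per-time-point noise, and triplicates share
  the time point's RR draw up to replicate noise.  An optional drug effect
  (none / linear in concentration / Emax) is added to QT on drug days.

Defaults are calibrated so the population medians reproduce a Day-1 Tmax of
about 4 h on the nominal sampling grid, a terminal half-life of 16.4 h, and a
Day-1 geometric-mean Cmax near 1500 nM for a 50 mg dose.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigError, DegenerateParameterError

#: nM per (mg/L) for a molecular weight of ~519 g/mol
DEFAULT_MW_SCALE = 1.0e6 / 518.92

#: clock hour of the 0-h nominal time point (dosing in the morning)
DOSING_CLOCK_HOUR = 8.0


@dataclass
class PkParameters:
    """One-compartment oral PK parameters with log-normal between-subject variability."""

    ka: float = 0.75              # first-order absorption rate (1/h)
    CL_F: float = 2.494           # apparent clearance (L/h)
    V_F: float = 59.0             # apparent volume (L); ke = CL_F/V_F -> t1/2 = 16.4 h
    bsv_cv: float = 0.41          # log-normal between-subject CV on CL_F and V_F
    dose_mg: float = 50.0
    mw_scale: float = DEFAULT_MW_SCALE  # converts mg/L to nM

    def __post_init__(self):
        if self.ka <= 0 or self.CL_F <= 0 or self.V_F <= 0:
            raise ConfigError("ka, CL_F and V_F must be strictly positive")
        if self.bsv_cv < 0:
            raise ConfigError("bsv_cv must be >= 0")
        if self.dose_mg < 0:
            raise ConfigError("dose_mg must be >= 0")
        ke = self.CL_F / self.V_F
        if abs(self.ka - ke) / ke < 1e-9:
            raise DegenerateParameterError(
                f"ka == ke ({self.ka}); one-compartment solution degenerate"
            )

    @property
    def ke(self) -> float:
        return self.CL_F / self.V_F

    @property
    def t_half(self) -> float:
        return math.log(2.0) / self.ke


@dataclass
class MetaboliteSpec:
    """Scaled, lagged copy of the parent profile standing in for a metabolite."""

    scale: float      # exposure scale relative to parent (AUC ratio target)
    ka: float         # metabolite appearance rate (1/h)
    t_half_h: float   # metabolite elimination half-life (h)


@dataclass
class EcgPhysiology:
    """Population QT/RR physiology of the generator.

    QT at RR = 1 s is ``qt_intercept_a`` ms; the subject exponent b is
    log-normal with the given mean/SD.  RR (s) follows a circadian cosine of
    amplitude ``rr_circadian_amp`` peaking at clock hour
    ``rr_circadian_phase`` around ``rr_mean``, with ``rr_timepoint_sd`` noise
    per nominal time and ``rr_replicate_sd`` noise per replicate.  QT noise:
    ``residual_sd`` per time point (shared by the triplicate) plus
    ``replicate_sd`` per replicate.
    """

    qt_intercept_a: float = 400.0
    exponent_b_mean: float = 0.35
    exponent_b_sd: float = 0.06
    rr_mean: float = 0.90
    rr_circadian_amp: float = 0.07
    rr_circadian_phase: float = 4.0
    rr_timepoint_sd: float = 0.05
    rr_replicate_sd: float = 0.015
    replicate_sd: float = 5.0
    residual_sd: float = 5.7
    pr_mean: float = 160.0
    pr_sd: float = 5.0
    qrs_mean: float = 95.0
    qrs_sd: float = 4.0

    def __post_init__(self):
        if self.rr_mean - self.rr_circadian_amp <= 0:
            raise ConfigError("rr_mean - rr_circadian_amp must be positive")
        for name in ("exponent_b_sd", "rr_timepoint_sd", "rr_replicate_sd",
                     "replicate_sd", "residual_sd", "pr_sd", "qrs_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if not (0.0 < self.exponent_b_mean < 1.0):
            raise ConfigError("exponent_b_mean must lie in (0, 1)")


@dataclass
class DrugEffectSpec:
    """Injected concentration effect on QT: none, linear slope, or (sigmoid) Emax."""

    form: str = "none"            # {"none", "linear", "emax"}
    slope: float = 0.0            # ms per nM (linear)
    emax: float = 0.0             # ms
    ec50: float = 1.0             # nM
    gamma: float = 1.0            # Hill coefficient

    def __post_init__(self):
        if self.form not in ("none", "linear", "emax"):
            raise ConfigError(f"unknown effect form {self.form!r}")
        if self.form == "emax" and self.ec50 <= 0:
            raise ConfigError("ec50 must be > 0 for an Emax effect")

    def effect_ms(self, conc_nM):
        c = np.asarray(conc_nM, dtype=float)
        if self.form == "none":
            return np.zeros_like(c)
        if self.form == "linear":
            return self.slope * c
        cg = np.where(c > 0, c, 0.0) ** self.gamma
        return self.emax * cg / (self.ec50**self.gamma + cg)


def _default_dosing_schedule() -> list[tuple[int, float]]:
    """Single dose Day 1; BID Days 4-9; morning dose Day 10."""
    sched = [(1, 0.0)]
    for d in range(4, 10):
        sched += [(d, 0.0), (d, 12.0)]
    sched.append((10, 0.0))
    return sched


@dataclass
class StudyDesign:
    """Nominal sampling/dosing layout of the virtual study."""

    n_subjects: int = 50
    ecg_days: tuple = (-1, 1, 10)
    ecg_times_h: dict = field(default_factory=lambda: {
        -1: (0.0, 0.5, 1.0, 2.0, 3.0, 4.0, 6.0, 8.0, 10.0, 24.0),
        1: (0.0, 0.5, 1.0, 2.0, 3.0, 4.0, 6.0, 8.0, 10.0, 24.0),
        10: (0.0, 0.5, 1.0, 2.0, 3.0, 4.0, 6.0, 8.0, 10.0),
    })
    n_replicates: int = 3
    pk_times_day1_h: tuple = (0.0, 0.5, 1.0, 2.0, 3.0, 4.0, 6.0, 8.0, 10.0, 24.0, 48.0, 72.0)
    pk_times_day10_h: tuple = (0.0, 0.5, 1.0, 2.0, 3.0, 4.0, 6.0, 8.0, 10.0)
    dosing_schedule: list = field(default_factory=_default_dosing_schedule)
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 0:
            raise ConfigError("n_subjects must be >= 0")
        if self.n_replicates < 1:
            raise ConfigError("n_replicates must be >= 1")
        base = set(self.ecg_times_h.get(-1, ()))
        day1_le24 = {t for t in self.ecg_times_h.get(1, ()) if t <= 24.0}
        if not day1_le24 <= base:
            raise ConfigError(
                "baseline-day ECG times must cover the Day-1 times up to 24 h "
                "(time matching would be impossible)"
            )

    def abs_time(self, day: int, time_h: float) -> float:
        """Hours since the Day-1 dose for a nominal (day, time)."""
        return (day - 1) * 24.0 + time_h

    def dose_times_abs(self) -> np.ndarray:
        return np.array(sorted(self.abs_time(d, off) for d, off in self.dosing_schedule))


@dataclass
class CohortConfig:
    """Full generator configuration: design + PK + physiology + injected effect."""

    design: StudyDesign = field(default_factory=StudyDesign)
    pk: PkParameters = field(default_factory=PkParameters)
    physiology: EcgPhysiology = field(default_factory=EcgPhysiology)
    effect: DrugEffectSpec = field(default_factory=DrugEffectSpec)
    metabolites: dict = field(default_factory=lambda: {
        "M1": MetaboliteSpec(scale=0.45, ka=0.75, t_half_h=16.4),
        "M2": MetaboliteSpec(scale=0.41, ka=0.23, t_half_h=22.0),
    })
    sex_female_frac: float = 0.64
    bmi_median: float = 27.0
    bmi_cv: float = 0.20
    ecog1_frac: float = 0.5


def one_compartment_conc(t_abs, dose_times_abs, dose_mg, ka, CL_F, V_F, mw_scale) -> np.ndarray:
    """Total concentration (nM) at absolute hours, by superposition of doses.

    Single-dose term: (D/V) * ka/(ka-ke) * (exp(-ke*t) - exp(-ka*t)) for
    t >= 0, zero before the dose.
    """
    t = np.atleast_1d(np.asarray(t_abs, dtype=float))
    ke = CL_F / V_F
    if abs(ka - ke) / ke < 1e-9:
        raise DegenerateParameterError("ka == ke: superposition term degenerate")
    amp = (dose_mg / V_F) * ka / (ka - ke) * mw_scale
    conc = np.zeros_like(t)
    for td in np.atleast_1d(dose_times_abs):
        dt = t - td
        mask = dt >= 0
        conc[mask] += amp * (np.exp(-ke * dt[mask]) - np.exp(-ka * dt[mask]))
    return np.maximum(conc, 0.0)


def simulate_pk_profile(
    params: PkParameters,
    design: StudyDesign,
    subject_seed,
    analyte: str = "parent",
    scale: float = 1.0,
) -> pd.DataFrame:
    """One subject's concentration records at the design's PK sampling times.

    ``subject_seed`` may be an int or a numpy SeedSequence/Generator; the
    subject's log-normal exposure deviate is the only random draw, so the
    profile is deterministic given the seed.
    """
    if not design.dosing_schedule:
        raise ConfigError("dosing schedule must be non-empty")
    rng = np.random.default_rng(subject_seed)
    sigma = math.sqrt(math.log(1.0 + params.bsv_cv**2))
    eta = rng.normal(0.0, sigma) if sigma > 0 else 0.0
    scale_i = math.exp(eta - 0.5 * sigma**2)  # median-preserving log-normal deviate
    cl_i, v_i = params.CL_F * scale_i, params.V_F * scale_i
    rows = []
    for day, times in ((1, design.pk_times_day1_h), (10, design.pk_times_day10_h)):
        t_abs = np.array([design.abs_time(day, t) for t in times])
        conc = scale * one_compartment_conc(
            t_abs, design.dose_times_abs(), params.dose_mg,
            params.ka, cl_i, v_i, params.mw_scale,
        )
        for t, c in zip(times, conc):
            rows.append({"day": day, "time_h": float(t), "analyte": analyte,
                         "conc_nM": float(c)})
    return pd.DataFrame(rows)


def _circadian_rr(physio: EcgPhysiology, time_h: float) -> float:
    clock = (DOSING_CLOCK_HOUR + time_h) % 24.0
    return physio.rr_mean + physio.rr_circadian_amp * math.cos(
        2.0 * math.pi * (clock - physio.rr_circadian_phase) / 24.0
    )


def simulate_ecg(
    physio: EcgPhysiology,
    effect: DrugEffectSpec,
    conc_at_times: dict,
    design: StudyDesign,
    subject_seed,
    exponent_b: float | None = None,
) -> pd.DataFrame:
    """One subject's replicate-level ECG table across the design's ECG days.

    ``conc_at_times`` maps (day, time_h) to the drug concentration entering
    the injected effect; drug-free times (baseline day, predose) must map to
    0 and every drug-day time point must be present.  Returns rows
    (day, time_h, replicate, qt_ms, rr_s, hr_bpm, pr_ms, qrs_ms) plus the
    subject exponent b used (as ``attrs['exponent_b']``).
    """
    rng = np.random.default_rng(subject_seed)
    if exponent_b is None:
        m, s = physio.exponent_b_mean, physio.exponent_b_sd
        if s > 0:
            sig = math.sqrt(math.log(1.0 + (s / m) ** 2))
            mu = math.log(m) - 0.5 * sig**2
            exponent_b = float(rng.lognormal(mu, sig))
        else:
            exponent_b = m
    rows = []
    for day in design.ecg_days:
        for t in design.ecg_times_h[day]:
            if day == -1 or (day == 1 and t == 0.0):
                conc = 0.0
            else:
                if (day, t) not in conc_at_times:
                    raise ConfigError(f"no concentration supplied for drug-day point ({day}, {t})")
                conc = conc_at_times[(day, t)]
            rr_t = _circadian_rr(physio, t) + rng.normal(0.0, physio.rr_timepoint_sd)
            eps_t = rng.normal(0.0, physio.residual_sd)
            drug_ms = float(effect.effect_ms(conc))
            for rep in range(1, design.n_replicates + 1):
                rr = rr_t + rng.normal(0.0, physio.rr_replicate_sd)
                tries = 0
                while rr <= 0.2 and tries < 100:
                    rr = rr_t + rng.normal(0.0, physio.rr_replicate_sd)
                    tries += 1
                if rr <= 0.2:
                    raise ConfigError("persistent non-physiological RR draw; check physiology")
                qt = (
                    physio.qt_intercept_a * rr**exponent_b
                    + drug_ms + eps_t + rng.normal(0.0, physio.replicate_sd)
                )
                rows.append({
                    "day": day, "time_h": float(t), "replicate": rep,
                    "qt_ms": qt, "rr_s": rr, "hr_bpm": 60.0 / rr,
                    "pr_ms": physio.pr_mean + rng.normal(0.0, physio.pr_sd),
                    "qrs_ms": physio.qrs_mean + rng.normal(0.0, physio.qrs_sd),
                })
    out = pd.DataFrame(rows)
    out.attrs["exponent_b"] = exponent_b
    return out


@dataclass
class Cohort:
    """Generated virtual cohort: replicate ECG, PK, and truth sidecar tables."""

    ecg: pd.DataFrame
    pk: pd.DataFrame
    truth: pd.DataFrame

    def write(self, out_dir) -> dict:
        """Write ecg.csv / pk.csv / truth.csv with a fixed float format.

        Re-running the generator with the same config and seed reproduces
        byte-identical files.
        """
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name, df in (("ecg", self.ecg), ("pk", self.pk), ("truth", self.truth)):
            p = out / f"{name}.csv"
            df.to_csv(p, index=False, float_format="%.10g", lineterminator="\n")
            paths[name] = p
        return paths


_ECG_COLS = ["subject_id", "day", "time_h", "replicate",
             "qt_ms", "rr_s", "hr_bpm", "pr_ms", "qrs_ms"]
_PK_COLS = ["subject_id", "day", "time_h", "analyte", "conc_nM"]


def generate_cohort(config: CohortConfig) -> Cohort:
    """Generate a full virtual cohort (ECG replicates, PK records, truth sidecar).

    The truth table records, per subject, the simulated QT/RR exponent, the
    individual PK parameters, the covariates (sex coded 1 = female, BMI,
    ECOG), and the injected drug-effect parameters -- everything a
    parameter-recovery test needs.
    """
    design = config.design
    root = np.random.SeedSequence(design.seed)
    ecg_frames, pk_frames, truth_rows = [], [], []
    met_items = sorted(config.metabolites.items())
    for i in range(design.n_subjects):
        sid = f"S{i + 1:03d}"
        ss_pk, ss_ecg, ss_cov = root.spawn(3)
        # parent PK (one shared deviate scales CL and V)
        pk_parent = simulate_pk_profile(config.pk, design, ss_pk, analyte="parent")
        # recover the subject scale deviate for the truth record
        rng_probe = np.random.default_rng(ss_pk)
        sig = math.sqrt(math.log(1.0 + config.pk.bsv_cv**2))
        eta = rng_probe.normal(0.0, sig) if sig > 0 else 0.0
        scale_i = math.exp(eta - 0.5 * sig**2)
        frames = [pk_parent]
        for name, mspec in met_items:
            mp = replace(
                config.pk,
                ka=mspec.ka,
                CL_F=config.pk.CL_F,
                V_F=config.pk.CL_F * mspec.t_half_h / math.log(2.0),
            )
            # metabolites reuse the parent's seed so the subject exposure
            # deviate is shared: metabolite/parent ratios are then exact
            frames.append(
                simulate_pk_profile(mp, design, ss_pk, analyte=name, scale=mspec.scale)
            )
        sub_pk = pd.concat(frames, ignore_index=True)
        sub_pk.insert(0, "subject_id", sid)
        pk_frames.append(sub_pk)

        # concentration at ECG times (model prediction at the same nominal time)
        cl_i, v_i = config.pk.CL_F * scale_i, config.pk.V_F * scale_i
        conc_map = {}
        for day in design.ecg_days:
            if day == -1:
                continue
            for t in design.ecg_times_h[day]:
                c = one_compartment_conc(
                    design.abs_time(day, t), design.dose_times_abs(),
                    config.pk.dose_mg, config.pk.ka, cl_i, v_i, config.pk.mw_scale,
                )
                conc_map[(day, t)] = float(c[0])
        sub_ecg = simulate_ecg(config.physiology, config.effect, conc_map, design, ss_ecg)
        b_i = sub_ecg.attrs["exponent_b"]
        sub_ecg.insert(0, "subject_id", sid)
        ecg_frames.append(sub_ecg)

        rng_cov = np.random.default_rng(ss_cov)
        sex = 1.0 if rng_cov.random() < config.sex_female_frac else 0.0
        bmi_sig = math.sqrt(math.log(1.0 + config.bmi_cv**2))
        bmi = float(np.exp(rng_cov.normal(math.log(config.bmi_median), bmi_sig)))
        ecog = 1.0 if rng_cov.random() < config.ecog1_frac else 0.0
        for param, value in [
            ("exponent_b", b_i), ("CL_F", cl_i), ("V_F", v_i), ("ka", config.pk.ka),
            ("sex", sex), ("bmi", bmi), ("ecog", ecog),
            ("effect_form", {"none": 0.0, "linear": 1.0, "emax": 2.0}[config.effect.form]),
            ("effect_slope", config.effect.slope),
            ("effect_emax", config.effect.emax), ("effect_ec50", config.effect.ec50),
        ]:
            truth_rows.append({"subject_id": sid, "parameter": param, "value": value})

    ecg = (
        pd.concat(ecg_frames, ignore_index=True)[_ECG_COLS]
        if ecg_frames else pd.DataFrame(columns=_ECG_COLS)
    )
    pk = (
        pd.concat(pk_frames, ignore_index=True)[_PK_COLS]
        if pk_frames else pd.DataFrame(columns=_PK_COLS)
    )
    truth = pd.DataFrame(truth_rows, columns=["subject_id", "parameter", "value"])
    return Cohort(ecg=ecg, pk=pk, truth=truth)
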