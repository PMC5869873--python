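"""Non-compartmental pharmacokinetic analysis of concentration-time profiles.

Implements the model-free parameter set for a first-dose (0-72 h) and a
steady-state (0-10 h) profile: Cmax/Tmax, AUC by the linear-log trapezoidal
rule, terminal slope (lambda_z) with automatic point selection, AUC
extrapolation to infinity, partial AUC over the dosing-interval window, the
accumulation ratio, and the cohort summary statistics used in PK parameter
tables (geometric means with %CV on the log-normal scale, medians with range,
arithmetic means with SD).

Below-quantitation handling: predose values are taken as 0; zero
concentrations embedded after the first positive value are excluded from AUC
and terminal-slope computations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError

ANALYTES = ("parent", "M1", "M2")

LN2 = math.log(2.0)


@dataclass
class LambdaZFit:
    """Terminal log-linear slope and its selection diagnostics."""

    lambda_z: float = math.nan
    t_half: float = math.nan
    n_points: int = 0
    r_squared_adj: float = math.nan
    span_ok: bool = False
    estimable: bool = False


@dataclass
class NcaResult:
    """Per-subject, per-analyte, per-day non-compartmental parameters."""

    subject_id: str
    analyte: str
    day: int
    cmax_nM: float = math.nan
    tmax_h: float = math.nan
    auc_last_nM_h: float = math.nan
    auc_inf_nM_h: float = math.nan
    auc_0_10_nM_h: float = math.nan
    lambda_z_per_h: float = math.nan
    t_half_h: float = math.nan
    r_ac: float = math.nan
    extrapolated_fraction: float = math.nan


@dataclass
class SummaryStats:
    n: int
    geo_mean: float = math.nan
    geo_cv_pct: float = math.nan
    arith_mean: float = math.nan
    sd: float = math.nan
    median: float = math.nan
    min: float = math.nan
    max: float = math.nan


def _check_profile(times, concs):
    t = np.asarray(times, dtype=float)
    c = np.asarray(concs, dtype=float)
    if len(t) != len(c):
        raise ValidationError("times and concentrations differ in length")
    if np.any(np.diff(t) <= 0):
        raise ValidationError("times must be strictly increasing")
    if np.any(c < 0):
        raise ValidationError("concentrations must be non-negative")
    return t, c


def auc_linlog(times, concs) -> float:
    """AUC by the linear-log trapezoidal rule.

    Per segment: the linear trapezoid when the concentration is rising
    (C2 >= C1) or either endpoint is zero; the logarithmic trapezoid
    (C1 - C2) * dt / ln(C1/C2) on a strictly positive decline.
    """
    t, c = _check_profile(times, concs)
    if len(t) < 2:
        return 0.0
    dt = np.diff(t)
    c1, c2 = c[:-1], c[1:]
    log_seg = (c1 > c2) & (c2 > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        log_ratio = np.log(c1) - np.log(np.where(c2 > 0, c2, 1.0))
    seg = np.where(
        log_seg,
        (c1 - c2) * dt / np.where(log_seg, log_ratio, 1.0),
        0.5 * (c1 + c2) * dt,
    )
    return float(seg.sum())


def cmax_tmax(times, concs) -> tuple[float, float]:
    """Maximum observed concentration and the first time it occurs."""
    t, c = _check_profile(times, concs)
    if len(t) == 0:
        raise ValidationError("empty profile")
    i = int(np.argmax(c))  # argmax returns the first maximum on ties
    return float(c[i]), float(t[i])


def fit_lambda_z(times, concs, min_points: int = 3) -> LambdaZFit:
    """Terminal slope by log-linear regression with automatic point selection.

    Candidate sets are the last k >= min_points positive concentrations
    strictly after Tmax.  Among candidates the set maximising the adjusted
    R-squared is chosen, preferring sets whose time span is at least twice the
    implied half-life when any such set exists.  A flat or rising terminal
    phase yields a non-estimable flag rather than an exception.
    """
    t, c = _check_profile(times, concs)
    pos = c > 0
    if pos.sum() == 0:
        return LambdaZFit()
    _, tmax = cmax_tmax(t, c)
    usable = pos & (t > tmax)
    tt, cc = t[usable], c[usable]
    if len(tt) < min_points:
        return LambdaZFit()
    candidates = []
    for k in range(min_points, len(tt) + 1):
        ts, cs = tt[-k:], np.log(cc[-k:])
        slope, intercept = np.polyfit(ts, cs, 1)
        if slope >= 0:
            continue
        fitted = slope * ts + intercept
        ss_res = float(np.sum((cs - fitted) ** 2))
        ss_tot = float(np.sum((cs - cs.mean()) ** 2))
        if ss_tot <= 0:
            continue
        r2 = 1.0 - ss_res / ss_tot
        r2_adj = 1.0 - (1.0 - r2) * (k - 1) / (k - 2) if k > 2 else r2
        lam = -slope
        thalf = LN2 / lam
        span_ok = (ts[-1] - ts[0]) >= 2.0 * thalf
        candidates.append(LambdaZFit(lam, thalf, k, r2_adj, span_ok, True))
    if not candidates:
        return LambdaZFit()
    spanning = [f for f in candidates if f.span_ok]
    pool = spanning if spanning else candidates
    return max(pool, key=lambda f: f.r_squared_adj)


def auc_extrapolate(auc_last: float, c_last: float, lambda_z: float) -> tuple[float, float]:
    """AUC extrapolated to infinity and the extrapolated fraction.

    auc_inf = auc_last + c_last / lambda_z.
    """
    if not (lambda_z > 0):
        raise ValidationError("lambda_z must be positive for extrapolation")
    auc_inf = auc_last + c_last / lambda_z
    frac = (auc_inf - auc_last) / auc_inf if auc_inf > 0 else 0.0
    return float(auc_inf), float(frac)


def accumulation_ratio(auc_0_10_day10: float, auc_0_10_day1: float) -> float:
    """Accumulation ratio: steady-state over first-dose partial AUC (same window)."""
    if not (auc_0_10_day1 > 0 and auc_0_10_day10 > 0):
        raise ValidationError("both partial AUCs must be positive")
    return float(auc_0_10_day10 / auc_0_10_day1)


def predicted_accumulation_ratio(tau_h: float, t_half_h: float) -> float:
    """Linear-kinetics accumulation ratio 1 / (1 - 2**(-tau/t_half))."""
    return 1.0 / (1.0 - 2.0 ** (-tau_h / t_half_h))


def steady_state_fraction(t_half_h: float, duration_h: float) -> float:
    """Fraction of steady state attained after `duration_h` of dosing.

    1 - 2**(-duration/t_half) under linear kinetics.
    """
    if not (t_half_h > 0) or duration_h < 0:
        raise ValidationError("t_half must be > 0 and duration >= 0")
    return 1.0 - 2.0 ** (-duration_h / t_half_h)


def unbound_concentration(total_conc: float, free_fraction: float) -> float:
    """Unbound concentration = free fraction x total concentration."""
    if not (0.0 <= free_fraction <= 1.0):
        raise ValidationError("free_fraction must lie in [0, 1]")
    return total_conc * free_fraction


def summarize_parameter(values, kind: str = "geometric") -> SummaryStats:
    """Cohort summary of one PK parameter.

    kind="geometric": geometric mean exp(mean log) and geometric CV%
    100*sqrt(exp(s2_log) - 1); all values must be positive.  Other kinds fill
    arithmetic/median fields only.  Missing values are dropped first.
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    out = SummaryStats(n=int(len(v)))
    if len(v) == 0:
        return out
    out.arith_mean = float(v.mean())
    out.sd = float(v.std(ddof=1)) if len(v) > 1 else 0.0
    out.median = float(np.median(v))
    out.min = float(v.min())
    out.max = float(v.max())
    if kind == "geometric":
        if np.any(v <= 0):
            bad = v[v <= 0]
            raise ValidationError(f"geometric summary requires positive values; got {bad}")
        logs = np.log(v)
        out.geo_mean = float(np.exp(logs.mean()))
        s2 = float(logs.var(ddof=1)) if len(v) > 1 else 0.0
        out.geo_cv_pct = 100.0 * math.sqrt(math.exp(s2) - 1.0)
    return out


def metabolite_ratio(parent_values: pd.Series, metabolite_values: pd.Series) -> float:
    """Arithmetic mean of per-subject metabolite/parent ratios.

    Both inputs are indexed by subject; only subjects present in both with a
    positive parent value contribute.
    """
    joined = pd.concat(
        {"parent": parent_values, "metabolite": metabolite_values}, axis=1
    ).dropna()
    joined = joined[joined["parent"] > 0]
    if len(joined) == 0:
        return math.nan
    return float((joined["metabolite"] / joined["parent"]).mean())


def _clean_profile(times: np.ndarray, concs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Drop embedded/trailing zero concentrations after the first positive value."""
    pos = concs > 0
    if not pos.any():
        return times, concs
    first_pos = int(np.argmax(pos))
    keep = pos | (np.arange(len(concs)) <= first_pos)
    # trailing zeros after the last positive are excluded too (covered by `pos`)
    return times[keep], concs[keep]


def nca_profile(times, concs, window_h: float | None = None) -> dict:
    """NCA of a single profile: Cmax/Tmax, AUCs, terminal slope.

    ``window_h`` requests an additional partial AUC from 0 to that time
    (requires a sample at the window edge).
    """
    t, c = _check_profile(times, concs)
    t, c = _clean_profile(t, c)
    cmax, tmax = cmax_tmax(t, c)
    last_pos = np.nonzero(c > 0)[0]
    out = {
        "cmax": cmax,
        "tmax": tmax,
        "auc_last": math.nan,
        "auc_inf": math.nan,
        "auc_window": math.nan,
        "lambda_z": math.nan,
        "t_half": math.nan,
        "extrapolated_fraction": math.nan,
    }
    if len(last_pos) == 0:
        return out
    i_last = last_pos[-1]
    out["auc_last"] = auc_linlog(t[: i_last + 1], c[: i_last + 1])
    lz = fit_lambda_z(t, c)
    if lz.estimable:
        out["lambda_z"] = lz.lambda_z
        out["t_half"] = lz.t_half
        auc_inf, frac = auc_extrapolate(out["auc_last"], c[i_last], lz.lambda_z)
        out["auc_inf"] = auc_inf
        out["extrapolated_fraction"] = frac
    if window_h is not None:
        in_win = t <= window_h + 1e-9
        if in_win.sum() >= 2 and abs(t[in_win][-1] - window_h) < 1e-6:
            out["auc_window"] = auc_linlog(t[in_win], c[in_win])
    return out


def run_nca(pk: pd.DataFrame, window_h: float = 10.0) -> pd.DataFrame:
    """Per-subject NCA over a long concentration table.

    Expects columns (subject_id, day, time_h, analyte, conc_nM) with a
    first-dose profile on day 1 and a steady-state profile on day 10.  Cmax
    and Tmax are computed on both days; AUC(0-last), AUC(0-inf) and the
    half-life on day 1 only; the 0-10 h partial AUC on both days and the
    accumulation ratio (day 10 / day 1 over the same window) on day 10 only.
    """
    rows = []
    for (sid, analyte), g in pk.groupby(["subject_id", "analyte"], sort=True):
        day1 = g[g["day"] == 1].sort_values("time_h")
        day10 = g[g["day"] == 10].sort_values("time_h")
        res1 = res10 = None
        if len(day1) >= 2:
            p = nca_profile(day1["time_h"].to_numpy(), day1["conc_nM"].to_numpy(), window_h)
            res1 = NcaResult(
                subject_id=sid, analyte=analyte, day=1,
                cmax_nM=p["cmax"], tmax_h=p["tmax"],
                auc_last_nM_h=p["auc_last"], auc_inf_nM_h=p["auc_inf"],
                auc_0_10_nM_h=p["auc_window"],
                lambda_z_per_h=p["lambda_z"], t_half_h=p["t_half"],
                extrapolated_fraction=p["extrapolated_fraction"],
            )
            rows.append(res1)
        if len(day10) >= 2:
            p = nca_profile(day10["time_h"].to_numpy(), day10["conc_nM"].to_numpy(), window_h)
            res10 = NcaResult(
                subject_id=sid, analyte=analyte, day=10,
                cmax_nM=p["cmax"], tmax_h=p["tmax"],
                auc_0_10_nM_h=p["auc_window"],
            )
            if res1 is not None and res1.auc_0_10_nM_h > 0 and res10.auc_0_10_nM_h > 0:
                res10.r_ac = accumulation_ratio(res10.auc_0_10_nM_h, res1.auc_0_10_nM_h)
            rows.append(res10)
    return pd.DataFrame([vars(r) for r in rows])


#: parameter -> summary convention used in the PK parameter table
_TABLE1_KINDS = {
    "cmax_nM": "geometric",
    "auc_last_nM_h": "geometric",
    "auc_inf_nM_h": "geometric",
    "auc_0_10_nM_h": "geometric",
    "tmax_h": "median",
    "t_half_h": "arithmetic",
    "r_ac": "arithmetic",
}


def summarize_nca(nca: pd.DataFrame) -> pd.DataFrame:
    """Cohort PK parameter summary (analyte x day x parameter x statistics)."""
    rows = []
    for (analyte, day), g in nca.groupby(["analyte", "day"], sort=True):
        for param, kind in _TABLE1_KINDS.items():
            vals = g[param].dropna()
            if len(vals) == 0:
                continue
            s = summarize_parameter(vals, kind="geometric" if kind == "geometric" else "arithmetic")
            rows.append(
                {
                    "analyte": analyte,
                    "day": day,
                    "parameter": param,
                    "statistic_kind": kind,
                    "n": s.n,
                    "geo_mean": s.geo_mean,
                    "geo_cv_pct": s.geo_cv_pct,
                    "arith_mean": s.arith_mean,
                    "sd": s.sd,
                    "median": s.median,
                    "min": s.min,
                    "max": s.max,
                }
            )
    return pd.DataFrame(rows)


def metabolite_ratios(nca: pd.DataFrame, parameter: str, day: int) -> dict[str, float]:
    """Mean per-subject metabolite/parent ratios of one NCA parameter."""
    wide = nca[nca["day"] == day].pivot_table(
        index="subject_id", columns="analyte", values=parameter
    )
    out = {}
    for met in ("M1", "M2"):
        if met in wide and "parent" in wide:
            out[met] = metabolite_ratio(wide["parent"], wide[met])
    return out
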