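"""Repeated-measures central-tendency analysis of ECG changes from baseline.

The primary regulatory summary of a QTc study is, per (day, time) cell, the
least-squares mean change from time-matched baseline together with its
one-sided 95% upper confidence bound (UCB).  The model is a repeated-measures
mixed-effects linear model: fixed day-by-time cell means, a random subject
intercept (compound-symmetric within-subject covariance), independent
residuals, estimated by REML.  Degrees of freedom use the containment rule,
``n_subjects_in_cell - 1``.

Also provided: the closed-form planning half-width of the one-sided 95% UCB,
``z_0.95 * sd / sqrt(n)``, used for sample-size arithmetic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientDataError

_ZERO_VAR_TOL = 1e-10


@dataclass(frozen=True)
class CentralTendencyResult:
    metric: str
    day: int
    time_h: float
    ls_mean: float
    se: float
    df: float
    ucb_95: float
    n_subjects: int


def plan_ucb_halfwidth(sd: float, n: int) -> float:
    """Planning half-width of a one-sided 95% UCB: z_0.95 * sd / sqrt(n)."""
    if sd < 0 or n < 1:
        raise InsufficientDataError("sd must be >= 0 and n >= 1")
    return float(stats.norm.ppf(0.95) * sd / np.sqrt(n))


def _cell_summaries(g: pd.DataFrame, metric: str, conf: float) -> list[CentralTendencyResult]:
    """Exact per-cell one-sample summaries (degenerate-input fallback).

    Used when the mixed model is unidentifiable (zero variance, or no subject
    contributes more than one observation); for a single cell this is the
    one-sample t analysis the mixed model reduces to.
    """
    out = []
    for (day, time_h), cell in g.groupby(["day", "time_h"], sort=True):
        vals = cell["delta"].to_numpy(dtype=float)
        n = len(vals)
        mean = float(vals.mean())
        sd = float(vals.std(ddof=1)) if n > 1 else 0.0
        se = sd / np.sqrt(n)
        df = max(n - 1, 1)
        ucb = mean + stats.t.ppf(conf, df) * se
        out.append(CentralTendencyResult(metric, int(day), float(time_h),
                                         mean, se, df, float(ucb), n))
    return out


def fit_repeated_measures(deltas: pd.DataFrame, conf: float = 0.95) -> pd.DataFrame:
    """LS means, SEs and one-sided UCBs per metric and (day, time) cell.

    ``deltas`` is the long change-from-baseline frame (subject_id, day,
    time_h, metric, delta).  Days are modelled jointly with day-by-time cells.
    Cells with no data are simply absent from the output.
    """
    import statsmodels.api as sm

    results: list[CentralTendencyResult] = []
    for metric, g in deltas.groupby("metric", sort=True):
        g = g.dropna(subset=["delta"])
        if g.empty:
            continue
        if g["subject_id"].nunique() < 2:
            raise InsufficientDataError(f"metric {metric}: need >=2 subjects")
        max_per_subject = g.groupby("subject_id").size().max()
        if g["delta"].var(ddof=0) < _ZERO_VAR_TOL or max_per_subject < 2:
            results.extend(_cell_summaries(g, metric, conf))
            continue
        g = g.copy()
        g["cell"] = list(zip(g["day"].astype(int), g["time_h"].astype(float)))
        cells = sorted(g["cell"].unique())
        X = pd.DataFrame(
            {str(c): (g["cell"] == c).astype(float).to_numpy() for c in cells}
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.MixedLM(g["delta"].to_numpy(), X, groups=g["subject_id"].to_numpy())
            fit = model.fit(reml=True)
        n_per_cell = g.groupby("cell")["subject_id"].nunique()
        for c in cells:
            mean = float(fit.params[str(c)])
            se = float(fit.bse[str(c)])
            n_sub = int(n_per_cell[c])
            df = max(n_sub - 1, 1)
            ucb = mean + stats.t.ppf(conf, df) * se
            results.append(CentralTendencyResult(metric, c[0], c[1], mean, se, df, ucb, n_sub))
    return pd.DataFrame([vars(r) for r in results])
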