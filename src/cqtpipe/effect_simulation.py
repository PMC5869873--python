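"""Simulation of the QTc effect-size distribution at a reference concentration.

Given a fitted concentration-effect model, each simulated patient draws

    dQTc_i = intercept + f(C_ref; theta) + eta_i + eps_i,

with eta ~ N(0, omega^2) and eps ~ N(0, sigma^2) -- both the between-subject
and the residual variability contribute, so the spread of the simulated
distribution is on the total-SD scale.  The summary reports the usual
distributional statistics plus the percentage of draws exceeding the 30 ms
and 60 ms thresholds of concern.  Analytic normal tail probabilities are
provided as the infinite-n counterpart of the empirical exceedances.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import ValidationError


@dataclass(frozen=True)
class SimulationSummary:
    n_simulated: int
    median: float
    mean: float
    sd: float
    cv_pct: float          # 100*SD/|mean|; NaN when the mean is exactly 0
    min: float
    p5: float
    p95: float
    max: float
    pct_gt_30: float
    pct_gt_60: float
    reference_conc_nM: float


def summarize_draws(draws, reference_conc_nM: float = math.nan) -> SimulationSummary:
    """Distributional summary of simulated changes from baseline.

    Percentiles use linear interpolation between order statistics; exceedance
    percentages use strict inequalities.
    """
    d = np.asarray(draws, dtype=float)
    if len(d) < 1:
        raise ValidationError("need at least one draw")
    mean = float(d.mean())
    sd = float(d.std(ddof=1)) if len(d) > 1 else 0.0
    return SimulationSummary(
        n_simulated=len(d),
        median=float(np.median(d)),
        mean=mean,
        sd=sd,
        cv_pct=(100.0 * sd / abs(mean)) if mean != 0.0 else math.nan,
        min=float(d.min()),
        p5=float(np.percentile(d, 5)),
        p95=float(np.percentile(d, 95)),
        max=float(d.max()),
        pct_gt_30=100.0 * float(np.mean(d > 30.0)),
        pct_gt_60=100.0 * float(np.mean(d > 60.0)),
        reference_conc_nM=reference_conc_nM,
    )


def simulate_population(fit, conc_nM: float, n: int = 1000, seed: int = 0):
    """Draws and summary of the predicted effect at one reference concentration.

    ``fit`` is a CqtModelFit (or anything with .predict, .omega, .sigma).
    Deterministic given the seed.
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    rng = np.random.default_rng(seed)
    pred = float(np.asarray(fit.predict(conc_nM)))
    eta = rng.normal(0.0, fit.omega, n) if fit.omega > 0 else np.zeros(n)
    eps = rng.normal(0.0, fit.sigma, n) if fit.sigma > 0 else np.zeros(n)
    draws = pred + eta + eps
    return draws, summarize_draws(draws, reference_conc_nM=conc_nM)


def tail_probability(mean: float, sd: float, threshold: float) -> float:
    """Percent of a N(mean, sd^2) population above ``threshold``.

    100 * (1 - Phi((threshold - mean)/sd)).
    """
    if sd <= 0:
        raise ValidationError("sd must be > 0")
    return 100.0 * float(stats.norm.sf((threshold - mean) / sd))
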