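"""Concentration-QTc (and concentration-HR) mixed-effects model hierarchy.

The observation model is, for subject i and record j,

    y_ij = intercept + f(C_ij; theta) + eta_i + eps_ij,
    eta_i ~ N(0, omega^2),   eps_ij ~ N(0, sigma^2),

with four structural forms for the drug effect f:

* ``no_effect``:      f = 0
* ``linear``:         f = slope * C
* ``emax``:           f = Emax * C / (EC50 + C)
* ``sigmoid_emax``:   f = Emax * C^gamma / (EC50^gamma + C^gamma)

Because the single random effect enters additively with Gaussian residuals,
the marginal likelihood is an exact multivariate normal with a
compound-symmetric per-subject covariance, so exact maximum likelihood is
available in closed form -- no linearisation or quadrature.  For speed and
robustness the linear fixed effects and the residual variance are profiled
out analytically (GLS given the variance ratio and any nonlinear
parameters), leaving a 1-3 dimensional outer optimisation.

Model selection follows the usual pharmacometric hierarchy: nested models by
likelihood-ratio test (an objective-function drop of 3.84 per added
parameter at alpha = 0.05), non-nested models by AIC, ties resolved in
favour of fewer parameters.  Covariates are screened as additive intercept
shifts by forward addition.  Uncertainty by subject-resampling bootstrap.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import FitError, InsufficientDataError, ValidationError

FORMS = ("no_effect", "linear", "emax", "sigmoid_emax")

#: number of fixed-effect parameters per structural form
N_FIXED = {"no_effect": 1, "linear": 2, "emax": 3, "sigmoid_emax": 4}

#: fixed-effect parameter names per form, in vector order
THETA_NAMES = {
    "no_effect": ("intercept",),
    "linear": ("intercept", "slope"),
    "emax": ("intercept", "emax", "ec50"),
    "sigmoid_emax": ("intercept", "emax", "ec50", "gamma"),
}

_CHI2_1DF_95 = float(stats.chi2.ppf(0.95, 1))  # 3.8415

_MIN_SIGMA2 = 1e-12


@dataclass
class CqtModelFit:
    """A fitted concentration-effect mixed model."""

    form: str
    theta: dict = field(default_factory=dict)     # fixed effects by name
    omega: float = math.nan                       # between-subject SD of the intercept
    sigma: float = math.nan                       # residual SD
    se: dict = field(default_factory=dict)        # SEs by name (incl. omega, sigma)
    se_pct: dict = field(default_factory=dict)    # 100*SE/|estimate|
    ofv: float = math.nan                         # -2 log-likelihood
    n_subjects: int = 0
    n_obs: int = 0
    converged: bool = False
    boundary: bool = False
    message: str = ""
    covariate_names: tuple = ()
    covariate_coefs: dict = field(default_factory=dict)

    @property
    def n_parameters(self) -> int:
        return N_FIXED[self.form] + len(self.covariate_names) + 2  # + omega, sigma

    @property
    def aic(self) -> float:
        return self.ofv + 2.0 * self.n_parameters

    def predict(self, conc_nM):
        """Population prediction intercept + f(conc)."""
        c = np.asarray(conc_nM, dtype=float)
        return self.theta["intercept"] + structural_effect(self.form, self.theta, c)

    def wald_ci(self, name: str, level: float = 0.95) -> tuple[float, float]:
        z = stats.norm.ppf(0.5 + level / 2.0)
        est, se = self.theta[name], self.se.get(name, math.nan)
        return est - z * se, est + z * se


def structural_effect(form: str, theta: dict, conc: np.ndarray) -> np.ndarray:
    """Drug-effect part f(C; theta) of each structural form."""
    if form == "no_effect":
        return np.zeros_like(conc)
    if form == "linear":
        return theta["slope"] * conc
    gamma = theta.get("gamma", 1.0) if form == "sigmoid_emax" else 1.0
    cg = np.where(conc > 0, conc, 0.0) ** gamma
    return theta["emax"] * cg / (theta["ec50"] ** gamma + cg)


class _Grouped:
    """Concentration/response data sorted into contiguous subject blocks."""

    def __init__(self, subject_ids, conc, y):
        subject_ids = np.asarray(subject_ids)
        conc = np.asarray(conc, dtype=float)
        y = np.asarray(y, dtype=float)
        order = np.argsort(subject_ids, kind="stable")
        self.codes, uniques = pd.factorize(subject_ids[order])
        self.subjects = list(uniques)
        self.conc = conc[order]
        self.y = y[order]
        self.counts = np.bincount(self.codes).astype(float)
        self.n_groups = len(self.counts)
        self.N = len(y)

    def group_sum(self, v: np.ndarray) -> np.ndarray:
        return np.bincount(self.codes, weights=v, minlength=self.n_groups)


def _design_columns(form: str, conc: np.ndarray, nonlin: tuple) -> np.ndarray:
    """Columns of the linear-in-coefficients design for given nonlinear params."""
    ones = np.ones_like(conc)
    if form == "no_effect":
        return ones[:, None]
    if form == "linear":
        return np.column_stack([ones, conc])
    if form == "emax":
        (ec50,) = nonlin
        return np.column_stack([ones, conc / (ec50 + conc)])
    ec50, gamma = nonlin
    cg = np.where(conc > 0, conc, 0.0) ** gamma
    return np.column_stack([ones, cg / (ec50**gamma + cg)])


def _profiled_nll(
    phi: float, form: str, nonlin: tuple, data: _Grouped, extra: np.ndarray | None = None
):
    """Exact marginal -log L profiled over the linear coefficients and sigma^2.

    phi = omega^2/sigma^2.  Returns (nll, beta, sigma2); beta covers the
    structural linear coefficients followed by any extra covariate columns.
    """
    X = _design_columns(form, data.conc, nonlin)
    if extra is not None:
        X = np.column_stack([X, extra])
    c = phi / (1.0 + data.counts * phi)  # per-group shrinkage weight
    Sx = np.column_stack([data.group_sum(X[:, j]) for j in range(X.shape[1])])
    Sy = data.group_sum(data.y)
    A = X.T @ X - (Sx * c[:, None]).T @ Sx
    bvec = X.T @ data.y - Sx.T @ (c * Sy)
    try:
        beta = np.linalg.solve(A, bvec)
    except np.linalg.LinAlgError:
        return math.inf, None, math.nan
    r = data.y - X @ beta
    Sr = data.group_sum(r)
    q = float(r @ r - np.sum(c * Sr**2))
    sigma2 = max(q / data.N, _MIN_SIGMA2)
    nll = 0.5 * (
        data.N * math.log(2.0 * math.pi)
        + data.N * math.log(sigma2)
        + float(np.sum(np.log1p(data.counts * phi)))
        + q / sigma2
    )
    return nll, beta, sigma2


def _nll_full(params: np.ndarray, form: str, data: _Grouped, extra: np.ndarray | None):
    """Exact marginal -log L at explicit natural parameters (for the Hessian)."""
    p_lin = N_FIXED[form] if form in ("no_effect", "linear") else 2
    n_nonlin = {"no_effect": 0, "linear": 0, "emax": 1, "sigmoid_emax": 2}[form]
    n_extra = 0 if extra is None else extra.shape[1]
    beta = params[:p_lin]
    nonlin = tuple(params[p_lin : p_lin + n_nonlin])
    cov_coefs = params[p_lin + n_nonlin : p_lin + n_nonlin + n_extra]
    omega, sigma = params[-2], params[-1]
    if sigma <= 0 or omega < 0:
        return math.inf
    if form in ("emax", "sigmoid_emax") and (nonlin[0] <= 0 or (len(nonlin) > 1 and nonlin[1] <= 0)):
        return math.inf
    X = _design_columns(form, data.conc, nonlin)
    mean = X @ beta
    if extra is not None:
        mean = mean + extra @ cov_coefs
    r = data.y - mean
    sigma2 = sigma**2
    phi = omega**2 / sigma2
    c = phi / (1.0 + data.counts * phi)
    Sr = data.group_sum(r)
    q = float(r @ r - np.sum(c * Sr**2))
    return 0.5 * (
        data.N * math.log(2.0 * math.pi)
        + data.N * math.log(sigma2)
        + float(np.sum(np.log1p(data.counts * phi)))
        + q / sigma2
    )


def _hessian(fun, x: np.ndarray) -> np.ndarray:
    """Central-difference Hessian with relative steps."""
    n = len(x)
    h = 1e-4 * np.maximum(np.abs(x), 1e-5)
    H = np.empty((n, n))
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = h[i]
            ej = np.zeros(n); ej[j] = h[j]
            fpp = fun(x + ei + ej)
            fpm = fun(x + ei - ej)
            fmp = fun(x - ei + ej)
            fmm = fun(x - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4.0 * h[i] * h[j])
    return H


_PHI_LOG_BOUNDS = (-16.0, 8.0)


def _optimize_phi(form, nonlin, data, extra):
    """1-d minimisation of the profiled NLL over log(phi)."""
    def obj(u):
        return _profiled_nll(math.exp(u), form, nonlin, data, extra)[0]

    res = optimize.minimize_scalar(obj, bounds=_PHI_LOG_BOUNDS, method="bounded",
                                   options={"xatol": 1e-6})
    # compare against the omega -> 0 boundary
    nll0 = _profiled_nll(0.0, form, nonlin, data, extra)[0]
    if nll0 <= res.fun:
        return 0.0, nll0
    return math.exp(res.x), res.fun


def fit_cqt(
    observations: pd.DataFrame,
    form: str = "linear",
    value_col: str = "value",
    conc_col: str = "conc_nM",
    covariate_cols: tuple = (),
    compute_se: bool = True,
) -> CqtModelFit:
    """Exact marginal-ML fit of one structural concentration-effect model.

    ``observations`` needs columns (subject_id, conc_nM, <value_col>) and any
    requested covariate columns (screened as additive intercept shifts,
    centred for numerical stability).
    """
    if form not in FORMS:
        raise ValidationError(f"unknown form {form!r}; expected one of {FORMS}")
    obs = observations.dropna(subset=[value_col, conc_col])
    if obs["subject_id"].nunique() < 2:
        raise InsufficientDataError("need >=2 subjects for BSV identifiability")
    if np.any(obs[conc_col].to_numpy() < 0):
        raise ValidationError("concentrations must be non-negative")
    data = _Grouped(obs["subject_id"].to_numpy(), obs[conc_col].to_numpy(),
                    obs[value_col].to_numpy())
    extra = None
    if covariate_cols:
        order = np.argsort(obs["subject_id"].to_numpy(), kind="stable")
        cols = []
        for c in covariate_cols:
            v = obs[c].to_numpy(dtype=float)[order]
            cols.append(v - float(v.mean()))
        extra = np.column_stack(cols)
    return _fit_data(data, extra, form, tuple(covariate_cols), compute_se)


def _fit_data(
    data: _Grouped, extra, form: str, covariate_cols: tuple, compute_se: bool
) -> CqtModelFit:
    conc_pos = data.conc[data.conc > 0]
    boundary = False
    message = ""
    if form in ("no_effect", "linear"):
        nonlin = ()
        phi, nll = _optimize_phi(form, nonlin, data, extra)
    else:
        if len(conc_pos) == 0:
            raise InsufficientDataError("no positive concentrations; Emax not identifiable")
        lo = math.log(float(np.quantile(conc_pos, 0.05)))
        hi = math.log(float(conc_pos.max()))
        starts = [lo + frac * (hi - lo) for frac in (0.25, 0.5, 0.75)]
        n_nl = 1 if form == "emax" else 2

        def obj(v):
            ec50 = math.exp(np.clip(v[0], lo - 5.0, hi + 5.0))
            nl = (ec50,) if n_nl == 1 else (ec50, math.exp(np.clip(v[1], math.log(0.1), math.log(10.0))))
            return _optimize_phi(form, nl, data, extra)[1]

        best = None
        for s in starts:
            x0 = np.array([s] if n_nl == 1 else [s, 0.0])
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                r = optimize.minimize(obj, x0, method="Nelder-Mead",
                                      options={"xatol": 1e-4, "fatol": 1e-7, "maxiter": 250})
            if best is None or r.fun < best.fun:
                best = r
        v = best.x
        ec50 = math.exp(float(np.clip(v[0], lo - 5.0, hi + 5.0)))
        nonlin = (ec50,) if n_nl == 1 else (
            ec50, math.exp(float(np.clip(v[1], math.log(0.1), math.log(10.0)))),
        )
        if not (conc_pos.min() / 100.0 <= ec50 <= conc_pos.max() * 100.0):
            boundary = True
            message = f"EC50 = {ec50:.4g} nM at/beyond the informative range"
        phi, nll = _optimize_phi(form, nonlin, data, extra)

    _, beta, sigma2 = _profiled_nll(phi, form, nonlin, data, extra)
    if beta is None:
        raise FitError(f"{form}: singular design in final GLS step")
    sigma = math.sqrt(sigma2)
    omega = math.sqrt(phi * sigma2)
    names = list(THETA_NAMES[form])
    p_lin = 2 if form in ("emax", "sigmoid_emax") else N_FIXED[form]
    theta = {n: float(b) for n, b in zip(names[:p_lin], beta[:p_lin])}
    if form == "emax":
        theta["ec50"] = nonlin[0]
    elif form == "sigmoid_emax":
        theta["ec50"], theta["gamma"] = nonlin
    n_extra = 0 if extra is None else extra.shape[1]
    cov_coefs = {c: float(b) for c, b in zip(covariate_cols, beta[p_lin : p_lin + n_extra])}

    fit = CqtModelFit(
        form=form, theta=theta, omega=omega, sigma=sigma,
        ofv=2.0 * nll, n_subjects=data.n_groups, n_obs=data.N,
        converged=True, boundary=boundary, message=message,
        covariate_names=tuple(covariate_cols), covariate_coefs=cov_coefs,
    )
    if compute_se:
        _attach_se(fit, form, data, extra, covariate_cols)
    return fit


def _attach_se(fit: CqtModelFit, form: str, data: _Grouped, extra, covariate_cols):
    """SEs from the inverse Hessian of the exact NLL at the optimum."""
    names = list(THETA_NAMES[form]) + list(covariate_cols) + ["omega", "sigma"]
    p_lin = 2 if form in ("emax", "sigmoid_emax") else N_FIXED[form]
    x = [fit.theta[n] for n in THETA_NAMES[form][:p_lin]]
    if form == "emax":
        x.append(fit.theta["ec50"])
    elif form == "sigmoid_emax":
        x += [fit.theta["ec50"], fit.theta["gamma"]]
    x += [fit.covariate_coefs[c] for c in covariate_cols]
    x += [fit.omega, fit.sigma]
    x = np.asarray(x, dtype=float)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            H = _hessian(lambda p: _nll_full(p, form, data, extra), x)
            cov = np.linalg.inv(H)
            ses = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except (np.linalg.LinAlgError, FloatingPointError, ValueError):
        ses = np.full(len(x), math.nan)
    if fit.omega < 1e-8:
        ses[-2] = math.nan  # boundary: omega SE not meaningful
    fit.se = {n: float(s) for n, s in zip(names, ses)}
    ests = dict(fit.theta, **fit.covariate_coefs, omega=fit.omega, sigma=fit.sigma)
    fit.se_pct = {
        n: (100.0 * fit.se[n] / abs(ests[n]) if abs(ests[n]) > 0 else math.nan)
        for n in names
    }


def _nested(simpler: str, richer: str) -> bool:
    if simpler == richer:
        return False
    if simpler == "no_effect":
        return True
    return simpler == "emax" and richer == "sigmoid_emax"


def select_model(fits: list[CqtModelFit], alpha: float = 0.05) -> CqtModelFit:
    """Choose the final structural model from candidate fits on shared data.

    Nested pairs: likelihood-ratio test at ``alpha`` per added parameter
    (objective-function drop of 3.84 per df at the default).  Non-nested
    pairs: AIC.  Ties favour fewer parameters.  A rationale string is left in
    the winner's ``message``.
    """
    if not fits:
        raise ValidationError("empty candidate list")
    threshold_per_df = float(stats.chi2.ppf(1.0 - alpha, 1))
    ordered = sorted(fits, key=lambda f: (N_FIXED[f.form], FORMS.index(f.form)))
    best = ordered[0]
    notes = [f"start: {best.form} (OFV {best.ofv:.3f})"]
    for cand in ordered[1:]:
        if not cand.converged:
            notes.append(f"{cand.form}: skipped (non-converged)")
            continue
        if _nested(best.form, cand.form):
            ddf = N_FIXED[cand.form] - N_FIXED[best.form]
            dofv = best.ofv - cand.ofv
            if dofv > threshold_per_df * ddf:
                notes.append(f"{cand.form} beats {best.form} (dOFV {dofv:.3f} > "
                             f"{threshold_per_df * ddf:.2f})")
                best = cand
            else:
                notes.append(f"{cand.form} rejected vs {best.form} (dOFV {dofv:.3f})")
        else:
            if cand.aic < best.aic - 1e-9:
                notes.append(f"{cand.form} beats {best.form} by AIC "
                             f"({cand.aic:.3f} < {best.aic:.3f})")
                best = cand
            else:
                notes.append(f"{cand.form} rejected vs {best.form} by AIC")
    best.message = "; ".join(notes)
    return best


def fit_hierarchy(
    observations: pd.DataFrame,
    forms: tuple = FORMS,
    value_col: str = "value",
    alpha: float = 0.05,
) -> tuple[CqtModelFit, list[CqtModelFit]]:
    """Fit every requested structural form and select the final model."""
    fits = []
    for form in forms:
        try:
            fits.append(fit_cqt(observations, form, value_col=value_col))
        except (FitError, InsufficientDataError) as exc:
            fits.append(CqtModelFit(form=form, converged=False, message=str(exc)))
    usable = [f for f in fits if f.converged]
    if not usable:
        raise FitError("no structural model converged")
    return select_model(usable, alpha=alpha), fits


def bootstrap_cqt(
    observations: pd.DataFrame,
    form: str,
    B: int = 1000,
    seed: int = 0,
    value_col: str = "value",
    n_grid: int = 50,
) -> dict:
    """Subject-resampling bootstrap of one structural model.

    Resamples subjects with replacement B times and refits.  Returns
    per-parameter medians and 5th/95th percentiles, a 90% band for the
    population-predicted line over the observed concentration range, and the
    count of failed replicates (dropped; a warning is raised when more than
    20% fail).  Deterministic given ``seed``.
    """
    if B < 1:
        raise ValidationError("B must be >= 1")
    rng = np.random.default_rng(seed)
    obs = observations.dropna(subset=[value_col, "conc_nM"])
    blocks = {
        sid: (g["conc_nM"].to_numpy(dtype=float), g[value_col].to_numpy(dtype=float))
        for sid, g in obs.groupby("subject_id", sort=True)
    }
    subjects = sorted(blocks)
    grid = np.linspace(0.0, float(obs["conc_nM"].max()), n_grid)
    params_rows, curves = [], []
    n_failed = 0
    for b in range(B):
        picks = rng.choice(len(subjects), size=len(subjects), replace=True)
        conc = np.concatenate([blocks[subjects[k]][0] for k in picks])
        y = np.concatenate([blocks[subjects[k]][1] for k in picks])
        ids = np.repeat(np.arange(len(picks)),
                        [len(blocks[subjects[k]][0]) for k in picks])
        try:
            f = _fit_data(_Grouped(ids, conc, y), None, form, (), compute_se=False)
        except (FitError, InsufficientDataError, ValidationError):
            n_failed += 1
            continue
        params_rows.append(dict(f.theta, omega=f.omega, sigma=f.sigma))
        curves.append(f.predict(grid))
    if n_failed > 0.2 * B:
        warnings.warn(f"bootstrap: {n_failed}/{B} replicates failed to fit")
    params = pd.DataFrame(params_rows)
    summary = pd.DataFrame({
        "median": params.median(),
        "p5": params.quantile(0.05),
        "p95": params.quantile(0.95),
    })
    band = None
    if curves:
        C = np.vstack(curves)
        band = pd.DataFrame({
            "conc_nM": grid,
            "median": np.median(C, axis=0),
            "p5": np.quantile(C, 0.05, axis=0),
            "p95": np.quantile(C, 0.95, axis=0),
        })
    return {"parameters": summary, "band": band, "n_failed": n_failed,
            "n_success": B - n_failed, "replicates": params}


def screen_covariates(
    observations: pd.DataFrame,
    form: str = "no_effect",
    covariates: tuple = ("sex", "bmi", "ecog"),
    alpha: float = 0.01,
    value_col: str = "value",
) -> dict:
    """Forward-addition covariate screening on the model intercept.

    Each covariate is tested as an additive intercept shift by a 1-df
    likelihood-ratio test; the most significant covariate with p < alpha is
    added and screening repeats until no addition qualifies.  Constant
    covariates are skipped (logged in the report).  Returns the retained
    list, per-covariate p-values from their first test, and the final fit.
    """
    import logging

    log = logging.getLogger(__name__)
    candidates = []
    skipped = []
    for c in covariates:
        v = observations[c].dropna()
        if v.nunique() < 2:
            skipped.append(c)
            log.info("covariate %s constant; skipped", c)
        else:
            candidates.append(c)
    retained: list[str] = []
    pvalues: dict[str, float] = {}
    base = fit_cqt(observations, form, value_col=value_col,
                   covariate_cols=tuple(retained), compute_se=False)
    while candidates:
        trials = []
        for c in candidates:
            f = fit_cqt(observations, form, value_col=value_col,
                        covariate_cols=tuple(retained + [c]), compute_se=False)
            p = float(stats.chi2.sf(max(base.ofv - f.ofv, 0.0), 1))
            pvalues.setdefault(c, p)
            trials.append((p, c, f))
        trials.sort()
        p_best, c_best, f_best = trials[0]
        if p_best < alpha:
            retained.append(c_best)
            candidates.remove(c_best)
            base = f_best
        else:
            break
    final = fit_cqt(observations, form, value_col=value_col, covariate_cols=tuple(retained))
    return {"retained": retained, "pvalues": pvalues, "skipped": skipped, "fit": final}


def fit_hr_model(
    observations: pd.DataFrame, forms: tuple = ("no_effect", "linear"),
    value_col: str = "value", alpha: float = 0.05,
) -> tuple[CqtModelFit, list[CqtModelFit]]:
    """Concentration-HR model: same machinery on heart-rate observations.

    The intercept is freely estimated (a population heart rate, not forced
    to zero), so this is just the hierarchy applied to HR values.
    """
    return fit_hierarchy(observations, forms=forms, value_col=value_col, alpha=alpha)
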