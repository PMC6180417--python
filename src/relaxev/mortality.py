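"""Two-stage Gompertz mortality model with a late-life plateau, and its
nonlinear mixed-effects fit across replicate populations.

The hazard is Gompertz (A * exp(alpha * t)) up to a break day ``bd`` and
constant at A * exp(alpha * bd) afterwards, giving the survivorship

    p_t = exp(A * (1 - exp(alpha*t)) / alpha)                      for t <= bd
    p_t = exp(A * (1 - exp(alpha*bd)) / alpha
              + A * exp(alpha*bd) * (bd - t))                      for t >  bd

and daily mortality q_t = 1 - p_{t+1} / p_t.  ``A`` is the age-independent
baseline hazard per day, ``alpha`` the age-dependent rate of aging and ``bd``
the age at which mortality transitions to the plateau.

Across populations the three parameters carry regime and sex fixed effects
plus a shared per-population random effect (additive on the natural scale),
with residual variance growing with age as sigma^2 * |t|^(2*Delta).  The fit
is a global two-stage scheme: per-population(-per-sex) weighted nonlinear
least squares on observed daily mortality, then exact marginal REML of the
stage-one estimates with the stage-one sampling covariances propagated.
Directions of parameter space the data do not constrain (for example a break
day beyond the last observed death) receive a very large sampling variance
rather than a spuriously tight one.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "GompertzParams", "survivorship", "daily_mortality",
    "GompertzNLMEFit", "fit_gompertz_nlme", "compare_gompertz_models",
    "MeanLongevity", "mean_longevity",
]

_ALPHA_TINY = 1e-8
PARAM_NAMES = ("A", "alpha", "bd")


@dataclass(frozen=True)
class GompertzParams:
    """Parameters of the plateau Gompertz model.

    A: baseline hazard per day (> 0); alpha: rate of aging per day (any real,
    the alpha -> 0 limit is constant hazard); bd: break day in days (>= 0).
    """

    A: float
    alpha: float
    bd: float

    def __post_init__(self):
        if not all(np.isfinite([self.A, self.alpha, self.bd])):
            raise ValueError("non-finite Gompertz parameters")
        if self.A <= 0:
            raise ValueError("A must be positive")
        if self.bd < 0:
            raise ValueError("break day must be non-negative")


def _cumhaz_gompertz(A: float, alpha: float, t: np.ndarray) -> np.ndarray:
    """Integrated Gompertz hazard A*(exp(alpha t)-1)/alpha, series-safe at alpha->0."""
    if abs(alpha) < _ALPHA_TINY:
        return A * t * (1.0 + 0.5 * alpha * t)
    return A * (np.exp(alpha * t) - 1.0) / alpha


def survivorship(params: GompertzParams, t) -> np.ndarray | float:
    """Probability of surviving to age ``t`` (days), p_0 = 1."""
    t_arr = np.asarray(t, dtype=float)
    if (t_arr < 0).any():
        raise ValueError("t must be non-negative")
    A, alpha, bd = params.A, params.alpha, params.bd
    below = -_cumhaz_gompertz(A, alpha, np.minimum(t_arr, bd))
    plateau_h = A * np.exp(alpha * bd)
    above = plateau_h * np.maximum(t_arr - bd, 0.0)
    out = np.exp(below - above)
    return out if out.ndim else float(out)


def daily_mortality(params: GompertzParams, t) -> np.ndarray | float:
    """Chance of dying between day ``t`` and ``t``+1: q_t = 1 - p_{t+1}/p_t.

    Where p_t underflows to zero, q_t is defined as 1 (with a warning)."""
    t_arr = np.asarray(t, dtype=float)
    pt = np.asarray(survivorship(params, t_arr))
    pt1 = np.asarray(survivorship(params, t_arr + 1.0))
    with np.errstate(invalid="ignore", divide="ignore"):
        q = np.where(pt > 0, 1.0 - pt1 / pt, 1.0)
    if (pt == 0).any():
        warnings.warn("survivorship underflow: q_t set to 1 where p_t = 0", stacklevel=2)
    q = np.clip(q, 0.0, 1.0)
    return q if q.ndim else float(q)


# ---------------------------------------------------------------------------
# stage 1: per-series weighted nonlinear least squares on observed q_t


def _qcurve(theta_nat: np.ndarray, t: np.ndarray) -> np.ndarray:
    A, alpha, bd = theta_nat
    p = GompertzParams(max(A, 1e-12), alpha, max(bd, 0.0))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return np.asarray(daily_mortality(p, t))


def _fit_series(t: np.ndarray, qhat: np.ndarray, at_risk: np.ndarray,
                delta: float = 0.0, bd_grid: np.ndarray | None = None):
    """Weighted NLS of the plateau-Gompertz q_t to one mortality series.

    Weights combine the binomial information (at-risk count) with the
    power-of-age variance model: w_t = at_risk_t * |t|^(-2*delta).  The break
    day is profiled over a grid (ties toward the smaller bd) and then refined
    continuously.  Returns the natural-scale estimates, their eigenvalue-
    floored covariance, the residual scale and the weighted RSS.
    """
    keep = at_risk > 0
    t, qhat, at_risk = t[keep], qhat[keep], at_risk[keep]
    if len(t) < 4:
        raise ValueError("need at least 4 ages with at-risk > 0")
    w = at_risk * np.where(t > 0, t, 1.0) ** (-2.0 * delta)
    sw = np.sqrt(w)

    # moment start for (A, alpha) from the daily log-hazard
    h = -np.log(np.clip(1.0 - qhat, 1e-10, 1.0))
    pos = h > 0
    if pos.sum() >= 2:
        slope, intercept = np.polyfit(t[pos] + 0.5, np.log(h[pos]), 1)
        alpha0 = float(np.clip(slope, -1.0, 1.0))
        A0 = float(np.clip(np.exp(intercept), 1e-8, 1.0))
    else:
        alpha0, A0 = 0.05, max(qhat.mean(), 1e-4)

    tmax = float(t.max())
    if bd_grid is None:
        bd_grid = np.unique(np.concatenate([
            np.linspace(max(2.0, 0.2 * tmax), 1.5 * tmax, 25), [2.0 * tmax]]))

    def resid_eta2(eta2, bd):
        th = np.array([np.exp(eta2[0]), eta2[1], bd])
        return sw * (_qcurve(th, t) - qhat)

    best = None
    profile = []
    x0 = np.array([np.log(A0), alpha0])
    for bd in bd_grid:  # ascending grid; strict improvement keeps the smaller bd
        sol = optimize.least_squares(resid_eta2, x0, args=(bd,), method="lm",
                                     max_nfev=200)
        profile.append((bd, sol.cost))
        if best is None or sol.cost < best[0] - 1e-12:
            best = (sol.cost, sol.x, bd)
    _, eta2, bd0 = best

    def resid_eta3(eta):
        th = np.array([np.exp(eta[0]), eta[1], np.exp(eta[2])])
        return sw * (_qcurve(th, t) - qhat)

    sol = optimize.least_squares(resid_eta3, np.array([eta2[0], eta2[1], np.log(bd0)]),
                                 method="lm", max_nfev=500)
    theta = np.array([np.exp(sol.x[0]), sol.x[1], np.exp(sol.x[2])])
    rss = 2.0 * sol.cost
    dof = max(len(t) - 3, 1)
    sigma2 = rss / dof

    # covariance on the natural scale via finite differences, eigen-floored
    J = np.empty((len(t), 3))
    for m in range(3):
        step = 1e-6 * max(abs(theta[m]), 1e-6)
        up, dn = theta.copy(), theta.copy()
        up[m] += step
        dn[m] -= step
        J[:, m] = sw * (_qcurve(up, t) - _qcurve(dn, t)) / (2 * step)
    H = J.T @ J
    evals, evecs = np.linalg.eigh(H)
    floor = max(evals.max(), 1e-30) * 1e-10
    V = sigma2 * (evecs @ np.diag(1.0 / np.maximum(evals, floor)) @ evecs.T)

    # Break-day uncertainty from the profile: the local Jacobian understates
    # it badly when the likelihood is flat in bd (a plateau beyond the last
    # observed deaths).  Take the half-width of the 1-sigma profile set
    # {bd: cost <= cost_min + sigma2/2} as a variance lower bound for bd.
    costs = np.array([c for _, c in profile])
    grid = np.array([bd for bd, _ in profile])
    inset = grid[costs <= costs.min() + 0.5 * sigma2]
    if len(inset) >= 2:
        half_width = 0.5 * (inset.max() - inset.min())
        V[2, 2] = max(V[2, 2], half_width**2)
    return theta, V, sigma2, rss, len(t)


def _estimate_delta(series_fits, data_series) -> float:
    """Pooled power-variance exponent: regress log(resid^2 * at_risk) on log t."""
    logs, logt = [], []
    for (theta, *_), (t, qhat, at_risk) in zip(series_fits, data_series):
        keep = (at_risk > 0) & (t > 0)
        r = qhat[keep] - _qcurve(theta, t[keep])
        v = r**2 * at_risk[keep]
        ok = v > 0
        logs.append(np.log(v[ok]))
        logt.append(np.log(t[keep][ok]))
    logs, logt = np.concatenate(logs), np.concatenate(logt)
    if len(logs) < 5:
        return 0.0
    slope = np.polyfit(logt, logs, 1)[0]
    return float(np.clip(slope / 2.0, -3.0, 3.0))


# ---------------------------------------------------------------------------
# stage 2: marginal REML of stage-one estimates


@dataclass
class GompertzNLMEFit:
    """Fixed effects, random-effect variances and diagnostics of the
    population-level Gompertz mixed model."""

    fixed: pd.DataFrame            # rows like "A:baseline", "A:regime", ...
    Sigma_b: pd.DataFrame          # 3x3 (diagonal) random-effect covariance
    delta: float                   # power-of-age variance exponent
    sigma: float                   # stage-one residual scale (pooled)
    blups: pd.DataFrame            # per-population random-effect predictions
    series: pd.DataFrame           # per-series stage-one estimates
    loglik: float
    aic: float
    bic: float
    df: int
    converged: bool
    random_effects: tuple = PARAM_NAMES
    variance: str = "power"

    def estimate(self, name: str) -> float:
        return float(self.fixed.loc[name, "estimate"])

    def pvalue(self, name: str) -> float:
        return float(self.fixed.loc[name, "p"])


def _design_row(regime_is_alt: bool, sex_is_alt: bool | None, with_sex: bool):
    row = [1.0, 1.0 if regime_is_alt else 0.0]
    if with_sex:
        row.append(1.0 if sex_is_alt else 0.0)
    return row


def fit_gompertz_nlme(data: pd.DataFrame, variance: str = "power",
                      random_effects=PARAM_NAMES) -> GompertzNLMEFit:
    """Fit the plateau-Gompertz mixed model to daily cohort mortality.

    ``data`` needs columns population, regime, day, deaths, at_risk and
    optionally sex; each population (x sex) series is fit separately and the
    estimates combined by marginal REML with a diagonal random-effect
    covariance shared within population.  ``variance`` selects the
    power-of-age residual model or the constant-variance variant;
    ``random_effects`` restricts which of A, alpha, bd carry population
    variation (the others' variances are pinned at zero).
    """
    req = {"population", "regime", "day", "deaths", "at_risk"}
    if not req <= set(data.columns):
        raise ValueError(f"data missing columns: {sorted(req - set(data.columns))}")
    with_sex = "sex" in data.columns and data["sex"].nunique() > 1
    pops = sorted(data["population"].unique())
    if len(pops) < 2:
        raise ValueError("need at least 2 populations")
    regimes = sorted(data["regime"].unique(), key=lambda r: (r != "TDO", r))
    if len(regimes) != 2:
        raise ValueError("need exactly two regimes")
    sexes = sorted(data["sex"].unique(), key=lambda s: (s != "F", s)) if with_sex else [None]

    series_keys, series_fits, data_series = [], [], []
    group_cols = ["population"] + (["sex"] if with_sex else [])
    for key, sub in data.groupby(group_cols):
        key = key if isinstance(key, tuple) else (key,)
        sub = sub.sort_values("day")
        t = sub["day"].to_numpy(dtype=float)
        n_pos = int((sub["at_risk"] > 0).sum())
        if n_pos < 10:
            raise ValueError(f"series {key} has fewer than 10 ages with at-risk > 0")
        at_risk = sub["at_risk"].to_numpy(dtype=float)
        qhat = np.where(at_risk > 0, sub["deaths"].to_numpy(dtype=float) / np.maximum(at_risk, 1), 0.0)
        data_series.append((t, qhat, at_risk))
        series_keys.append(key)

    delta = 0.0
    for _ in range(2 if variance == "power" else 1):
        series_fits = [_fit_series(t, q, n, delta=delta) for (t, q, n) in data_series]
        if variance != "power":
            break
        delta = _estimate_delta(series_fits, data_series)

    pop_regime = data.groupby("population")["regime"].first()
    # per-series design rows: baseline, regime contrast (+ sex contrast)
    eff_names = ["baseline", "regime"] + (["sex"] if with_sex else [])
    n_eff = len(eff_names)
    by_pop: dict = {}
    for key, fit in zip(series_keys, series_fits):
        pop = key[0]
        sex = key[1] if with_sex else None
        row = _design_row(pop_regime[pop] != regimes[0],
                          (sex != sexes[0]) if with_sex else None, with_sex)
        by_pop.setdefault(pop, []).append((row, fit[0], fit[1]))

    re_mask = np.array([name in random_effects for name in PARAM_NAMES])
    theta_mat = np.array([fit[0] for fit in series_fits])
    v_diag_mean = np.mean([np.diag(fit[1]) for fit in series_fits], axis=0)
    start_var = np.maximum(theta_mat.var(axis=0, ddof=1) - v_diag_mean, 1e-4 * np.maximum(theta_mat.var(axis=0, ddof=1), 1e-12))

    def assemble(pop_entries, Sigma_diag):
        rows = []
        X = []
        for row, theta, _ in pop_entries:
            rows.append(theta)
            X.append(np.kron(np.eye(3), np.asarray(row)[None, :]))  # (3, 3*n_eff)
        y = np.concatenate(rows)
        Xk = np.vstack(X)
        ns = len(pop_entries)
        W = np.zeros((3 * ns, 3 * ns))
        for i, (_, _, V) in enumerate(pop_entries):
            W[3 * i:3 * i + 3, 3 * i:3 * i + 3] = V
        Sb = np.diag(Sigma_diag)
        for i in range(ns):
            for j in range(ns):
                W[3 * i:3 * i + 3, 3 * j:3 * j + 3] += Sb
        return y, Xk, W

    def reml_nll(log_tau2):
        Sigma_diag = np.zeros(3)
        Sigma_diag[re_mask] = np.exp(log_tau2)
        XtWX = np.zeros((3 * n_eff, 3 * n_eff))
        XtWy = np.zeros(3 * n_eff)
        nll = 0.0
        blocks = []
        for pop in pops:
            y, Xk, W = assemble(by_pop[pop], Sigma_diag)
            try:
                L = np.linalg.cholesky(W)
            except np.linalg.LinAlgError:
                return 1e12, None, None
            Wi_y = np.linalg.solve(W, y)
            Wi_X = np.linalg.solve(W, Xk)
            nll += np.linalg.slogdet(W)[1]
            XtWX += Xk.T @ Wi_X
            XtWy += Xk.T @ Wi_y
            blocks.append((pop, y, Xk, W))
        try:
            beta = np.linalg.solve(XtWX, XtWy)
        except np.linalg.LinAlgError:
            return 1e12, None, None
        quad = 0.0
        for pop, y, Xk, W in blocks:
            r = y - Xk @ beta
            quad += r @ np.linalg.solve(W, r)
        nll = 0.5 * (nll + quad + np.linalg.slogdet(XtWX)[1])
        return nll, beta, XtWX

    n_re = int(re_mask.sum())
    x0 = np.log(np.maximum(start_var[re_mask], 1e-12))
    if n_re > 0:
        res = optimize.minimize(lambda x: reml_nll(x)[0], x0, method="Nelder-Mead",
                                options={"xatol": 1e-4, "fatol": 1e-6, "maxiter": 600})
        log_tau2 = res.x
        converged = bool(res.success)
    else:
        log_tau2 = np.empty(0)
        converged = True
    nll, beta, XtWX = reml_nll(log_tau2)
    if beta is None:
        raise RuntimeError("Gompertz NLME failed to converge: singular covariance")
    cov_beta = np.linalg.inv(XtWX)
    Sigma_diag = np.zeros(3)
    Sigma_diag[re_mask] = np.exp(log_tau2)

    dof = len(pops) - 2
    names = [f"{pn}:{en}" for pn in PARAM_NAMES for en in eff_names]
    se = np.sqrt(np.diag(cov_beta))
    tvals = beta / se
    fixed = pd.DataFrame({"estimate": beta, "se": se, "t": tvals,
                          "p": 2 * stats.t.sf(np.abs(tvals), dof)}, index=names)

    # BLUPs of the population random effects
    blup_rows = {}
    Sb = np.diag(Sigma_diag)
    for pop in pops:
        y, Xk, W = assemble(by_pop[pop], Sigma_diag)
        ns = len(by_pop[pop])
        Z = np.kron(np.ones((ns, 1)), np.eye(3))
        r = y - Xk @ beta
        blup_rows[pop] = Sb @ Z.T @ np.linalg.solve(W, r)
    blups = pd.DataFrame(blup_rows, index=PARAM_NAMES).T

    n_var_params = n_re + (1 if variance == "power" else 0)
    k = len(beta) + n_var_params
    n_obs_stage2 = 3 * len(series_keys)
    loglik = -nll - 0.5 * n_obs_stage2 * np.log(2 * np.pi)
    aic = 2 * k - 2 * loglik
    bic = k * np.log(n_obs_stage2) - 2 * loglik

    series_df = pd.DataFrame(
        [dict(zip(["population"] + (["sex"] if with_sex else []), key),
              A=fit[0][0], alpha=fit[0][1], bd=fit[0][2], sigma2=fit[2])
         for key, fit in zip(series_keys, series_fits)])
    return GompertzNLMEFit(
        fixed=fixed,
        Sigma_b=pd.DataFrame(np.diag(Sigma_diag), index=PARAM_NAMES, columns=PARAM_NAMES),
        delta=delta, sigma=float(np.sqrt(np.mean([f[2] for f in series_fits]))),
        blups=blups, series=series_df, loglik=float(loglik), aic=float(aic),
        bic=float(bic), df=dof, converged=converged,
        random_effects=tuple(random_effects), variance=variance,
    )


def compare_gompertz_models(data: pd.DataFrame,
                            random_subsets=None,
                            variances=("power", "constant")) -> pd.DataFrame:
    """Fit the mixed model with population variation on subsets of the
    parameters and with the power vs constant residual-variance model, and
    report AIC/BIC for each variant (lowest is the selected model)."""
    if random_subsets is None:
        random_subsets = [PARAM_NAMES, ("A", "alpha"), ("A",), ()]
    rows = []
    for re_set, var in itertools.product(random_subsets, variances):
        try:
            fit = fit_gompertz_nlme(data, variance=var, random_effects=tuple(re_set))
            rows.append({"random_effects": "+".join(re_set) or "none", "variance": var,
                         "loglik": fit.loglik, "aic": fit.aic, "bic": fit.bic,
                         "converged": fit.converged})
        except (RuntimeError, ValueError) as exc:
            rows.append({"random_effects": "+".join(re_set) or "none", "variance": var,
                         "loglik": np.nan, "aic": np.nan, "bic": np.nan,
                         "converged": False, "error": str(exc)})
    return pd.DataFrame(rows).sort_values("aic").reset_index(drop=True)


# ---------------------------------------------------------------------------
# mean longevity


@dataclass
class MeanLongevity:
    population_means: pd.DataFrame  # per population (x sex): mean, n
    regime_means: pd.Series
    contrast: float                 # TDO mean minus TSO mean (population-weighted)


def mean_longevity(records: pd.DataFrame) -> MeanLongevity:
    """Per-population, per-regime (and per-sex when present) mean death day,
    with the regime contrast computed from equally weighted population means."""
    req = {"population", "regime", "death_day"}
    if not req <= set(records.columns):
        raise ValueError(f"records missing columns: {sorted(req - set(records.columns))}")
    if records.empty:
        raise ValueError("empty records")
    by = ["population", "regime"] + (["sex"] if "sex" in records.columns else [])
    pop_means = records.groupby(by)["death_day"].agg(["mean", "count"]).reset_index()
    per_pop = records.groupby(["population", "regime"])["death_day"].mean().reset_index()
    regime_means = per_pop.groupby("regime")["death_day"].mean()
    for r in regime_means.index:
        if (per_pop["regime"] == r).sum() == 0:
            raise ValueError(f"empty regime group {r}")
    tdo = regime_means.get("TDO", np.nan)
    tso = regime_means.get("TSO", np.nan)
    if np.isnan(tdo) or np.isnan(tso):
        # generic two-group fallback: second level minus first
        levels = list(regime_means.index)
        contrast = float(regime_means[levels[1]] - regime_means[levels[0]]) if len(levels) == 2 else np.nan
    else:
        contrast = float(tdo - tso)
    return MeanLongevity(population_means=pop_means, regime_means=regime_means,
                         contrast=contrast)
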