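"""Phenotype-level inference for replicated selection experiments.

Replicate populations, not individual flies, are the unit of replication:
fixed-effect tests for the selection-regime contrast therefore use
among-population denominator degrees of freedom (n_pops - 2), which keeps the
type-I error calibrated when traits are compared between two groups of five
populations.  The module provides

* one- and two-factor linear mixed models (regime, sex, their interaction,
  population random intercept),
* the piecewise-linear interval fecundity mixed model,
* a daily-mortality logistic regression for a regime x treatment exposure
  assay,
* the continuity-corrected Cochran-Mantel-Haenszel test over K stratified
  2x2 tables, and
* simulation-based power and minimum-detectable-difference calculations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "cmh_counts", "ContingencySet", "CMHResult", "cmh_test",
    "LMEFit", "fit_lme", "FecundityFit", "fit_fecundity",
    "LogisticFit", "fit_daily_logistic",
    "power_by_simulation", "detectable_difference",
]


# ---------------------------------------------------------------------------
# Cochran-Mantel-Haenszel


def cmh_counts(a, b, c, d, continuity: bool = True):
    """CMH statistic over K stratified 2x2 tables [[a, b], [c, d]].

    Accepts scalars, 1-d arrays of length K, or 2-d arrays (n_tests, K) and
    broadcasts over the leading axis.  With ``continuity`` the statistic is

        X^2 = (|sum_i [a_i - (a_i+b_i)(a_i+c_i)/n_i]| - 0.5)^2 / D,
        D   = sum_i (a_i+b_i)(a_i+c_i)(b_i+d_i)(c_i+d_i) / (n_i^3 - n_i^2)

    and without it the 0.5 is omitted.  Degenerate strata with n_i = 0
    contribute zero to both sums.  Returns (statistic, chi2_1 upper-tail p).
    """
    a, b, c, d = (np.atleast_1d(np.asarray(x, dtype=float)) for x in (a, b, c, d))
    n = a + b + c + d
    ok = n > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        num_terms = np.where(ok, a - (a + b) * (a + c) / n, 0.0)
        den_terms = np.where(ok, (a + b) * (a + c) * (b + d) * (c + d) / (n**3 - n**2), 0.0)
    s = num_terms.sum(axis=-1)
    dd = den_terms.sum(axis=-1)
    if continuity:
        num = (np.abs(s) - 0.5) ** 2
    else:
        num = s**2
    with np.errstate(invalid="ignore", divide="ignore"):
        stat = np.where(dd > 0, num / dd, 0.0)
    p = stats.chi2.sf(stat, 1)
    p = np.where(dd > 0, p, 1.0)
    if stat.ndim == 0:
        return float(stat), float(p)
    return stat, p


@dataclass
class ContingencySet:
    """K stratified 2x2 tables with cells [[a, b], [c, d]] per stratum."""

    a: np.ndarray
    b: np.ndarray
    c: np.ndarray
    d: np.ndarray

    def __post_init__(self) -> None:
        self.a, self.b, self.c, self.d = (
            np.asarray(x, dtype=np.int64) for x in (self.a, self.b, self.c, self.d))
        if not (len(self.a) == len(self.b) == len(self.c) == len(self.d)):
            raise ValueError("cell vectors must have equal length")
        if any((x < 0).any() for x in (self.a, self.b, self.c, self.d)):
            raise ValueError("cells must be non-negative")

    @property
    def n(self) -> np.ndarray:
        return self.a + self.b + self.c + self.d

    @classmethod
    def from_binary_records(cls, records: pd.DataFrame, stratum: str = "stratum",
                            group: str = "regime", outcome: str = "outcome",
                            group_levels=None) -> "ContingencySet":
        """Build strata from record-level binary outcomes.

        ``a``/``c`` are successes/failures in the first group level, ``b``/``d``
        in the second, within each stratum.
        """
        levels = group_levels or sorted(records[group].unique())
        if len(levels) != 2:
            raise ValueError("need exactly two group levels")
        g = records.groupby([stratum, group])[outcome].agg(["sum", "count"]).unstack(group)
        a = g[("sum", levels[0])].to_numpy()
        b = g[("sum", levels[1])].to_numpy()
        c = g[("count", levels[0])].to_numpy() - a
        d = g[("count", levels[1])].to_numpy() - b
        return cls(a, b, c, d)


@dataclass
class CMHResult:
    statistic: float
    pvalue: float
    dof: int = 1
    continuity: bool = True


def cmh_test(tables: ContingencySet, continuity: bool = True) -> CMHResult:
    """Continuity-corrected (by default) CMH test of conditional independence."""
    if len(tables.a) < 1:
        raise ValueError("need at least one stratum")
    stat, p = cmh_counts(tables.a, tables.b, tables.c, tables.d, continuity=continuity)
    return CMHResult(statistic=stat, pvalue=p, continuity=continuity)


# ---------------------------------------------------------------------------
# linear mixed models on individual phenotype records
#
# delta-coding follows the experiment's convention: regime level 1 (TDO) and
# sex level 1 (female) are the reference, so alpha is the TDO-female mean,
# beta the TSO offset, gamma the male offset and pi the TSO-male interaction.

REGIME_REF = "TDO"
SEX_REF = "F"


@dataclass
class LMEFit:
    """Fixed effects, variance components and among-population tests."""

    effects: pd.DataFrame          # index alpha/beta[/gamma/pi]: estimate, se, t, p
    sigma1_sq: float               # between-population variance
    sigma2_sq: float               # residual (within-population) variance
    n_pops: int
    n_obs: int
    df: int                        # denominator df for the fixed-effect tests
    singular: bool = False

    def __getitem__(self, name: str) -> float:
        return float(self.effects.loc[name, "estimate"])

    def pvalue(self, name: str) -> float:
        return float(self.effects.loc[name, "p"])


def _pop_cell_means(records: pd.DataFrame, by):
    g = records.groupby(by, observed=True)["value"]
    return g.mean(), g.count()


def fit_lme(records: pd.DataFrame, design: str = "regime") -> LMEFit:
    """Fit the replicated-population mixed model by its balanced closed form.

    ``design='regime'`` fits y = alpha + delta_regime*beta + b_pop + eps;
    ``design='regime_sex'`` adds sex and the regime x sex interaction.  The
    regime contrast is tested on population(-level) means with a two-sample t
    on n_pops - 2 df; in the two-factor design, sex and interaction are tested
    on within-population sex differences (the split-plot within stratum), also
    on n_pops - 2 df.  Variance components are method-of-moments estimates.
    """
    req = {"value", "regime", "population"}
    if design == "regime_sex":
        req.add("sex")
    missing = req - set(records.columns)
    if missing:
        raise ValueError(f"records missing columns: {sorted(missing)}")
    regimes = sorted(records["regime"].unique(), key=lambda r: (r != REGIME_REF, r))
    if len(regimes) != 2:
        raise ValueError("need exactly two regimes")
    ref, alt = regimes
    pops_by_regime = records.groupby("regime")["population"].nunique()
    if (pops_by_regime < 2).any():
        raise ValueError("need >=2 populations per regime")
    n_pops = int(records["population"].nunique())
    dof = n_pops - 2

    pop_regime = records.groupby("population")["regime"].first()

    def two_sample(series: pd.Series):
        """two-sample comparison of per-population statistics between regimes"""
        x = series[pop_regime[series.index] == ref].to_numpy(dtype=float)
        y = series[pop_regime[series.index] == alt].to_numpy(dtype=float)
        sp2 = (((x - x.mean()) ** 2).sum() + ((y - y.mean()) ** 2).sum()) / (len(x) + len(y) - 2)
        est = y.mean() - x.mean()
        se = np.sqrt(sp2 * (1 / len(x) + 1 / len(y)))
        se_ref = np.sqrt(sp2 / len(x))
        return x.mean(), est, se, se_ref, sp2

    rows = {}
    if design == "regime":
        pm, _ = _pop_cell_means(records, "population")
        a_hat, b_hat, se_b, se_a, sp2 = two_sample(pm)
        singular = sp2 <= 0
        tvals = {"alpha": a_hat / se_a if se_a > 0 else np.inf,
                 "beta": b_hat / se_b if se_b > 0 else np.inf}
        rows["alpha"] = (a_hat, se_a, tvals["alpha"])
        rows["beta"] = (b_hat, se_b, tvals["beta"])
        between_var = sp2
    elif design == "regime_sex":
        sexes = sorted(records["sex"].unique(), key=lambda s: (s != SEX_REF, s))
        if len(sexes) != 2:
            raise ValueError("need exactly two sexes")
        cm, _ = _pop_cell_means(records, ["population", "sex"])
        cm = cm.unstack("sex")
        fem, male = cm[sexes[0]], cm[sexes[1]]
        a_hat, b_hat, se_b, se_a, sp2f = two_sample(fem)
        diff = male - fem
        g_hat_ref_mean, pi_hat, se_pi, se_g, sp2d = two_sample(diff)
        rows["alpha"] = (a_hat, se_a, a_hat / se_a if se_a > 0 else np.inf)
        rows["beta"] = (b_hat, se_b, b_hat / se_b if se_b > 0 else np.inf)
        rows["gamma"] = (g_hat_ref_mean, se_g,
                         g_hat_ref_mean / se_g if se_g > 0 else np.inf)
        rows["pi"] = (pi_hat, se_pi, pi_hat / se_pi if se_pi > 0 else np.inf)
        singular = sp2f <= 0 and sp2d <= 0
        pm, _ = _pop_cell_means(records, "population")
        _, _, _, _, between_var = two_sample(pm)
    else:
        raise ValueError(f"unknown design: {design}")

    # variance components by method of moments
    resid_var = records.groupby(
        ["population"] + (["sex"] if design == "regime_sex" else []), observed=True
    )["value"].var(ddof=1)
    sigma2_sq = float(np.nanmean(resid_var))
    n_harm = stats.hmean(records.groupby("population")["value"].count())
    sigma1_sq = float(max(0.0, between_var - sigma2_sq / n_harm))

    eff = pd.DataFrame(
        {k: {"estimate": v[0], "se": v[1], "t": v[2],
             "p": 2 * stats.t.sf(abs(v[2]), dof)} for k, v in rows.items()}
    ).T[["estimate", "se", "t", "p"]]
    if singular:
        warnings.warn("singular fit: no between-population variation", stacklevel=2)
    return LMEFit(effects=eff, sigma1_sq=sigma1_sq, sigma2_sq=sigma2_sq,
                  n_pops=n_pops, n_obs=len(records), df=dof, singular=singular)


# ---------------------------------------------------------------------------
# interval fecundity model


@dataclass
class FecundityFit:
    """Piecewise-linear interval fecundity mixed model.

    Fecundity is linear in age within each interval; the selection regime can
    shift the intercept (overall and per interval) but not the slope.  The
    per-interval regime contrast in interval k is gamma (k = reference) or
    gamma + mu_k, tested with t on n_pops - 2 df.
    """

    params: pd.Series
    cov: pd.DataFrame
    interval_contrasts: pd.DataFrame  # per interval: estimate, se, t, p
    sigma_c_sq: float
    sigma_e_sq: float
    n_pops: int
    df: int
    converged: bool


def assign_intervals(age: np.ndarray, intervals) -> np.ndarray:
    """Map ages (days) to 1-based interval indices; unassigned ages raise."""
    age = np.asarray(age, dtype=float)
    idx = np.full(len(age), -1)
    for k, (lo, hi) in enumerate(intervals, start=1):
        idx[(age >= lo) & (age <= hi)] = k
    if (idx < 0).any():
        bad = age[idx < 0][0]
        raise ValueError(f"age {bad} falls outside all intervals")
    return idx


def fit_fecundity(records: pd.DataFrame, intervals) -> FecundityFit:
    """REML fit of the interval fecundity model with a population random
    intercept (statsmodels MixedLM under the hood)."""
    from statsmodels.regression.mixed_linear_model import MixedLM

    df = records.copy()
    df["interval"] = assign_intervals(df["age"].to_numpy(), intervals)
    K = int(df["interval"].max())
    for k in range(1, K + 1):
        if not (df["interval"] == k).any():
            raise ValueError(f"interval {k} has no observations")
    regimes = sorted(df["regime"].unique(), key=lambda r: (r != REGIME_REF, r))
    if len(regimes) != 2:
        raise ValueError("need exactly two regimes")
    d_regime = (df["regime"] == regimes[1]).astype(float).to_numpy()
    x = df["age"].to_numpy(dtype=float)

    cols = {"alpha": np.ones(len(df)), "gamma": d_regime, "omega": x}
    for k in range(2, K + 1):
        ik = (df["interval"] == k).astype(float).to_numpy()
        cols[f"beta_{k}"] = ik
        cols[f"pi_{k}"] = ik * x
        cols[f"mu_{k}"] = ik * d_regime
    X = pd.DataFrame(cols, index=df.index)
    model = MixedLM(df["value"].to_numpy(dtype=float), X, groups=df["population"])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(reml=True)
    params = pd.Series(res.fe_params, index=X.columns)
    cov = pd.DataFrame(res.cov_params().iloc[: len(X.columns), : len(X.columns)].to_numpy(),
                       index=X.columns, columns=X.columns)
    n_pops = df["population"].nunique()
    dof = n_pops - 2

    rows = []
    for k in range(1, K + 1):
        vec = pd.Series(0.0, index=X.columns)
        vec["gamma"] = 1.0
        if k > 1:
            vec[f"mu_{k}"] = 1.0
        est = float(vec @ params)
        se = float(np.sqrt(max(vec @ cov @ vec, 0.0)))  # singular fits can go slightly negative
        t = est / se if se > 0 else np.inf
        rows.append((k, est, se, t, 2 * stats.t.sf(abs(t), dof)))
    contrasts = pd.DataFrame(rows, columns=["interval", "estimate", "se", "t", "p"]).set_index("interval")
    return FecundityFit(
        params=params, cov=cov, interval_contrasts=contrasts,
        sigma_c_sq=float(res.cov_re.iloc[0, 0]), sigma_e_sq=float(res.scale),
        n_pops=int(n_pops), df=dof, converged=bool(res.converged),
    )


# ---------------------------------------------------------------------------
# daily-mortality logistic regression (pathogen-exposure assay)


@dataclass
class LogisticFit:
    """Eight-coefficient logistic model for daily mortality in a 2x2
    regime x treatment design: intercept and slope-in-day terms, each with a
    regime, treatment and interaction offset."""

    params: pd.Series
    se: pd.Series
    pvalues: pd.Series
    deviance: float
    converged: bool
    separation: bool


def fit_daily_logistic(counts: pd.DataFrame, regime_level_one: str = "TDO",
                       treatment_level_one: str = "fungus") -> LogisticFit:
    """ML fit of logit p(t) = mu0 + d_i*alpha0 + d_j*beta0 + d_i*d_j*gamma0
    + (mu1 + d_i*alpha1 + d_j*beta1 + d_i*d_j*gamma1) * t on day-indexed
    binomial counts.  Here the indicator is 1 for level one (d_i = 1 for the
    first regime, d_j = 1 for the exposed treatment).  Complete separation is
    reported via the ``separation`` flag.
    """
    import statsmodels.api as sm

    req = {"day", "regime", "treatment", "deaths", "at_risk"}
    missing = req - set(counts.columns)
    if missing:
        raise ValueError(f"counts missing columns: {sorted(missing)}")
    d_i = (counts["regime"] == regime_level_one).astype(float).to_numpy()
    d_j = (counts["treatment"] == treatment_level_one).astype(float).to_numpy()
    t = counts["day"].to_numpy(dtype=float)
    X = pd.DataFrame({
        "mu0": 1.0, "alpha0": d_i, "beta0": d_j, "gamma0": d_i * d_j,
        "mu1": t, "alpha1": d_i * t, "beta1": d_j * t, "gamma1": d_i * d_j * t,
    }, index=counts.index)
    y = np.column_stack([counts["deaths"], counts["at_risk"] - counts["deaths"]])
    model = sm.GLM(y, X, family=sm.families.Binomial())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit()
    separation = bool((np.abs(res.params) > 15).any() or (res.bse > 1e3).any())
    if separation:
        warnings.warn("possible complete separation in logistic fit", stacklevel=2)
    return LogisticFit(
        params=pd.Series(res.params, index=X.columns),
        se=pd.Series(res.bse, index=X.columns),
        pvalues=pd.Series(res.pvalues, index=X.columns),
        deviance=float(res.deviance), converged=bool(res.converged),
        separation=separation,
    )


# ---------------------------------------------------------------------------
# power by simulation


def power_by_simulation(sigma1_sq: float, sigma2_sq: float, delta: float,
                        n_pops_per_regime: int = 5, n_per_pop: int = 30,
                        alpha: float = 0.05, n_sims: int = 2000, seed=None) -> float:
    """Monte-Carlo power of the among-population regime test.

    Population means are drawn from the fitted two-level model (between-
    population variance ``sigma1_sq`` plus residual variance ``sigma2_sq``
    divided by the per-population sample size) with a true regime shift
    ``delta``, and the two-sample t-test on population means (the test
    :func:`fit_lme` performs) is applied; power is the rejection frequency.
    """
    if sigma1_sq < 0 or sigma2_sq < 0:
        raise ValueError("variance components must be non-negative")
    rng = np.random.default_rng(seed)
    k = n_pops_per_regime
    sd = np.sqrt(sigma1_sq + sigma2_sq / n_per_pop)
    x = rng.normal(0.0, sd, size=(n_sims, k))
    y = rng.normal(delta, sd, size=(n_sims, k))
    sp2 = (x.var(axis=1, ddof=1) + y.var(axis=1, ddof=1)) / 2
    t = (y.mean(axis=1) - x.mean(axis=1)) / np.sqrt(sp2 * 2 / k)
    crit = stats.t.ppf(1 - alpha / 2, 2 * k - 2)
    return float((np.abs(t) > crit).mean())


def detectable_difference(sigma1_sq: float, sigma2_sq: float,
                          target_power: float = 0.8,
                          n_pops_per_regime: int = 5, n_per_pop: int = 30,
                          alpha: float = 0.05, n_sims: int = 4000, seed=0,
                          tol: float = 1e-3) -> float:
    """Smallest regime difference detectable at ``target_power``, found by
    bisection on the simulated power curve (common random numbers make the
    curve monotone in delta for a fixed seed)."""
    if not (alpha < target_power < 1):
        raise ValueError("target_power must lie in (alpha, 1)")
    sd = np.sqrt(sigma1_sq + sigma2_sq / n_per_pop)
    lo, hi = 0.0, 10.0 * sd + 1e-9
    while power_by_simulation(sigma1_sq, sigma2_sq, hi, n_pops_per_regime,
                              n_per_pop, alpha, n_sims, seed) < target_power:
        hi *= 2
        if hi > 1e6 * (sd + 1):
            raise RuntimeError("power never reaches target")
    while hi - lo > tol * max(1.0, hi):
        mid = 0.5 * (lo + hi)
        pw = power_by_simulation(sigma1_sq, sigma2_sq, mid, n_pops_per_regime,
                                 n_per_pop, alpha, n_sims, seed)
        if pw < target_power:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
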