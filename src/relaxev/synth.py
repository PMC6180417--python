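"""Synthetic data generators for every stage of the pipeline.

Each generator draws from exactly the generative structure the downstream
model assumes — two-level Gaussian phenotypes with population random effects,
plateau-Gompertz daily mortality, piecewise-linear interval fecundity,
binomial assay outcomes, and binomial pool-seq allele counts for two groups of
five replicate populations with a controllable differentiated fraction — so
that every fitting routine has a parameter-recovery test surface.  All
generators are bit-reproducible given a seed.

Regime labels follow the experiment's convention: two regimes TDO (the
reference level in every delta-coded model) and TSO, five replicate
populations each, populations 1-5 TDO and 6-10 TSO.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mortality import GompertzParams, survivorship
from .poolseq import SyncTable

logger = logging.getLogger(__name__)

REGIMES = ("TDO", "TSO")
SEXES = ("F", "M")

#: five fecundity age windows (days from egg); the second spans days 18-20
DEFAULT_FECUNDITY_INTERVALS = ((15, 17), (18, 20), (21, 23), (24, 26), (27, 28))

#: major chromosome arm lengths (bp) used to place synthetic SNPs
CHROM_LENGTHS = {"X": 23_500_000, "2L": 23_000_000, "2R": 25_300_000,
                 "3L": 28_100_000, "3R": 32_100_000}


@dataclass(frozen=True)
class LMEGenParams:
    """Truth for the two-level phenotype model
    y = alpha + d_regime*beta + d_sex*gamma + d_regime*d_sex*pi + b_pop + eps."""

    grand_mean: float
    regime_effect: float = 0.0
    sex_effect: float = 0.0
    interaction: float = 0.0
    pop_sd: float = 0.0
    resid_sd: float = 0.0

    def __post_init__(self):
        if self.pop_sd < 0 or self.resid_sd < 0:
            raise ValueError("standard deviations must be non-negative")


def _population_ids(n_pops_per_regime: int):
    return {
        "TDO": list(range(1, n_pops_per_regime + 1)),
        "TSO": list(range(n_pops_per_regime + 1, 2 * n_pops_per_regime + 1)),
    }


def gen_lme_records(params: LMEGenParams, n_pops_per_regime: int = 5,
                    n_per_pop: int = 30, two_factor: bool = False,
                    seed=None) -> pd.DataFrame:
    """Individual phenotype records under the two-level mixed model.

    The TDO regime and female sex are the reference levels: a TDO female has
    mean ``grand_mean``; TSO adds ``regime_effect``, males add ``sex_effect``
    and TSO males additionally ``interaction``.  The population effect
    b ~ N(0, pop_sd^2) is shared by every record of a population; residuals
    are iid N(0, resid_sd^2).  In the two-factor design ``n_per_pop`` is the
    count per population per sex.
    """
    if n_pops_per_regime < 1 or n_per_pop < 1:
        raise ValueError("need >=1 population per regime and >=1 record per population")
    rng = np.random.default_rng(seed)
    pops = _population_ids(n_pops_per_regime)
    rows = []
    for regime in REGIMES:
        d_i = 0.0 if regime == "TDO" else 1.0
        for pop in pops[regime]:
            b = rng.normal(0.0, params.pop_sd)
            for sex in (SEXES if two_factor else (None,)):
                d_j = 0.0 if sex in (None, "F") else 1.0
                mean = (params.grand_mean + d_i * params.regime_effect
                        + d_j * params.sex_effect + d_i * d_j * params.interaction + b)
                vals = mean + rng.normal(0.0, params.resid_sd, n_per_pop)
                for m, v in enumerate(vals, start=1):
                    row = {"regime": regime, "population": pop,
                           "individual": m, "value": v}
                    if two_factor:
                        row["sex"] = sex
                    rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# mortality cohorts


def gen_mortality_cohort(params, n_pops_per_regime: int = 5,
                         cohort_size: int = 3000, max_age: int = 80,
                         pop_sd=(0.0, 0.0, 0.0), seed=None):
    """Daily death counts per population under the plateau-Gompertz model.

    ``params`` maps a regime (or ``(regime, sex)`` pair) to the group-level
    :class:`~relaxev.mortality.GompertzParams`; ``pop_sd`` gives the SDs of
    additive population effects on (A, alpha, bd).  Death days are drawn by
    inverse sampling of the discrete survivorship (a multinomial over days
    plus a censored-at-``max_age`` bin), so deaths + survivors = cohort size.

    Returns ``(cohort, truth)``: the cohort table (population, regime, [sex],
    day, deaths, at_risk) and the per-series realized parameters.
    """
    rng = np.random.default_rng(seed)
    keys = list(params)
    with_sex = isinstance(keys[0], tuple)
    pops = _population_ids(n_pops_per_regime)
    pop_sd = np.asarray(pop_sd, dtype=float)
    if (pop_sd < 0).any():
        raise ValueError("pop_sd must be non-negative")
    rows, truth = [], []
    days = np.arange(max_age + 1)
    for regime in REGIMES:
        for pop in pops[regime]:
            b = rng.normal(0.0, pop_sd)
            for key in keys:
                if with_sex:
                    if key[0] != regime:
                        continue
                    sex = key[1]
                else:
                    if key != regime:
                        continue
                    sex = None
                base = params[key]
                gp = GompertzParams(max(base.A + b[0], 1e-8), base.alpha + b[1],
                                    max(base.bd + b[2], 0.0))
                p = np.asarray(survivorship(gp, days))
                probs = np.append(p[:-1] - p[1:], p[-1])  # death on day t, or survive
                counts = rng.multinomial(cohort_size, probs)
                deaths = counts[:-1]
                alive = cohort_size - np.concatenate([[0], np.cumsum(deaths)[:-1]])
                for t in range(max_age):
                    row = {"population": pop, "regime": regime, "day": t,
                           "deaths": int(deaths[t]), "at_risk": int(alive[t])}
                    if with_sex:
                        row["sex"] = sex
                    rows.append(row)
                trow = {"population": pop, "regime": regime,
                        "A": gp.A, "alpha": gp.alpha, "bd": gp.bd}
                if with_sex:
                    trow["sex"] = sex
                truth.append(trow)
    return pd.DataFrame(rows), pd.DataFrame(truth)


def cohort_to_death_records(cohort: pd.DataFrame) -> pd.DataFrame:
    """Expand daily death counts into one record per dead individual
    (column ``death_day``); survivors at the end of follow-up are omitted."""
    cols = [c for c in ("population", "regime", "sex") if c in cohort.columns]
    reps = cohort["deaths"].to_numpy()
    out = cohort.loc[cohort.index.repeat(reps), cols + ["day"]].reset_index(drop=True)
    return out.rename(columns={"day": "death_day"})


# ---------------------------------------------------------------------------
# fecundity


def gen_fecundity_records(interval_intercepts, interval_slopes,
                          regime_offsets=None, pop_sd: float = 0.0,
                          resid_sd: float = 0.0,
                          intervals=DEFAULT_FECUNDITY_INTERVALS,
                          n_pops_per_regime: int = 5, n_pairs: int = 20,
                          seed=None) -> pd.DataFrame:
    """Eggs-per-female-per-day records, linear in age within each interval.

    Within interval k the expected trajectory is ``intercept_k + slope_k * x``
    (x = age in days from egg); the TSO regime shifts the intercept of
    interval k by ``regime_offsets[k]`` (slope is never regime-dependent).
    Populations contribute a shared random intercept.
    """
    intervals = tuple(tuple(iv) for iv in intervals)
    for (lo, hi), (lo2, _) in zip(intervals, intervals[1:]):
        if hi >= lo2:
            raise ValueError("intervals must be ordered and non-overlapping")
    K = len(intervals)
    if len(interval_intercepts) != K or len(interval_slopes) != K:
        raise ValueError("need one intercept and slope per interval")
    if regime_offsets is None:
        regime_offsets = np.zeros(K)
    if len(regime_offsets) != K:
        raise ValueError("need one regime offset per interval")
    if pop_sd < 0 or resid_sd < 0:
        raise ValueError("standard deviations must be non-negative")
    rng = np.random.default_rng(seed)
    pops = _population_ids(n_pops_per_regime)
    rows = []
    for regime in REGIMES:
        d_j = 0.0 if regime == "TDO" else 1.0
        for pop in pops[regime]:
            c = rng.normal(0.0, pop_sd)
            for pair in range(1, n_pairs + 1):
                for k, (lo, hi) in enumerate(intervals):
                    for x in range(lo, hi + 1):
                        mean = (interval_intercepts[k] + interval_slopes[k] * x
                                + d_j * regime_offsets[k] + c)
                        rows.append({"regime": regime, "population": pop,
                                     "individual": pair, "age": x,
                                     "value": mean + rng.normal(0.0, resid_sd)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# binary outcomes (pathogen exposure, cardiac pacing)


def gen_binary_outcomes(group_rates: dict, n_per_cell: int,
                        n_pops_per_regime: int = 5, seed=None) -> pd.DataFrame:
    """Bernoulli outcome records per regime (x treatment) x population.

    ``group_rates`` maps a regime name, or a ``(regime, treatment)`` pair, to
    a success probability; each population contributes ``n_per_cell``
    independent Bernoulli draws per cell.
    """
    rng = np.random.default_rng(seed)
    keys = list(group_rates)
    with_treatment = isinstance(keys[0], tuple)
    pops = _population_ids(n_pops_per_regime)
    rows = []
    for key in keys:
        regime, treatment = key if with_treatment else (key, None)
        rate = group_rates[key]
        if not 0.0 <= rate <= 1.0:
            raise ValueError(f"rate {rate} outside [0, 1]")
        for replicate, pop in enumerate(pops[regime], start=1):
            outcomes = (rng.random(n_per_cell) < rate).astype(int)
            for m, o in enumerate(outcomes, start=1):
                row = {"regime": regime, "population": pop, "replicate": replicate,
                       "individual": m, "outcome": o}
                if with_treatment:
                    row["treatment"] = treatment
                rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# pool-seq sync datasets


@dataclass
class SyncGenConfig:
    """Generative settings for a two-group replicated pool-seq dataset."""

    n_snps: int = 10_000
    chrom_lengths: dict = field(default_factory=lambda: dict(CHROM_LENGTHS))
    freq_low: float = 0.05
    freq_high: float = 0.5
    differentiated_fraction: float = 0.0
    effect: float = 0.0          # frequency shift at differentiated sites
    coverage_mean: float = 70.0
    coverage_min: int = 30
    coverage_max: int = 200
    n_pops_per_group: int = 5

    def __post_init__(self):
        if not (0.0 < self.freq_low <= self.freq_high < 1.0):
            raise ValueError("frequencies must satisfy 0 < low <= high < 1")
        if not 0.0 <= self.differentiated_fraction <= 1.0:
            raise ValueError("differentiated_fraction outside [0, 1]")
        if self.coverage_min < 1:
            raise ValueError("coverage must be >= 1")


def _draw_positions(rng, n_snps, chrom_lengths):
    names = list(chrom_lengths)
    lengths = np.array([chrom_lengths[c] for c in names], dtype=float)
    counts = rng.multinomial(n_snps, lengths / lengths.sum())
    chrom, pos = [], []
    for name, ln, k in zip(names, lengths, counts):
        p = np.sort(rng.choice(int(ln), size=k, replace=False)) + 1
        chrom.extend([name] * k)
        pos.extend(p.tolist())
    return np.array(chrom, dtype=object), np.array(pos, dtype=np.int64)


def gen_sync_dataset(cfg: SyncGenConfig, seed=None):
    """Two groups of replicate pools with binomial read sampling.

    At non-differentiated sites both groups share one minor-allele frequency
    and every population's minor count is Binomial(coverage, f): the exact
    null of the per-site scans.  Differentiated sites shift the second
    group's frequency by ``cfg.effect`` (clipped into [0.01, 0.99], keeping
    the site polymorphic; clips are logged).  Returns ``(sync, truth)`` where
    truth records each site's group frequencies and differentiation flag.
    The minor allele is written as T against an A reference/major.
    """
    rng = np.random.default_rng(seed)
    chrom, pos = _draw_positions(rng, cfg.n_snps, cfg.chrom_lengths)
    f_a = rng.uniform(cfg.freq_low, cfg.freq_high, cfg.n_snps)
    n_diff = int(round(cfg.differentiated_fraction * cfg.n_snps))
    diff_mask = np.zeros(cfg.n_snps, dtype=bool)
    diff_mask[rng.choice(cfg.n_snps, n_diff, replace=False)] = True
    f_b = f_a.copy()
    shift = np.where(f_a + cfg.effect <= 0.99, cfg.effect, -cfg.effect)
    f_b[diff_mask] = f_a[diff_mask] + shift[diff_mask]
    clipped = (f_b < 0.01) | (f_b > 0.99)
    if clipped.any():
        logger.info("clipped %d shifted frequencies into [0.01, 0.99]", int(clipped.sum()))
    f_b = np.clip(f_b, 0.01, 0.99)

    n_pops = 2 * cfg.n_pops_per_group
    cov = rng.poisson(cfg.coverage_mean, size=(cfg.n_snps, n_pops))
    cov = np.clip(cov, cfg.coverage_min, cfg.coverage_max)
    freqs = np.concatenate([np.repeat(f_a[:, None], cfg.n_pops_per_group, axis=1),
                            np.repeat(f_b[:, None], cfg.n_pops_per_group, axis=1)], axis=1)
    minor = rng.binomial(cov, freqs)
    counts = np.zeros((cfg.n_snps, n_pops, 6), dtype=np.int64)
    counts[:, :, 0] = cov - minor  # A = major/reference
    counts[:, :, 1] = minor        # T = minor
    sync = SyncTable(chrom=chrom, pos=pos, ref=np.array(["A"] * cfg.n_snps, dtype=object),
                     counts=counts)
    truth = pd.DataFrame({"chrom": chrom, "pos": pos, "is_diff": diff_mask,
                          "freq_a": f_a, "freq_b": f_b})
    return sync, truth


def gen_founder_freqs(n_snps: int, differentiated_fraction: float = 0.1,
                      freq_low: float = 0.1, freq_high: float = 0.9,
                      diff_low: float = 0.05, diff_high: float = 0.95,
                      spacing: int = 1000, seed=None):
    """Founding allele-frequency vectors for a two-group forward simulation.

    Shared sites get one frequency ~ U(freq_low, freq_high) in both groups;
    differentiated sites are founded near-fixed for opposite alleles
    (``diff_low`` in one group, ``diff_high`` in the other, with the group
    receiving the high allele randomized per site).  Returns
    ``(freq_a, freq_b, diff_mask, chrom, pos)`` with sites evenly spaced on a
    single synthetic chromosome.
    """
    rng = np.random.default_rng(seed)
    f_a = rng.uniform(freq_low, freq_high, n_snps)
    f_b = f_a.copy()
    n_diff = int(round(differentiated_fraction * n_snps))
    idx = rng.choice(n_snps, n_diff, replace=False)
    hi_in_a = rng.random(n_diff) < 0.5
    f_a[idx] = np.where(hi_in_a, diff_high, diff_low)
    f_b[idx] = np.where(hi_in_a, diff_low, diff_high)
    mask = np.zeros(n_snps, dtype=bool)
    mask[idx] = True
    chrom = np.array(["sim"] * n_snps, dtype=object)
    pos = np.arange(1, n_snps + 1, dtype=np.int64) * spacing
    return f_a, f_b, mask, chrom, pos


def write_table(df: pd.DataFrame, path) -> None:
    """Write a phenotype table as CSV, or XLSX when the suffix is .xlsx."""
    path = str(path)
    if path.endswith(".xlsx"):
        df.to_excel(path, index=False)
    else:
        df.to_csv(path, index=False)
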