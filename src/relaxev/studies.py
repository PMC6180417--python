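"""Reference study conditions for the replicated TDO/TSO comparison.

The printed group summaries of the source experiment (starvation and
desiccation survival hours, cardiac-arrest rates, the mean-longevity and
eclosion-time contrasts) serve as generator truths: synthetic phenotype
tables are drawn at exactly these values and the study's sample sizes, and
the pipeline's summaries are recomputed from them.  The module also fixes the
simulation designs used for the parameter-recovery and migration-erosion
studies so that tests and reproduction scripts run identical conditions.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import synth, wfsim
from .mortality import GompertzParams

# group means in hours (5 populations x 30 females each, one-factor design)
STARVATION_HOURS = {"TSO": 73.54, "TDO": 69.05}
STARVATION_SD = {"pop": 2.0, "resid": 12.0}   # checked every 4 h
DESICCATION_HOURS = {"TSO": 13.26, "TDO": 15.04}
DESICCATION_SD = {"pop": 0.8, "resid": 3.5}   # checked hourly
N_PER_STRAW_ASSAY = 30

# cardiac pacing: arrest probability, 90 females per population
CARDIAC_ARREST_RATE = {"TSO": 0.276, "TDO": 0.2578}
N_CARDIAC_PER_POP = 90

# mean longevity: TDO lives ~7 days longer (both sexes); eclosion ~1 h apart
LONGEVITY_DAYS = {"TSO": 35.0, "TDO": 42.0}
LONGEVITY_SD = {"pop": 1.5, "resid": 12.0}
ECLOSION_HOURS = {"TSO": 250.0, "TDO": 251.0}
ECLOSION_SD = {"pop": 1.5, "resid": 8.0}


def _one_factor_params(means: dict, sd: dict) -> synth.LMEGenParams:
    return synth.LMEGenParams(
        grand_mean=means["TDO"], regime_effect=means["TSO"] - means["TDO"],
        pop_sd=sd["pop"], resid_sd=sd["resid"])


def starvation_table(seed=None, n_per_pop: int = N_PER_STRAW_ASSAY) -> pd.DataFrame:
    return synth.gen_lme_records(_one_factor_params(STARVATION_HOURS, STARVATION_SD),
                                 5, n_per_pop, seed=seed)


def desiccation_table(seed=None, n_per_pop: int = N_PER_STRAW_ASSAY) -> pd.DataFrame:
    return synth.gen_lme_records(_one_factor_params(DESICCATION_HOURS, DESICCATION_SD),
                                 5, n_per_pop, seed=seed)


def cardiac_table(seed=None, n_per_pop: int = N_CARDIAC_PER_POP) -> pd.DataFrame:
    return synth.gen_binary_outcomes(dict(CARDIAC_ARREST_RATE), n_per_pop, 5, seed=seed)


def longevity_table(seed=None, n_per_pop: int = 300) -> pd.DataFrame:
    rec = synth.gen_lme_records(_one_factor_params(LONGEVITY_DAYS, LONGEVITY_SD),
                                5, n_per_pop, seed=seed)
    return rec.rename(columns={"value": "death_day"})


def eclosion_table(seed=None, n_per_pop: int = 200) -> pd.DataFrame:
    return synth.gen_lme_records(_one_factor_params(ECLOSION_HOURS, ECLOSION_SD),
                                 5, n_per_pop, seed=seed)


def regime_mean_se(sd: dict, n_per_pop: int, n_pops: int = 5) -> float:
    """Sampling SE of a regime mean of population means under the two-level model."""
    return float(np.sqrt((sd["pop"] ** 2 + sd["resid"] ** 2 / n_per_pop) / n_pops))


# ---------------------------------------------------------------------------
# Gompertz parameter-recovery study: 10 populations, regime effect on the
# baseline hazard A only, plateau at day 40.

GOMPERTZ_TRUTH = {
    "A:baseline": 0.002, "A:regime": 0.002,
    "alpha:baseline": 0.25, "alpha:regime": 0.0,
    "bd:baseline": 40.0, "bd:regime": 0.0,
}
GOMPERTZ_POP_SD = (0.0003, 0.01, 0.0)
GOMPERTZ_COHORT = 3000
GOMPERTZ_MAX_AGE = 80


def gompertz_cohort(seed=None):
    gp = {"TDO": GompertzParams(GOMPERTZ_TRUTH["A:baseline"],
                                GOMPERTZ_TRUTH["alpha:baseline"],
                                GOMPERTZ_TRUTH["bd:baseline"]),
          "TSO": GompertzParams(GOMPERTZ_TRUTH["A:baseline"] + GOMPERTZ_TRUTH["A:regime"],
                                GOMPERTZ_TRUTH["alpha:baseline"],
                                GOMPERTZ_TRUTH["bd:baseline"])}
    cohort, _ = synth.gen_mortality_cohort(gp, 5, cohort_size=GOMPERTZ_COHORT,
                                           max_age=GOMPERTZ_MAX_AGE,
                                           pop_sd=GOMPERTZ_POP_SD, seed=seed)
    return cohort


# ---------------------------------------------------------------------------
# Migration-erosion study: two groups of five replicates founded with a 10%
# near-fixed differentiated fraction, evolved 100 generations at N = 200
# under 0/2/10 single-migrant events per generation, pool-sequenced at 50x.
# The 5-Mb synthetic chromosome is a genome proxy: its uniform female map
# totals ~5 Morgans (0.1 per 100-kb window), halved in the simulator to
# average over the absence of male recombination.

EROSION = {
    "n_snps": 5000, "differentiated_fraction": 0.1,
    "diff_low": 0.05, "diff_high": 0.95,
    "N": 200, "generations": 100, "depth": 50,
    "events": (0, 2, 10), "map_rate_per_window": 0.1,
}


def erosion_founders(seed=None):
    return synth.gen_founder_freqs(
        EROSION["n_snps"], EROSION["differentiated_fraction"],
        diff_low=EROSION["diff_low"], diff_high=EROSION["diff_high"], seed=seed)


def erosion_map() -> wfsim.RecombMap:
    length = EROSION["n_snps"] * 1000
    return wfsim.RecombMap.uniform({"sim": length}, EROSION["map_rate_per_window"])
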