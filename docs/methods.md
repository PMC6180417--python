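# Methods

`relaxev` re-implements, as a tested library, the statistical and simulation
machinery used to ask whether replicated *Drosophila* populations converge —
phenotypically and genomically — after a selective pressure is relaxed. Two
regimes of five replicate populations each (the previously intensely selected
group, TDO, and its control, TSO) are compared at the level of life-history
traits and of pooled-sequencing allele frequencies, and a forward simulator
quantifies how much differentiation accidental migration could have erased.
This note records the models, the defaults, and the judgement calls.

Throughout, δ-coding follows the experiment's convention: regime level 1
(TDO) and sex level 1 (female) are the reference, so a model's intercept α is
the TDO-female mean, β the TSO offset, γ the male offset and π the TSO-male
interaction. The one exception is the daily-mortality logistic model for the
pathogen-exposure assay, whose printed form sets the indicator to 1 for level
one; `fit_daily_logistic` follows that form.

## Mortality: two-stage Gompertz with a late-life plateau

The hazard is Gompertz, `h(t) = A exp(αt)`, up to a break day `bd`, and
constant at `A exp(α·bd)` afterwards. Survivorship is

    p_t = exp{A[1 − exp(αt)]/α}                                   t ≤ bd
    p_t = exp{A[1 − exp(α·bd)]/α + A exp(α·bd)(bd − t)}           t > bd

and daily mortality is `q_t = 1 − p_{t+1}/p_t`. `A` (per day) is the
age-independent baseline, `α` (per day) the rate of aging, `bd` (days) the
plateau onset. The α → 0 limit is taken by series expansion below |α| <
1e−8, recovering the exponential; `bd → ∞` recovers the classic Gompertz.
Where `p_t` underflows to zero, `q_t` is defined as 1 with a warning.

Across populations each parameter carries regime and sex fixed effects plus
an additive per-population random effect, e.g. `A_ijk = π₁ + δᵢβ₁ + δⱼγ₁ +
b_1k`, with residual variance growing with age as `σ²|t|^{2Δ}`.

**Fitting.** The mixed model is estimated by a global two-stage (GTS) scheme
rather than a single joint Laplace/REML optimization: breakpoint likelihoods
are multimodal, and a 3-parameter nonlinear model with a random effect on the
breakpoint is fragile under joint optimization, while the two-stage route is
robust and statistically transparent.

1. *Per-series weighted NLS.* Each population(-by-sex) series of observed
   `q̂_t` (ages with at-risk > 0) is fit by least squares with weights
   `at_risk_t · |t|^{−2Δ}` — binomial information times the power-variance
   model. `A` and `bd` are log-parameterized for positivity. The break day
   is profiled over a grid (ties broken toward the smaller `bd`) and then
   refined continuously. Δ is estimated by regressing the log squared
   weighted residuals on log age, pooled over series, with one refit; a
   constant-variance variant (`variance="constant"`) is available for model
   comparison.
2. *Sampling covariance with honest flat directions.* The per-series
   covariance comes from the Jacobian with an eigenvalue-floored inverse, and
   the `bd` variance is additionally bounded below by the half-width of the
   1-σ profile set {bd : RSS ≤ RSS_min + σ²}. When the data end before the
   plateau (no deaths beyond some age), the profile in `bd` is flat and the
   fit reports a very large `bd` variance instead of a spuriously tight one.
   A `bd` beyond the last observed death is *set-identified only* — no point
   estimator can recover it, and downstream SEs say so.
3. *Marginal REML.* The stage-one estimates are modeled as
   `θ̂_k ~ N(Xβ, Σ_b + V_k)` with a diagonal 3×3 `Σ_b` shared across the two
   sex series of a population; β is profiled by GLS and the restricted
   likelihood maximized over `log τ²` (Nelder–Mead, 3 parameters). A full
   covariance `Σ_b` would be overparameterized with 10 populations.
   Random effects can be restricted to parameter subsets, and
   `compare_gompertz_models` reports AIC/BIC across subsets × variance
   models, mirroring the information-criterion selection the original
   analysis describes (the criteria are computed from the stage-two
   restricted likelihood, so comparisons are like-for-like).

Fixed-effect p-values are t-tests with `n_pops − 2` denominator df —
populations, not flies, are the replicated unit. Parameter recovery: on
identifiable configurations (e.g. A = 0.002, α = 0.12, bd = 30, cohorts of
3000) the fit recovers all fixed effects, detects a regime effect on `A` and
correctly finds none on `α`; on noise-free deterministic curves the
parameters are recovered to < 1e−4 relative error.

## Phenotype inference

**Two-level LMEs** (`fit_lme`). For balanced replicated designs the REML
solution has a closed form, which is what the implementation computes: the
regime contrast is the two-sample comparison of population means (t,
`n_pops − 2` df); in the two-factor design, sex and the regime×sex
interaction are tested on within-population sex differences (the split-plot
within stratum). Variance components are method-of-moments (floored at 0).
This hand-rolled estimator is used instead of a generic mixed-model routine
because the population-level denominator df is what keeps the type-I error
calibrated — verified at 4.3% empirical rejection at nominal 5% over 1000
null simulations — while generic Wald z tests are anticonservative with 10
groups; statsmodels MixedLM serves as the cross-check oracle in the tests.

**Interval fecundity** (`fit_fecundity`). Eggs/female/day are piecewise
linear in age within five intervals (default 15–17, 18–20, 21–23, 24–26,
27–28 days from egg — the second interval is the one the source experiment
names; the remaining boundaries are a configurable reading of a 3-day grid).
Regime shifts intercepts only (`γ` plus per-interval `μ_k`), never slopes.
The fit is statsmodels MixedLM REML with a population random intercept;
per-interval regime contrasts (`γ + μ_k`) are Wald t-tests on `n_pops − 2`
df.

**Daily-mortality logistic** (`fit_daily_logistic`). An eight-coefficient
binomial GLM in day, regime, treatment and their products, ML-fit via
statsmodels; complete separation is flagged, not silently returned.

**CMH test** (`cmh_test`). The continuity-corrected statistic

    X² = (|Σᵢ[aᵢ − (aᵢ+bᵢ)(aᵢ+cᵢ)/nᵢ]| − 0.5)² / Σᵢ(aᵢ+bᵢ)(aᵢ+cᵢ)(bᵢ+dᵢ)(cᵢ+dᵢ)/(nᵢ³−nᵢ²)

referred to χ²₁. The formula is implemented literally, including when the
absolute sum is below 0.5 (the numerator is then the pure continuity term —
the statistic is conservative there by construction). Degenerate strata with
n = 0 contribute zero to both sums. Without the correction the statistic
equals the textbook CMH exactly (n³−n² = n²(n−1)). For the cardiac assay,
heart status after the 2-minute recovery check is the default outcome (both
post-shock and post-recovery status are recorded in the source protocol
without a statement of which enters the test; the choice is configurable by
passing whichever column as the outcome).

**Power** (`power_by_simulation`, `detectable_difference`). The source
reports power and minimum-detectable-difference numbers without a method.
Here power is Monte-Carlo: population means are redrawn from the fitted
two-level variance structure under a shifted truth and the same
population-level t-test applied; the detectable difference is found by
bisection with common random numbers. Exact reproduction of the printed
power values (0.88/0.31/0.60/0.96) is not promised — they depend on variance
estimates from data not distributed with the paper.

## Pool-seq genome scans

Sync files follow the PoPoolation2 convention (tab-separated, 1-based
positions, `A:T:C:G:N:del` sextets). SNP calling keeps sites with every
population's A+C+G+T coverage in [30, 200] and pooled minor-allele frequency
≥ 2% (the per-population coverage reading of the ambiguous "coverage between
30× and 200×" rule; both bounds are arguments). Major/minor are decided on
counts summed across populations, ties alphabetical; sites with a third
segregating allele are collapsed to the top two and flagged. Coverage
rescaling to a uniform 50× preserves each frequency to within one half-read
(minor count = nearest integer, ties to even; sites outside [50, 200×]
dropped first).

Expected heterozygosity is `2p(1−p)` per site without a pool-size unbiased
correction (the quantity is used descriptively); windows are 0-based
half-open 150-kb bins. `F_ST = (H_T − H_S)/H_T` with `H_T` from the
unweighted mean replicate frequency and `H_S` the mean per-replicate
heterozygosity; `H_T = 0` sites are skipped.

**CMH scan.** Replicate *i* of one group is paired with replicate *i* of the
other (index pairing — the pairing is configurable since the original one is
not recorded), giving five (minor, major) × (group) strata per site; the scan
is numerically identical (≤ 1e−12) to the single-table CMH on the same
strata. **Permutation threshold:** the ten populations are re-assigned to
balanced 5-vs-5 groups (sampling with replacement from the 126 distinct
balanced partitions, original included), the minimum p recorded per shuffle,
and the 5% quantile of those minima is the genome-wide threshold. Its
family-wise error calibration on fresh null genomes is the headline property
(measured ~3–5% against the nominal 5%, within the [2%, 9%] band expected at
200 permutations).

**Quasibinomial GLM scan.** Per site, minor counts regressed on group with a
logit link; with a single binary covariate the fit is closed-form (group
pooled frequencies), the dispersion is Pearson χ²/(n_pops − 2) as in R's
`quasibinomial` (statsmodels' two-column `scale="X2"` normalizes differently
and is *not* the reference), and the contrast uses a dispersion-scaled t on
`n_pops − 2` df. Wherever a population has a zero count for either allele,
one is added to both of its allele counts before fitting. Under the null the
p-values are uniform to KS distance < 0.01 on called (naturally varying)
coverage. With counts rescaled to exactly equal coverage and balanced
groups, a ~5% atom appears at p = 1 from exact frequency ties; this is a
discreteness artifact, conservative by nature, so the uniformity diagnostic
is run on called counts while rescaling remains the recommended input for
real scans (it removes coverage-driven power variation).

**Corrections.** Bonferroni (`p < level/m`) and Storey q-values with π₀
estimated at λ = 0.5 (the single-λ estimator; the source cites the q-value
method without settings), cut at FDR 0.05. Significant sites merge into
regions by runs with inter-site gaps ≤ `max_gap`, emitted as 0-based
half-open (BED-style) intervals.

## Forward Wright–Fisher simulator

Populations are N = 1000 (default) hermaphroditic diploids, selfing
excluded, non-overlapping generations, no mutation and no selection — the
scenarios are strictly neutral drift plus migration from standing variation.
Founding uses the pot scheme: exactly `round(2N·p)` copies (ties up) of each
allele dealt uniformly over the 2N haplotype slots, loci independent
(linkage equilibrium; the fixed count, not a binomial draw, is the point of
the pot metaphor). Each generation N offspring draw two distinct parents
uniformly; each parent contributes one gamete; crossover counts per 100-kb
window are Poisson with half the female map rate (males do not recombine;
halving averages over the sexes rather than modeling them), breakpoints
uniform within the window, chromosomes assorting independently.

Measured against theory: one-generation `Var(Δp)` matches `p(1−p)/(2N)`
(the no-selfing constraint makes the empirical coefficient ≈ 0.98, inside
sampling error), and expected heterozygosity decays as `(1 − 1/(2N))^t` over
100 generations.

Migration replaces one uniformly chosen resident per event with a migrant
drawn at linkage equilibrium from the *opposite group's mean founding
frequencies* (sources are fixed gene pools, as in the original design);
N is held constant. Events split evenly between groups; the receiving
replicate cycles deterministically 1→5 by default (uniform-random available)
— the original rule ("one of the 5") is unstated. Pooled sequencing draws
`Binomial(depth, p)` reads per site per population and writes sync.

### The migration-erosion study and its scale

The reference scenario — 1.1M SNPs × 1000 diploids × 230 generations — is
far beyond desk scale, so the packaged study runs a scaled twin: 5000 SNPs
on a 5-Mb synthetic chromosome, N = 200, 100 generations, 0/2/10 events per
generation, pool-sequenced at 50×. Differentiated sites (10%) are founded
near-fixed for opposite alleles (0.05 vs 0.95), the realistic proxy for
differentiation at the height of intense selection, and the chromosome
carries a uniform female map of ~5 Morgans total (0.1 per 100-kb window) so
that its recombination stands in for a whole genome's.

What the scaling preserves and what it does not: the *ordering* is robust —
Bonferroni-significant counts from the GLM scan fall steeply and strictly as
migration rises (typical counts ~100 / ~35 / 0 for 0/2/10 events). The
*absolute* count at 10 events does not survive scaling: per-capita migration
pressure at N = 200 is five times the original's, leaving an aligned
frequency gap of ~0.16 against a between-replicate drift SD of ~0.13
(per-site noncentrality ≈ 2), and a >0 count at the full scale was itself an
extreme order statistic over 1.1M sites whose expectation scales to ~0.005
sites at m = 5000. The q-value counts, reported alongside, show the same
monotone erosion.

## Synthetic data: what it emulates and what it does not

The generators draw from exactly the generative structure the estimators
assume: Gaussian two-level phenotypes, multinomial death days from the
discrete plateau-Gompertz survivorship (survivors censored at `max_age`),
per-cell binomial assay outcomes, and binomial read counts at shared (null)
or shifted (differentiated) frequencies with Poisson-distributed coverage
clipped to [30, 200] (mean 70, as in the sequenced data). Shifted
frequencies are clipped into [0.01, 0.99] to keep sites polymorphic under
the 2% MAF rule, and clips are logged.

Real data depart from all of this in ways the tests therefore do not probe:
phenotypes are skewed and heteroscedastic, death days are recorded with
handling losses, read counts carry mapping and reference bias, repetitive
regions are masked upstream, replicate populations share drift history
(so real null sites are overdispersed relative to binomial sampling — the
quasibinomial dispersion absorbs this but the synthetic null does not
exercise it), and real linkage disequilibrium is block-structured rather
than free-recombining. Passing tests demonstrate correctness of the
machinery under its own assumptions, not robustness to these departures.

Reference study values (group means for starvation/desiccation hours,
cardiac-arrest rates, the ~7-day longevity and ~1-h eclosion contrasts) are
used as generator truths in `relaxev.studies`, with assay noise SDs chosen
at realistic magnitudes (e.g. 12 h residual SD for starvation checked every
4 h, 3.5 h for desiccation checked hourly) since the underlying individual
tables are not redistributed; the reproduction script regenerates these
tables and recomputes every summary through the pipeline.

## Numerical choices and degenerate inputs

- Survivorship/mortality identities hold to 1e−12 relative to `p_t`; the
  `q_t` round trip cannot be more precise than that near `q = 1`.
- `least_squares` (LM) with analytic-free Jacobians; break-day grid from 20%
  to 200% of the last observed age, 25 points, ties to the smaller day.
- GLM dispersion floored at 1e−12: a perfect within-group fit would
  otherwise zero the SE of a genuine contrast.
- Sites with all-zero strata, zero margins, or `H_T = 0` contribute nothing
  rather than NaN; parse errors report 1-based line numbers.
- All stochastic APIs accept either a seed or a `numpy` Generator;
  `run_scenario` spawns independent child streams per replicate so results
  are invariant to replicate count changes elsewhere.

## Problem sizes in packaged studies

The packaged studies run at sizes chosen for routine re-execution: 50
cohorts of 10 × 3000 flies for mortality recovery; 2000-site genomes with
200 permutations and 200 fresh null genomes for FWER calibration; 10⁴ sites
for null uniformity; 200 replicates for the drift laws; and the 5000-SNP
erosion scenario above. All complete in a few minutes on one core.

## Known limitations

- The GTS mortality fit approximates the joint NLME; its AIC/BIC are
  stage-two quantities, valid for comparing variants fit to the same series
  but not exchangeable with a joint-likelihood criterion.
- No frailty/heterogeneity mortality models, no Cox-type survival
  regression, no Bayesian fitting.
- No read-level simulation (counts are generated at the sync level), no
  haplotype-block structure in founders, no sex chromosomes or dioecy in the
  simulator, and no selection coefficients.
- Storey's π₀ uses a single λ; the smoother variant is not implemented.
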