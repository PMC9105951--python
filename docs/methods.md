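# Methods

## Model structure and assumptions

The package implements a cohort comparative risk assessment. The unit of
analysis is the 2017 Indonesian birth cohort during its 6–23-month window,
stratified into ten socioeconomic deciles. Each decile's altitude-adjusted
hemoglobin is modelled as normal with the decile mean from the baseline
table and a common standard deviation of 1.4 g/dL — only the pooled
dispersion is observed, so per-decile dispersions default to it
(overridable per decile in the population CSV).

Anemia severity uses the WHO convention for children 6–59 months on
altitude-adjusted Hb: severe < 7.0, moderate < 10.0, mild < 11.0 g/dL. The
altitude adjustment is the WHO band table (no decrement below 1000 m, then
0.2/0.5/0.8/1.3/1.9/2.7/3.5/4.5 g/dL at 1000/1500/…/4500 m). Neither the
cutoffs nor the adjustment formula are fixed by the model; both are
configuration.

Iron attribution is a single multiplicative share `ida_share` applied
uniformly across severities (default 0.46, the midpoint of the 25–67%
envelope reported for under-twos; values outside the envelope require an
explicit override flag).

### Dose-response of fortified cereals

The Hb gain from consuming fortified infant cereals ramps with total
consumption duration and saturates at `max_effect_gdl` (default 0.87 g/dL,
the meta-analytic effect of micronutrient-fortified milk/cereal products)
once `lag_months` (default 6) of consumption are reached. The ramp shape is
not identified by the available evidence; the default is linear, with a
step alternative for sensitivity analysis. Two servings per day are
modelled as doubling the accumulation rate — the ceiling is reached after
half the lag — while the ceiling itself stays at `max_effect_gdl ×
two_serving_cap` (default cap 1.0: the meta-analytic effect is treated as
the attainable maximum, since the trials behind it did not titrate dose).
Setting `two_serving_cap` up to 2.0 explores dose-proportional responses.

### Counterfactual construction

The observed decile distributions are the *current-consumption* state. A
scenario is represented as a coupling: a list of population slices
`(weight, duration_old, servings_old, duration_new, servings_new)`. Each
slice's Hb component shifts by `effect(new) − effect(old)`, and the decile
distribution becomes the corresponding normal mixture (components are kept
exactly; summary moments are computed from them, never by forcing a single
normal). Removing fortification maps every slice to zero effect, which
reproduces the simple mixture `mean − Σ p(d)·effect(d)`.

Deterministic scenarios (duration extension, two servings) couple each
duration to its image directly. The tertile-lift scenarios couple the
lowest tertile's duration distribution to the middle tertile's by the
comonotone (quantile) coupling, which preserves ranks and — because the
middle tertile's distribution stochastically dominates — never shortens any
child's duration.

### Per-tertile duration distributions

The published inputs give an overall duration distribution in bands (26%
never, 17% at 1–2 months, 21% at 3–5, 25% at 6–11, 11% at 12+; spread
uniformly within bands this yields the reported consumer median of 5
months) and consumption-by-age curves per tertile, but no per-tertile
duration distribution. For the lift scenarios the package derives one by a
survival-curve construction: the share consuming at age `6+k` months,
relative to the peak share, is read as proportional to P(duration ≥ k),
anchored so P(duration ≥ 1) equals the tertile's ever-consumer fraction
(the overall 74% scaled by the tertile's month-6 share relative to the
population's). Durations beyond the observed window are extrapolated
geometrically and truncated at 18 months. These derived distributions do
not aggregate exactly back to the printed overall bands — the printed
anchors are mutually inconsistent at that level of detail — so the lift
comparisons use the survival-derived distributions on *both* sides
(lowest-tertile current vs lifted), keeping each comparison internally
consistent. The lift scenarios report the lowest-tertile subpopulation
only, which is the population the policy targets.

Similarly, the packaged consumption fixture stores the printed overall
monthly shares (46/63/25/13/9% at months 6/7/12/18/23, interpolated
linearly between anchors) *and* per-tertile curves that keep the printed
tertile values verbatim at months 6, 12 and 23; at other months the
interpolated tertile pattern is rescaled so its births-weighted average
matches the overall curve. No single consistent table reproduces every
printed percentage simultaneously (e.g. the month-6 tertile shares
39/49/52% average to 46.6% under birth weights, printed as 46%); the
overall curve is authoritative for population-level shares.

## Burden accounting

With `N_{d,s}` = births × IDA prevalence of severity *s* in decile *d*
(births in thousands, so DALYs come out in thousands and losses, after
division by 1000, in millions of USD):

- **Impaired physical activity**: `Σ N_{d,s} · DW_s · exposure_years`,
  with `exposure_years` = 1.5 (the 6–23-month window). By default this
  channel is confined to childhood; persisting it into adulthood is a
  parameter choice (raise `exposure_years`).
- **Cognitive impairment**: all IDA-positive children (mild+moderate+
  severe, uniformly across severities by default) accrue
  `DW_cog · discounted_life_years(life_expectancy)` DALYs and lose
  `cognitive_income_loss × PV(income stream)` of earnings.
- **Mortality**: severe cases face `mortality_risk_severe`; each death
  costs `discounted_life_years(life_expectancy)` DALYs and the full
  `PV(income stream)`.

`PV` sums wages over integer working ages (default 15–65) with growth
`(1+g)` and discount `(1+r)` factors relative to the valuation age
(default 1 year). `discounted_life_years` is the standard geometric sum
with the last partial year prorated; DALYs are discounted at the same
single 3% rate, with no age weighting (an undiscounted variant is obtained
by setting the rate to 0). Life expectancy is treated as constant (71
years) rather than via a life table.

Wages are SES-specific: a decile's wage defaults to the national mean wage
(31.9M IDR/year converted at the 2020 mean exchange rate 14,582 IDR/USD)
scaled by the decile's share of household income times ten, so a decile
holding exactly 10% of income earns the national mean. An explicit
per-decile USD wage vector overrides this.

### Stand-in parameters

The published values of the disability weights, the cognitive sequel
weight, the severe-case mortality risk, the income-loss fraction, wages and
the PSA hyperparameters are not part of this package's inputs. The
defaults — DW mild/moderate/severe 0.004/0.052/0.149 (the conventional
anemia weights), DW_cog 0.01, mortality risk 0.008, income loss 0.04,
income growth 0.04/yr — are documented stand-ins chosen once from
literature convention and national statistics. Consequently the absolute
burden levels this package prints are illustrative; the published absolute
tables are not reproduced, and the test suite instead verifies the
comparison arithmetic on the published rows, the structural identities
(additivity, homogeneity, monotonicity, scenario ordering) and the
numerical kernels against independent oracles.

## Difference tables

Comparisons report absolute differences per channel and percentages with
the *current-consumption* value as denominator (the published difference
rows divide by the current row). Levels render at one decimal; difference
cells render as integers at or above 10 and at one decimal below, rounding
half-up (so 36.5 prints 37 and 0.6 prints 1 at integer precision). The
published tables use heterogeneous precision for difference cells; the
acceptance recomputation therefore rounds each computed difference at the
precision of the corresponding printed cell. Published percentage cells
embed rounding of unprinted intermediate values (e.g. a mortality
difference printed as 0.6 against 4.7 yields 12.8%, printed as 13.4%), so
percentage checks are not asserted at printed precision.

## Probabilistic sensitivity analysis

Draws are independent across parameters (no correlation structure is
configured by default; the draw machinery accepts any per-parameter
family from beta, gamma, lognormal, normal, uniform, degenerate, with
truncation by rejection). Default families follow parameter nature:
uniform(0.25, 0.67) for the attribution share, betas centred on the point
estimates for probabilities and disability weights, normal(0.87, 0.10) for
the Hb effect, gamma (cv 0.25) for the wage, normal for growth, lognormal
for the exchange rate. Intervals are empirical 2.5/97.5 percentiles, not
normal approximations. Draw `k` is generated from a seed sequence spawned
as `(seed, k)`, so results are independent of evaluation order and
bit-reproducible; the base-case scenario evaluated per draw is current
consumption.

## Synthetic microdata

The generator emulates the child-level structure the estimation stages
need: decile (births-weighted by default), age uniform over 6–23 months,
altitude from a lowland-dominated band mixture, consumption duration from
the band distribution (74% ever-consumers), and Hb drawn as
normal(decile mean + effect(duration) − mean effect, 1.4). Centring the
effect keeps each decile's pooled mean at its configured value while
building the dose-response pattern into the data. By default consumption
is linked to Hb *only* through the effect (no confounding), so
parameter-recovery tests are clean; a `wealth_confounding` switch tilts
consumption probability with the decile to emulate the real-data situation
in which wealth shapes both diet and Hb. The generator does not emulate
survey weights, cluster design or panel structure — passing tests on these
data show the estimators and the burden pipeline are internally correct,
not that the real surveys satisfy the model's assumptions.

Decile means are estimated by a saturated OLS of Hb on decile indicators;
the heteroskedasticity-robust (HC1) covariance makes each standard error
the per-decile s/√n, and an optional transform is propagated by the delta
method (identity by default). Singleton deciles report their value with
the SE flagged unreliable.

## Numerical and scale choices

Tolerances: duration and prevalence mass conservation at 1e-9; oracle
equivalence of the discounting kernels at 1e-6 relative; exact equality for
empirical prevalence versus classify-and-count. Problem sizes in the test
suite — 10^7 draws for the normal-prevalence Monte Carlo oracle, 10^6
children for the mixture-shift microsimulation, 200 surveys of n=5000 for
parameter recovery, 10^4 PSA draws for the linear-propagation check — were
chosen so each check's Monte Carlo error is several times smaller than its
assertion tolerance while the whole suite stays quick.

Known limitations: no other Hb determinants (maternal iron status,
animal-source foods) are modelled; burden channels may overlap with other
micronutrient deficiencies, so summing across deficiency-specific models
would overcount; the attribution share is the dominant single uncertainty
and is deliberately exposed as both a parameter and a PSA distribution.
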