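# Methods

`canopymort` estimates annual forest canopy mortality rates and their
temporal trends from pixel-level satellite-interpretation records, relates
mortality to climate and forest structure, and situates the satellite-based
estimate within a multi-proxy analysis. This note documents the models, the
numerical choices, and what the synthetic-data generator does and does not
emulate.

## Data model: interpretation records

A sample plot is one interpreted 30 m pixel. Its yearly spectral trajectory
is segmented into linear pieces bounded by *vertices*; each vertex carries a
calendar year, a land use (`forest` / `non_forest`) and a land cover
(`treed` / `non_treed`), and each *segment* a change process (`stable`,
`mortality`, `regrowth`). Mortality segments become discrete mortality
events:

* **Event year.** An event is booked to `start.year + 1`, the first
  observation year on the declining segment. The start vertex is the last
  pre-disturbance observation at annual resolution, so the first year on the
  segment is the first year in which the decline is expressed. A consequence
  is that events can occur only in years `start+1 .. end` of the study
  period (32 at-risk years for 1984–2016).
* **Severity.** An event is *stand-replacing* when the segment's end vertex
  records non-treed land cover (no live trees remain at pixel scale) and
  *non-stand-replacing* when the end cover is treed (residual live trees).
  Severity is a total function of end cover.
* **Denominator.** A plot is at risk ("forest") for year *t* if its land use
  is forest at the vertex bounding *t* from below. Land use persists through
  mortality events: harvest does not change land use, so disturbed plots
  stay in the denominator unless the interpreter records a land-use change.
* Multiple events per plot are allowed, at most one per calendar year.

Aggregation produces, per country and year, the binomial data
(`n_forest`, `n_mortality`, split into `n_sr`/`n_nsr`) consumed by the trend
model. Conservation (`n_sr + n_nsr = n_mortality`) holds by construction and
is asserted in tests.

## Rate-and-trend model

For one stratum with `y_t` of `n_t` at-risk plots experiencing an event in
year *t*:

```
y_t ~ Binomial(n_t, p_t)
logit(p_t) = mu + beta * (t - t_bar) + eps_t,   eps_t ~ Normal(0, sigma)
```

with `t_bar` the midpoint year. Each year's rate emerges from a common
population: a linear time trend on the logit scale plus exchangeable annual
deviations that absorb year-to-year variation (storm years, drought years)
beyond binomial noise. The fractional change in the rate per year is
reported as

```
alpha = (exp(beta) - 1) * 100        [% per year]
```

This is exact for a log link and an excellent approximation for a logit link
when rates are far below 1 (here ~0.5–1.5%, where log and logit differ by
O(p) ≈ 1%). `P(alpha > 0)` is the posterior probability of a positive
trend, the Bayesian analogue of a one-sided trend test.

**Priors** (weakly informative, overwhelmed at the design scale of
thousands of plots per stratum):

| parameter | prior | rationale |
|---|---|---|
| `mu` | Normal(−4.8, 1.5) | centred near a 0.8% annual rate on the logit scale |
| `beta` | Normal(0, 0.1) | ±10%/yr trend a priori; data dominate |
| `sigma` | HalfNormal(0.5) | annual deviations rarely exceed ±1 logit unit |

**Pooling.** A regional estimate is the forest-area-weighted mean of the
per-country posterior draws: pooled draw *i* is `sum_c w_c * draw_{i,c}`,
honouring the stratified design (equal sample sizes per country, very
different forest areas). Weights default to forest-area shares; total land
area is a configurable alternative.

## Sampling and convergence

Posteriors are sampled with affine-invariant ensemble MCMC (emcee) using a
0.8/0.2 mixture of differential-evolution and snooker moves, which mix far
better than stretch moves in the ~35-dimensional trend posterior. The annual
deviations use a non-centred parameterisation (`eps = sigma * z`), and
`sigma` is sampled on the log scale with the Jacobian included.

Defaults: 2 fully independent ensembles × 80 walkers × 2500 post-warmup
steps (2500 warmup), thinned by 10, ~40,000 retained draws. Convergence is
assessed with split-R-hat on four "superchains" (walker groups within each
independent ensemble, so genuine between-ensemble disagreement is detected)
and bulk ESS on the individual walker chains; targets are R-hat ≤ 1.01 and
ESS ≥ 400. Individual walker chains are too short relative to the
autocorrelation time for a chain-per-walker R-hat to be informative — its
noise floor sits near 1.03 even at equilibrium — which is why the
superchain construction is used. Non-convergence sets a flag on the result
and emits a `ConvergenceWarning`; it is never silent. Fixed seeds give
bit-identical draws.

Degenerate inputs: all-zero event counts are valid (the posterior shrinks
to the prior baseline); zero denominators, non-integer counts and fewer
than five years are rejected.

## Covariate regression

Annual mortality (posterior medians, in %) and four covariates — mean
annual temperature (°C), total annual precipitation (mm), growing stock
(m³ ha⁻¹), median stand age (yr) — are averaged to six fixed 5-year
intervals (1984–1989, 1990–1994, 1995–1999, 2000–2004, 2005–2009,
2010–2015; the outer intervals absorb the first and last years). Sparse
structure series (5-yearly data) contribute the years they have.

One covariate at a time is fit with a hierarchical log-linear model

```
log(m_ci) = a_c + b_c * x_ci + e_ci,   e_ci ~ Normal(0, sigma_e)
```

with country intercepts `a_c` (and optionally slopes `b_c`) partially
pooled around population means. Covariates are standardised internally;
slopes are reported per natural unit. The two variants (random intercept
vs random intercept + slope) are compared by PSIS-LOO; when more than 20%
of points have Pareto k̂ > 0.7 the comparison falls back to exact
refit-one-out LOO (logged). R² is Bayesian R²: per draw,
`var(fitted) / (var(fitted) + sigma_e²)` — note that in a hierarchical
model the fitted values include country effects, so R² measures the whole
structured part, not the covariate alone.

The reported covariate effect is the posterior average marginal effect on
the response scale: per draw, the mean over panel cells of
`exp(log m̂ + b*delta) − m̂`, in percentage points of forest area per
`delta` covariate units. This matches effects expressed as "mortality
increased by X% per unit" read as absolute percentage points; the relative
reading would instead be `(exp(b*delta) − 1)`.

## Multi-proxy analysis

* **Fraction proxies** (wood removal, wind and bark-beetle disturbance as
  fractions of growing stock) get a Beta-regression trend:
  `y_t ~ Beta(mean m_t, precision phi)` with `logit(m_t) = a + b (t − t_bar)`
  and trend `(exp(b) − 1)·100 %/yr`, directly comparable to the canopy
  alpha. Values at exactly 0 or 1 are adjusted by the standard
  `y' = (y(n−1) + 0.5)/n` transformation (logged).
* **Individual-tree mortality** from crown-condition surveys uses the
  operational death rule: a tree is dead in year *t* iff its defoliation is
  100% in *t* and it is not assessed in *t+1*. Trees leaving the panel with
  defoliation < 100% are censored (removed from the risk set, not deaths);
  the final survey year, and any year without a successor survey, carries no
  risk set (the rule needs one year of look-ahead). The resulting annual
  counts feed the same binomial trend model with trees as trials. Deaths,
  censorings and survivors partition the risk set every year.
* **Correlations.** Pearson r between the posterior annual canopy rates and
  a fixed proxy over the overlapping years (≥5 required), computed per
  posterior draw and summarised — so the credible interval reflects
  canopy-rate uncertainty only. A year-bootstrap alternative is available
  via `method="bootstrap"`.

## Synthetic-data generator

The generator produces every input with known truth so all stages are
testable offline. Per country it draws a fixed number of plots across
forest and non-forest land (`forest_fraction`), applies independent annual
Bernoulli mortality with hazard

```
p_t = base_rate * (1 + alpha) ** (t - start_year)
```

to every forest plot-year, marks each event stand-replacing with probability
`sr_fraction`, and assembles contiguous segments. Two deliberate choices:

* The hazard applies in **every** forest plot-year, including the 5-year
  cosmetic regrowth window after a stand-replacing event (an event there
  truncates the regrowth and necessarily ends non-treed). This keeps
  `n_mortality_t ~ Binomial(n_forest, p_t)` exact, so law-of-large-numbers
  and recovery checks have clean targets.
* Land use never changes, so the at-risk denominator is constant — the
  simplest setting in which the "rate per forest area" concept is sharp.

Covariates follow linear trajectories with Gaussian noise; proxies are Beta
draws around logit-linear means with optional storm-pulse years
(1990/1999/2007 on the wind series by default); tree panels apply an annual
death hazard with 100% defoliation in the death year and absence after.
Sub-generators draw from streams spawned from the scenario seed with fixed
spawn keys, so adding or dropping one generator never perturbs another.

The default `paper_like` scenario encodes the published design: 4000 plots
in each of six central-European countries over 1984–2016 (~30.6 Mha forest
on ~92.4 Mha land from public statistics), country mean rates and trends
whose forest-area-weighted means give a pooled mean annual rate of ~0.79%
and a pooled trend of ~2.4 %/yr, `sr_fraction = 0.4` as a plausible mix of
stand-replacing (clear-cut, windthrow) versus partial (thinning, selection)
canopy loss, and an ICP-style panel of 2423 plots × 32 trees over
1990–2010 with a gently declining death hazard.

**What the generator does not emulate:** spatial autocorrelation of
disturbance (storm tracks, beetle patches), interpreter error and
inter-interpreter variability, land-use change, country-specific survey
start years, and overdispersion of annual rates beyond the exponential
trend (the generating model has no extra-binomial year effects, so the
fitted `sigma` concentrates near zero and credible intervals are, if
anything, slightly conservative). Passing recovery tests therefore
demonstrate correctness of the inference chain under the stated design, not
robustness to these real-data complications.

## Problem sizes in tests

Unit tests run reduced sampler settings (one ensemble, ~900 kept steps)
with a correspondingly relaxed R-hat bound; the end-to-end recovery tests
run the full 24,000-plot scenario with default settings, and the
calibration check uses 50 replicates of a 500-plot stratum. These sizes
keep the whole suite in the minutes range on a single CPU while leaving
the statistical conclusions unchanged.

## Known limitations

* The logit-scale `alpha` understates the log-scale fractional change by
  O(p); negligible at sub-2% rates, visible above ~10%.
* Ensemble MCMC needs many walkers in high dimensions; trend models for
  much longer series (T ≫ 50) would be better served by a
  gradient-based sampler.
* PSIS-LOO on 36-cell panels has few points; variant comparisons within
  2 SE should be treated as ties (the simpler variant is a reasonable
  default).
* The correlation credible intervals condition on the proxy being
  noise-free; proxies with substantial measurement error will yield
  overconfident intervals.
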