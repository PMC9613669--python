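# Methods

This note records the modelling and numerical choices behind the pipeline,
what the synthetic data generator does and does not emulate, and the known
limitations.

## 1. Data model and pipeline

The pipeline estimates counts of married women of reproductive age (MWRA,
ages 15–49) by division and region, observed at three censuses (1976, 1987,
2005) and projected annually over 2000–2030. Stages:

```
simulate → migration → fertility → survival → fit → project
         → summarize → diagnose → sensitivity
```

Every stage derives its RNG seed deterministically from the master seed
(`derive_stage_seed`), so any prefix of the pipeline is independently
re-runnable and byte-reproducible.

## 2. Net-migration (X₁)

Counting rule. For one census year, a woman is an in-migrant to her current
division if her previous division differs, and an out-migrant from that
previous division. Flows are person-weighted sums by single age; net = in −
out. Rows with a missing previous division contribute to neither flow —
treating non-response as non-migration is conservative and preserves the
closed-system zero-sum identity that the tests enforce exactly.

Boundary harmonization. Counts recorded on historical division registers
are split across current divisions by fixed shares (a `PartitionMap` whose
shares sum to one per old division); totals are conserved to 1e-9 relative
tolerance.

Age proportions. X₁(a,d,t) = net(a,d,t) / Σₐ net(a,d,t), normalized within
division-year. When the division-year total is zero the proportion is
undefined; the pipeline sets X₁ = 0 for all ages there and flags the cells
(`x1_defined = False`). This keeps the covariate defined without inventing
a direction of flow. Note that with mixed-sign age nets the proportions
legitimately fall outside [0, 1]; only their sum is constrained (= 1 where
defined).

Model. X₁ is smoothed and extrapolated by a Gaussian hierarchical model:

```
X₁(a,d,t) = β₀ + v_region(r) + v_division(d) + v_age(a,d) + m(d,t) + ε
m(d,t) = Σ_{s ≤ t} δ(d,s),   δ ~ N(0, τ_rw²)
```

with exchangeable normal effects at each level and half-normal priors on
all scales. The random walk runs at annual resolution; increments between
censuses are identified only in sums, which is exactly the Bayesian
interpolation wanted. Projection propagates the walk with fresh N(0, τ_rw)
increments per draw. Whether proportions should be normalized within
division or within region is ambiguous in principle; this package
normalizes within division, matching the covariate's (a,d,r,t) indexing in
the population model.

## 3. Fertility (X₂)

Empirical ASFR. Each woman's history is unrolled month by month between her
15th birthday and the month before interview (CMC arithmetic); each month
contributes `weight × all_women_factor / 12` woman-years to its (single
age, calendar cell); births are allocated to the cell containing their CMC.
The all-women factor multiplies both numerator and denominator — it cancels
in a rate when constant but matters when it varies by woman, which is what
re-expresses rates for the surveyed women as rates for all women. Cells
with zero exposure are flagged undefined, never set to 0. Calendar years
can be pooled into periods (`period_length`, default 5 in the pipeline)
labelled by the midpoint year; pooling keeps cell birth counts large enough
that modelling log rates is not materially biased by small-count noise.

Model. Log-ASFR with an age random walk (smooth single-age profile),
exchangeable region intercepts, and a region-level random walk over
calendar years; cells with zero births carry no likelihood contribution
(the log link needs a positive empirical rate). The intercept prior is
N(log 0.02, 1.5²), so with no data at all the posterior median rate is
about 0.02 — a deliberately low prior level that makes "no signal" visible.
Positivity of posterior rate surfaces holds by construction (rates are
exponentials of the linear predictor).

## 4. Survival (X₃)

Five-year survival probabilities ₅pₓ are interpolated to a single-age,
single-year surface: each value is anchored at its age-group midpoint
(x + 2.5) and period midpoint (start + 2), interpolated linearly along age
within each period column, then linearly along calendar year, with linear
extrapolation beyond the outermost anchors and clipping into (0, 1]
(logged). The default interpolates the five-year probabilities directly
onto the single-age grid; `mode="fifth-root"` applies the standard
constant-hazard conversion ₅pₓ^(1/5) first. The direct mode is the default
because it is the simpler stated procedure this pipeline reproduces; the
fifth-root mode is the demographically conventional alternative. Anchor
fidelity, linearity, and in-hull monotonicity are tested exactly;
monotonicity can break under extrapolation, where the linear rule uses a
negative weight.

## 5. Population model

Observation model: `log η ~ Normal(log η*, σ²)` with

```
log η* = β₀ + β₁·X₁ + β₂·X₂·X₃ + u₁(a,d,t) + u₂(d,r,t)
```

- Fertility and survival enter as an interaction X₂·X₃ (their product is
  the effective rate of surviving daughters/mothers driving cohort growth);
  the frame-building step reports all pairwise covariate correlations as a
  collinearity diagnostic.
- β's are global coefficients with Normal(0, 10²) priors; u₁ and u₂ are
  additive zero-mean normal varying effects over their index sets with
  half-normal(1) scale priors. Giving each β a single shared value (rather
  than one per cell) is the only specification under which a two-step
  regression forecast — estimate coefficients on census years, apply them
  to projected covariates — is meaningful.
- u₁ is indexed by (age, division, time) and therefore has one level per
  observed cell: only σ² + τ₁² is identified by the data. Both parameters
  are kept (they play different roles in projection — u₁ is structure, ε is
  observation noise), and the sampler handles the ridge with a collapsed
  update (below).
- Zero observed counts are offset by +0.5 persons before logging and
  flagged; the log-scale likelihood requires positivity.

Projection (step two) evaluates the linear predictor at 2000–2030 covariate
values taken from the driver models' posteriors, paired draw-wise with the
population model's coefficient draws (recycled modulo length when draw
counts differ, e.g. 5,000 fertility vs. 10,000 population draws at default
settings). Fresh u₁ (per cell), u₂ (per division-year, shared across ages —
this preserves within-division correlation of the age profile), and ε are
drawn per draw from their posterior scales; both can be switched off to
obtain the pure linear predictor.

## 6. MCMC

All three models are linear-Gaussian hierarchies and are sampled with a
blocked Gibbs sampler (`mwra.gibbs`):

- location blocks (coefficients, each random-effect vector, whole random
  walks) have exact multivariate-normal full conditionals, sampled jointly
  per block via Cholesky of the precision;
- scale parameters (half-normal priors) are updated by univariate slice
  sampling on the log scale;
- three mixing accelerators address the known pathologies of the centered
  parameterization: (i) a generalized-Gibbs *sweep* that shifts each group
  effect's mean into the intercept (the shift is drawn from its exact
  conditional under the priors; the likelihood is flat along this
  direction); (ii) *ASIS interweaving* — after the centered scale update,
  the scale is re-drawn from its conjugate conditional in the non-centered
  parameterization (u/τ held fixed), breaking the τ–u funnel; (iii) a
  *collapsed* Metropolis update of (τ, σ) for observation-level effects,
  with the effect integrated out analytically (marginally r ~ N(0, τ²+σ²))
  and re-drawn from its exact conditional afterwards.

Default run sizes are 10,000 iterations per chain with 3,000 burn-in for
the net-migration and population models and 5,000 with 3,000 burn-in for
the fertility model, two chains each. Convergence is assessed by split-R̂
(flagging at ≥ 1.1; results are returned with a warning, not discarded),
effective sample size (via arviz, which also serves as an independent
cross-check of the R̂ implementation in the tests), and trace plots.
Posterior-predictive p-values are computed for the mean, SD, and maximum
absolute residual of cell log counts under replicated data; values outside
(0.05, 0.95) indicate misfit. Scales are floored at 1e-4 to keep precision
matrices well-conditioned in degenerate (noise-free) inputs.

Percentile rule: linear interpolation between order statistics (numpy's
default, type 7), verified against a sort-based oracle in the tests.
Unit-year point estimates use the sum-of-medians convention; the
median-of-sums alternative is reported alongside (for right-skewed cell
draws sum-of-medians is systematically the smaller of the two, which the
tests document); credible intervals are always percentiles of the per-draw
age-summed totals.

## 7. Synthetic world

The generator emulates the real inputs' *structure*: person-level census
records (10% sample, weight 10, configurable) including unmarried women and
men so MWRA subsetting is exercised (proportion married logistic in age);
birth histories with CMC dates, lognormal sampling weights, and uniform
all-women factors in [1.0, 1.3]; abridged life tables with survival
declining in age and improving slowly over periods.

Ground truth is exact by construction: for every cell, `log η*` equals the
log-linear predictor evaluated at stored covariates, coefficients, varying
effects, and noise (an identity the tests assert at machine precision), and
census cell counts are Poisson draws with mean η* (log-normal optionally),
so weighted census totals converge to the truth over repeated generation
(tested against a 3-Monte-Carlo-SE band). Internal migration follows a
gravity-flavoured process — movers leave with probability
`migration_intensity` and choose destinations proportional to per-division
attractiveness weights — and the stored truth X₁ is the analytic
expectation of net flows under that process, so census-derived proportions
are noisy but unbiased estimates of the truth. Birth histories are a
piecewise-constant-hazard process: per (age, calendar) cell, birth counts
are Poisson with mean rate × exposure, with birth months uniform within the
cell (no minimum spacing between births is enforced; the hazard, which is
what the estimator recovers, is unaffected).

What the generator does **not** emulate: covariate codebooks of real census
extracts; correlated survey non-response; age heaping and displacement of
birth dates; enumeration completeness differences between censuses; real
boundary-change geometries (partition maps are supplied, not derived from
shapefiles); international migration. Passing recovery tests on this world
therefore demonstrates the *estimators* are correct under the stated data
model, not that real-data artefacts are handled.

Default world: 2 regions × 2 divisions each, ages 15–49, censuses
1976/1987/2005, base scale 500 MWRA per (age, division) cell, migration
intensity 0.08 per inter-census interval, peak ASFR 0.24 at modal age 24
with a slow calendar decline, ₅p₁₅ = 0.985, log-scale noise 0.05, varying
effect SDs 0.04. Survey years mirror the five DHS rounds (1991–2018) with
1,000 women each by default. The covariate correlation structure of real
data (e.g. the strength of the fertility–survival correlation) is
config-driven, not calibrated to any empirical value.

## 8. Problem sizes used in tests and the acceptance script

Tests run on reduced worlds (typically ages 15–19, 2 × 2 divisions) with
MCMC sizes of 600–3,000 iterations and 2 chains, chosen so the whole suite
completes in about two minutes while keeping Monte-Carlo error well inside
the asserted tolerances; recovery/coverage suites use 20–30 replicates with
binomial-slack thresholds (≥ 86% for nominal 95% intervals). The acceptance
script runs the full-age default world with 1,500–3,000 iterations. These
sizes are package choices for test economy; the pipeline defaults remain
the full run sizes.

## 9. Known limitations

- The two-step regression forecast extrapolates relationships fitted to
  three census time points; with so few time observations, trend direction
  is driven by the raw data and long-horizon intervals should be read
  accordingly.
- Modelling empirical log-ASFR with additive Gaussian error ignores the
  Poisson character of small cell counts; the pipeline mitigates this by
  pooling calendar periods, and the zero-birth-cell exclusion slightly
  favours higher rates in sparse cells.
- The migration model treats the net-migration proportion as Gaussian;
  extreme proportions from near-zero division totals are downweighted only
  through the hierarchical shrinkage, not a heavy-tailed likelihood.
- u₁ and ε are separately retained but jointly identified; their split is
  prior-driven and only their sum is interpretable.
- Draw-wise pairing of driver and population posteriors treats the driver
  models as independent of the population model given the covariates; any
  joint dependence is not propagated.
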