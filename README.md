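# mwra — Bayesian subnational estimation of married women of reproductive age

Counts of **married women of reproductive age** (MWRA: women aged 15–49 who
are married or in union) are the base population for planning reproductive
health services — family planning demand, unmet need, contraceptive
coverage — yet many countries have no subnational series of them. This
package implements, as a tested and reusable pipeline, a Bayesian approach
for deriving MWRA counts by second-level administrative unit (*division*)
and first-level unit (*region*) from three standard data streams:

1. **census microdata** (person-weighted 10% samples with single age, sex,
   marital status, and current vs. previous division of residence),
2. **retrospective birth histories** (DHS-style, CMC-encoded dates,
   sampling weights, all-women factors), and
3. **abridged life tables** (five-year survival probabilities ₅pₓ by
   five-year age group and calendar period).

The geography and study design mirror Cameroon (divisions nested in
regions, censuses in 1976/1987/2005, projections 2000–2030), but every
input is synthetic: a generator with known ground truth stands in for the
restricted-access microdata, so the full pipeline is testable end to end.

## The model

For age *a*, division *d*, region *r*, and census time *t*, observed log
counts follow

```
log η_adrt ~ Normal(log η*_adrt, σ²)
log η*_adrt = β₀ + β₁·X₁_adrt + β₂·X₂_adrt·X₃_adrt + u₁_adt + u₂_drt
```

where

- **X₁** is the age-specific *net-migration proportion* — net migration at
  age *a* as a share of the division-year total, derived from current vs.
  previous residence in the census (counts for historical divisions are
  proportionately re-partitioned onto the current register);
- **X₂** is the *age-specific fertility rate* (ASFR), estimated from birth
  histories by exact month-level exposure and smoothed by a Bayesian
  hierarchical model (random walk over single ages, exchangeable region
  intercepts, region-level random walk over calendar time, on the log
  scale);
- **X₃** is the single-age, single-year *survival probability*, obtained
  from the abridged life table by bilinear interpolation anchored at
  age-group and period midpoints (fertility and survival enter as an
  interaction);
- **u₁, u₂** are zero-mean normal varying effects over (age, division,
  time) and (division, region, time), with half-normal scale hyperpriors;
  coefficients carry Normal(0, 10²) priors.

Net-migration proportions themselves are smoothed and extrapolated by a
hierarchical Gaussian model (ages within divisions, divisions within
regions, division-level random walk over calendar years). All three models
are sampled by a blocked Gibbs sampler written for this package (conjugate
normal updates per block; slice sampling for half-normal scales; collapsed
and interweaved updates for the weakly identified scale pairs). Step two
predicts 2000–2030 populations by pairing, draw for draw, the population
model's coefficients with the driver models' own posterior trajectories,
so driver uncertainty propagates into the projection intervals.

Summaries follow the published conventions: unit-year point estimates are
sums over ages of per-age posterior medians; 95% credible intervals are the
2.5th/97.5th percentiles of per-draw age-summed totals; the annual rate of
change over (t₁, t₂) is `100·(P_t₂ − P_t₁)/(P_t₁·(t₂ − t₁))` percentage
points per annum. Diagnostics include split-R̂, effective sample size,
posterior-predictive p-values, and two sensitivity exercises (predictor
exclusion; hyperprior rescaling).

## Worked example

Run the full pipeline on the default small synthetic world (2 regions × 4
divisions, ages 15–49, censuses 1976/1987/2005, reduced MCMC sizes):

```python
import pandas as pd
from mwra.config import McmcSettings, SyntheticWorldConfig
from mwra.pipeline import RunConfig, run_pipeline

cfg = RunConfig(
    out_dir="run",
    world=SyntheticWorldConfig(n_regions=2, divisions_per_region=2,
                               n_women_per_survey=400),
    migration_mcmc=McmcSettings(1500, 500, 2),
    fertility_mcmc=McmcSettings(1500, 500, 2),
    population_mcmc=McmcSettings(3000, 1000, 2),
    seed=1,
)
run_pipeline(cfg)
proj = pd.read_csv("run/projections.csv")
print(proj[(proj.level == "national") & proj.year.isin([2000, 2030])])
```

which prints (seed 1):

```
   level     unit  year  count_median  count_median_of_sums      cri_low      cri_high
national National  2000  81969.728165          85977.067719 64721.336146 118520.104909
national National  2030  85033.402252          89801.511124 65138.678112 129844.381480
```

i.e. a national MWRA count around 82,000 in 2000 rising to a median 85,000
by 2030 with a 95% credible interval of roughly 65,000–130,000 — intervals
widen over the horizon because random-walk extrapolation of the migration
and fertility drivers adds uncertainty year by year. The matching
convergence and fit diagnostics for this run are R̂max = 1.008 and
posterior-predictive p-values of 0.50 / 0.52 / 0.29 for the mean, SD, and
maximum absolute residual of cell log counts (all well inside the 0.05–0.95
band).

The same run is available from the shell:

```sh
mwra run-all --config cfg.yaml --seed 1
mwra simulate --config cfg.yaml       # any prefix of the pipeline
```

Each run directory contains `census.csv`, `births.csv`, `lifetable.csv`,
`migration_series.csv`, `asfr_empirical.csv`, `survival_surface.csv`,
`model_frame.csv`, posterior JSON summaries, `projections.csv`, `rates.csv`,
`diagnostics.json`, `sensitivity.json`, and a `manifest.json` with the
configuration hash, per-stage seeds, and output checksums.

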