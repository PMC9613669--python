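"""Synthetic demographic world with known ground truth.

Emulates the three real input streams of the estimation pipeline so every
downstream stage is testable without external data:

* person-weighted census microdata (10% samples) with current and previous
  division of residence, single age, sex, and marital status;
* DHS-style retrospective birth histories with CMC-encoded dates, sampling
  weights, and all-women factors;
* abridged life tables with five-year survival probabilities by five-year
  age group and calendar period.

The world is built around a stored :class:`GroundTruth`: for every
(age, division, region, year) cell the expected MWRA count eta* satisfies,
as an exact algebraic identity,

    log eta* = b0 + b1 * X1 + b2 * X2 * X3 + u1 + u2 + eps

where X1 is the age-proportion of net internal migration, X2 the
age-specific fertility rate, X3 the single-age survival probability, u1/u2
zero-mean random effects, and eps log-scale noise.  Census cell counts are
then Poisson draws around eta* (log-normal noise optionally), so weighted
census totals converge to the stored truth over repeated generation.

Internal migration is generated by a gravity-flavoured process: each mover
leaves their division with probability ``migration_intensity`` per
inter-census interval and picks a destination proportional to per-division
attractiveness weights.  The stored truth X1 is the analytic expectation of
age-specific net flows under that process, so census-derived proportions
are noisy estimates of the truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import (
    AdminRegister,
    ConfigurationError,
    SyntheticWorldConfig,
    ValidationError,
    derive_stage_seed,
)
from .survival import interpolate_survival

CENSUS_COLUMNS = [
    "census_year",
    "age",
    "sex",
    "marital_status",
    "division_current",
    "division_previous",
    "person_weight",
]

MODAL_FERTILITY_AGE = 24.0
FERTILITY_AGE_SPREAD = 7.5
FERTILITY_DECLINE_RATE = 0.004  # per calendar year, on the log scale


def cmc(year: int, month: int) -> int:
    """Century-month code: months since January 1900 (Jan 1900 = 1)."""
    return (year - 1900) * 12 + month


def cmc_year(c) -> np.ndarray:
    return 1900 + (np.asarray(c) - 1) // 12


@dataclass
class GroundTruth:
    """Stored truth of the synthetic world.

    ``frame`` holds one row per (age, division, region, year) with the
    covariates (x1, x2, x3), random effects (u1, u2), noise (eps), and the
    expected population ``eta_star``; ``betas_total`` is the coefficient
    vector of the log-linear identity including the population-scale offset
    folded into the intercept.
    """

    config: SyntheticWorldConfig
    frame: pd.DataFrame
    betas_total: tuple[float, float, float]
    attractiveness: pd.Series  # per-division destination weight
    lifetable: pd.DataFrame
    division_scale: pd.Series = field(default=None)
    asfr_full: pd.DataFrame = field(default=None)  # all calendar years

    @property
    def register(self) -> AdminRegister:
        return self.config.register

    def as_migration_series(self) -> pd.DataFrame:
        """Truth net-migration series (division, age, year, net counts and x1)."""
        f = self.frame
        return f[["division", "age", "year", "net_count", "x1"]].copy()

    def as_asfr_surface(self) -> pd.DataFrame:
        """Truth ASFR by (age, region, year), covering every calendar year a
        retrospective birth history can reach."""
        if self.asfr_full is not None:
            return self.asfr_full.copy()
        f = self.frame.drop_duplicates(["age", "region", "year"])
        out = f[["age", "region", "year", "x2"]].rename(columns={"x2": "asfr"})
        return out.reset_index(drop=True)

    def as_survival_surface(self) -> pd.DataFrame:
        """Truth single-age single-year survival (national)."""
        f = self.frame.drop_duplicates(["age", "year"])
        return f[["age", "year", "x3"]].rename(columns={"x3": "px1"}).reset_index(drop=True)

    def linear_predictor_identity_gap(self) -> float:
        """Max |log eta* - (b0 + b1 x1 + b2 x2 x3 + u1 + u2 + eps)|; 0 by construction."""
        b0, b1, b2 = self.betas_total
        f = self.frame
        lp = b0 + b1 * f.x1 + b2 * f.x2 * f.x3 + f.u1 + f.u2 + f.eps
        return float(np.abs(np.log(f.eta_star) - lp).max())


def true_asfr(config: SyntheticWorldConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Hump-shaped age schedule peaking at the modal age, with region
    multipliers and a slow log-linear calendar decline."""
    ages = config.ages
    years = np.arange(min(config.census_years + config.survey_years) - 35,
                      config.projection_years[1] + 1)
    regions = config.register.regions
    age_pat = np.exp(-0.5 * ((ages - MODAL_FERTILITY_AGE) / FERTILITY_AGE_SPREAD) ** 2)
    reg_mult = np.exp(rng.normal(0.0, 0.08, size=len(regions)))
    t0 = years[0]
    rows = []
    for ri, r in enumerate(regions):
        for yi, y in enumerate(years):
            decline = np.exp(-FERTILITY_DECLINE_RATE * (y - t0))
            rows.append(
                pd.DataFrame(
                    {
                        "age": ages,
                        "region": r,
                        "year": y,
                        "asfr": config.asfr_peak * age_pat * reg_mult[ri] * decline,
                    }
                )
            )
    return pd.concat(rows, ignore_index=True)


def generate_life_tables(config: SyntheticWorldConfig) -> pd.DataFrame:
    """Abridged female life table: 5px by five-year age group (15-19 .. 45-49)
    and five-year period covering 1976-2030; survival declines with age and
    improves slowly over calendar time."""
    base = config.survival_level
    age_groups = np.arange(15, 50, 5)
    periods = np.arange(1976, 2031, 5)
    rows = []
    for pi, p in enumerate(periods):
        for gi, g in enumerate(age_groups):
            px5 = base - 0.0035 * gi + 0.0006 * pi
            rows.append((p, g, min(px5, 1.0)))
    out = pd.DataFrame(rows, columns=["period_start_year", "age_group_start", "px5"])
    if (out.px5 <= 0).any():
        raise ConfigurationError("survival_level too low: generated px5 <= 0")
    return out


def _expected_net_flows(
    config: SyntheticWorldConfig,
    division_scale: pd.Series,
    attractiveness: pd.Series,
    age_weight: np.ndarray,
) -> pd.DataFrame:
    """Expected age-specific net migration per division under the gravity
    process, and the resulting age proportions X1 (zero where the division
    total net is zero)."""
    reg = config.register
    divisions = reg.divisions
    ages = config.ages
    i = config.migration_intensity
    w = attractiveness.loc[divisions].to_numpy()
    pop = np.outer(age_weight, division_scale.loc[divisions].to_numpy())
    pop *= config.base_population_scale
    # flow[a, o, d] = pop[a, o] * i * w[d] / sum_{d' != o} w[d']
    out_flow = pop * i  # total leaving each (a, o)
    inflow = np.zeros_like(pop)
    if len(divisions) > 1 and i > 0:
        denom = w.sum() - w  # per origin
        for o in range(len(divisions)):
            share = w / denom[o]
            share[o] = 0.0
            inflow += np.outer(out_flow[:, o], share)
    else:
        out_flow = np.zeros_like(pop)
    net = inflow - out_flow
    totals = net.sum(axis=0)  # per division
    x1 = np.zeros_like(net)
    nz = np.abs(totals) > 1e-12
    x1[:, nz] = net[:, nz] / totals[nz]
    recs = []
    for di, d in enumerate(divisions):
        recs.append(
            pd.DataFrame(
                {
                    "division": d,
                    "age": ages,
                    "in_count": inflow[:, di],
                    "out_count": out_flow[:, di],
                    "net_count": net[:, di],
                    "x1": x1[:, di],
                }
            )
        )
    return pd.concat(recs, ignore_index=True)


def make_ground_truth(config: SyntheticWorldConfig) -> GroundTruth:
    """Build the full ground truth: covariate surfaces, random effects, and
    expected populations on the union of census and projection years."""
    rng = np.random.default_rng(derive_stage_seed(config.seed, "truth"))
    reg = config.register
    divisions = reg.divisions
    ages = config.ages
    years = sorted(
        set(config.census_years)
        | set(range(config.projection_years[0], config.projection_years[1] + 1))
    )

    lifetable = generate_life_tables(config)
    surv = interpolate_survival(
        lifetable, ages=ages, years=np.arange(min(years), max(years) + 1)
    ).set_index(["age", "year"])["px1"]

    asfr_full = true_asfr(config, rng)
    asfr = asfr_full.set_index(["age", "region", "year"])["asfr"]

    division_scale = pd.Series(
        np.exp(rng.normal(0.0, 0.25, size=len(divisions))), index=divisions
    )
    attractiveness = pd.Series(
        np.exp(rng.normal(0.0, 0.7, size=len(divisions))), index=divisions
    )
    age_weight = np.exp(-0.015 * (ages - ages[0]))
    flows = _expected_net_flows(config, division_scale, attractiveness, age_weight)
    flow_idx = flows.set_index(["division", "age"])

    b0_cfg, b1, b2 = config.true_betas
    b0 = b0_cfg + np.log(config.base_population_scale)

    u2 = {
        (d, t): rng.normal(0.0, config.u2_sd) for d in divisions for t in years
    }
    rows = []
    for d in divisions:
        r = reg.region_of(d)
        for t in years:
            for a in ages:
                x1 = float(flow_idx.loc[(d, a), "x1"])
                x2 = float(asfr.loc[(a, r, t)])
                x3 = float(surv.loc[(a, t)])
                u1 = rng.normal(0.0, config.u1_sd)
                eps = rng.normal(0.0, config.noise_sd)
                # division size enters through the age-division intercept u1
                # channel: fold log division_scale and age weight into the
                # linear predictor so truth populations vary realistically
                offset = float(
                    np.log(division_scale.loc[d]) + np.log(age_weight[a - ages[0]])
                )
                u1_total = u1 + offset
                lp = b0 + b1 * x1 + b2 * x2 * x3 + u1_total + u2[(d, t)] + eps
                rows.append(
                    (
                        a, d, r, t, x1, x2, x3, u1_total, u2[(d, t)], eps,
                        float(flow_idx.loc[(d, a), "net_count"]),
                        float(np.exp(lp)),
                    )
                )
    frame = pd.DataFrame(
        rows,
        columns=[
            "age", "division", "region", "year",
            "x1", "x2", "x3", "u1", "u2", "eps", "net_count", "eta_star",
        ],
    )
    return GroundTruth(
        config=config,
        frame=frame,
        betas_total=(b0, b1, b2),
        attractiveness=attractiveness,
        lifetable=lifetable,
        division_scale=division_scale,
        asfr_full=asfr_full,
    )


def _previous_division_probs(
    truth: GroundTruth, division: str, age_idx: int
) -> tuple[list[str], np.ndarray]:
    """P(previous division | current division) under the gravity process."""
    cfg = truth.config
    divisions = truth.register.divisions
    i = cfg.migration_intensity
    w = truth.attractiveness.loc[divisions].to_numpy()
    scale = truth.division_scale.loc[divisions].to_numpy()
    age_weight = np.exp(-0.015 * age_idx)
    pop = scale * age_weight * cfg.base_population_scale
    di = divisions.index(division)
    if len(divisions) > 1 and i > 0:
        denom = w.sum() - w
        inflow = pop * i * w[di] / denom  # from each origin into `division`
    else:
        inflow = np.zeros_like(pop)
    inflow[di] = 0.0
    stay = pop[di] * (1 - i)
    probs = np.append(inflow, stay)
    probs = probs / probs.sum()
    return divisions + [division], probs


def generate_census(
    config: SyntheticWorldConfig,
    truth: GroundTruth,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Person-level census microdata for every configured census year.

    One row per sampled person (a ``sample_fraction`` sample, person weight
    1/fraction).  Weighted MWRA counts per (age, division, year) are Poisson
    draws around the stored truth eta*; unmarried women and men are added so
    MWRA subsetting is exercised, with the proportion married logistic in
    age.  Movers are assigned a previous division != current with the
    gravity-process conditional probabilities.
    """
    if truth.config != config:
        raise ConfigurationError("config: does not match the ground truth's config")
    if rng is None:
        rng = np.random.default_rng(derive_stage_seed(config.seed, "census"))
    reg = config.register
    slope, mid = config.marital_logistic
    weight = config.person_weight
    frames = []
    cells = truth.frame[truth.frame.year.isin(config.census_years)]
    prev_cache: dict[tuple[str, int], tuple[list[str], np.ndarray]] = {}
    for (d, t), cell in cells.groupby(["division", "year"], sort=True):
        cell = cell.sort_values("age")
        lam = cell.eta_star.to_numpy() * config.sample_fraction
        if config.count_noise == "poisson":
            n_married = rng.poisson(lam)
        else:
            n_married = np.round(
                lam * np.exp(rng.normal(0.0, config.noise_sd, size=len(lam)))
            ).astype(int)
        ages = cell.age.to_numpy()
        p_married = 1.0 / (1.0 + np.exp(-slope * (ages - mid)))
        n_unmarried = rng.poisson(lam * (1 - p_married) / p_married)
        n_male = rng.poisson(lam)

        parts = []
        for counts, sex, marital in (
            (n_married, "female", "married"),
            (n_unmarried, "female", "other"),
            (n_male, "male", "other"),
        ):
            n_tot = int(counts.sum())
            if n_tot == 0:
                continue
            parts.append(
                pd.DataFrame(
                    {
                        "census_year": t,
                        "age": np.repeat(ages, counts),
                        "sex": sex,
                        "marital_status": marital,
                        "division_current": d,
                        "person_weight": weight,
                    }
                )
            )
        if not parts:
            continue
        block = pd.concat(parts, ignore_index=True)
        # previous division of residence under the gravity process
        prev = np.empty(len(block), dtype=object)
        for a in np.unique(block.age.to_numpy()):
            sel = block.age.to_numpy() == a
            key = (d, int(a - config.age_min))
            if key not in prev_cache:
                prev_cache[key] = _previous_division_probs(truth, d, int(a - config.age_min))
            labels, probs = prev_cache[key]
            prev[sel] = rng.choice(labels, size=int(sel.sum()), p=probs)
        if config.missing_previous_frac > 0:
            miss = rng.random(len(block)) < config.missing_previous_frac
            prev[miss] = None
        block["division_previous"] = prev
        frames.append(block)
    out = pd.concat(frames, ignore_index=True)[CENSUS_COLUMNS]
    for col in ("division_current",):
        for div in out[col].unique():
            reg.check_division(div)
    return out


def generate_birth_histories(
    config: SyntheticWorldConfig,
    truth_asfr: pd.DataFrame,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Retrospective birth histories from a piecewise-constant-hazard process.

    For each survey year, ``n_women_per_survey`` women aged 15-49 at
    interview are drawn; each woman's exact-age trajectory is partitioned
    into (age, calendar-year) cells and the number of births in each cell is
    Poisson with mean (truth ASFR at that age/year/region) x (exposure in
    years).  Birth months are placed uniformly within their cell.

    Returns one row per woman with columns (woman_id, region, interview_cmc,
    woman_birth_cmc, weight, all_women_factor, child_birth_cmcs), the last a
    list of CMC codes.
    """
    rates = truth_asfr["asfr"].to_numpy(dtype=float)
    if np.any(rates < 0) or np.any(rates > 1):
        raise ValidationError("truth ASFR rates must lie in [0, 1] per woman-year")
    if rng is None:
        rng = np.random.default_rng(derive_stage_seed(config.seed, "births"))
    yr_min = int(truth_asfr.year.min())
    yr_max = int(truth_asfr.year.max())
    regions = sorted(truth_asfr.region.unique())
    age_lo = int(truth_asfr.age.min())
    age_hi = int(truth_asfr.age.max())
    n_years = yr_max - yr_min + 1
    # dense rate cube [age, region, year] for fast per-cell lookup
    rate_cube = np.zeros((age_hi - age_lo + 1, len(regions), n_years))
    ridx = {r: i for i, r in enumerate(regions)}
    for row in truth_asfr.itertuples(index=False):
        rate_cube[int(row.age) - age_lo, ridx[row.region], int(row.year) - yr_min] = row.asfr

    rows = []
    wid = 0
    for sy in config.survey_years:
        for _ in range(config.n_women_per_survey):
            wid += 1
            region = regions[rng.integers(len(regions))]
            interview = cmc(sy, int(rng.integers(1, 13)))
            age_at_interview = int(rng.integers(15, 50))
            birth = interview - (age_at_interview * 12 + int(rng.integers(0, 12)))
            weight = float(np.exp(rng.normal(0.0, 0.2)))
            awf = float(rng.uniform(1.0, 1.3))
            births: list[int] = []
            # month the woman turns the lowest modelled age .. month before interview
            start = birth + age_lo * 12
            months = np.arange(start, interview)
            if len(months):
                age_m = (months - birth) // 12
                year_m = cmc_year(months)
                ok = (age_m <= age_hi) & (year_m >= yr_min) & (year_m <= yr_max)
                months = months[ok]
                if len(months):
                    key = (age_m[ok] - age_lo) * n_years + (year_m[ok] - yr_min)
                    cells, first, counts = np.unique(
                        key, return_index=True, return_counts=True
                    )
                    rates = rate_cube[cells // n_years, ridx[region], cells % n_years]
                    ks = rng.poisson(rates * counts / 12.0)
                    for ci in np.nonzero(ks)[0]:
                        cell_months = months[first[ci] : first[ci] + counts[ci]]
                        births.extend(
                            int(m) for m in rng.choice(cell_months, size=int(ks[ci]))
                        )
            rows.append(
                (wid, region, interview, birth, weight, awf, sorted(births))
            )
    return pd.DataFrame(
        rows,
        columns=[
            "woman_id",
            "region",
            "interview_cmc",
            "woman_birth_cmc",
            "weight",
            "all_women_factor",
            "child_birth_cmcs",
        ],
    )


def write_world(config: SyntheticWorldConfig, out_dir) -> dict:
    """Generate and write census.csv, births.csv, lifetable.csv, truth.json."""
    import json
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    truth = make_ground_truth(config)
    census = generate_census(config, truth)
    births = generate_birth_histories(config, truth.as_asfr_surface())
    births_flat = births.copy()
    births_flat["child_birth_cmcs"] = births_flat.child_birth_cmcs.map(
        lambda xs: ";".join(str(x) for x in xs)
    )
    census.to_csv(out / "census.csv", index=False)
    births_flat.to_csv(out / "births.csv", index=False)
    truth.lifetable.to_csv(out / "lifetable.csv", index=False)
    truth.frame.to_csv(out / "truth_frame.csv", index=False)
    meta = {
        "betas_total": list(truth.betas_total),
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in config.to_dict().items()
        },
    }
    (out / "truth.json").write_text(json.dumps(meta, indent=2))
    return {
        "census": out / "census.csv",
        "births": out / "births.csv",
        "lifetable": out / "lifetable.csv",
        "truth": out / "truth.json",
    }


def read_birth_histories(path) -> pd.DataFrame:
    """Read births.csv, decoding the semicolon-joined CMC list column."""
    df = pd.read_csv(path)
    df["child_birth_cmcs"] = df.child_birth_cmcs.fillna("").map(
        lambda s: [int(x) for x in str(s).split(";") if x not in ("", "nan")]
    )
    return df
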