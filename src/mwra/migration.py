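"""Internal net-migration from census microdata.

A woman's current and previous administrative division of residence identify
her as an in-migrant to the current division and an out-migrant from the
previous one.  Person-weighted flows are tallied by single age, historical
counts are re-partitioned proportionately onto the current division register
(boundary harmonization), net counts are converted to age proportions of the
division-year total (the X1 covariate of the population model), and a
Bayesian hierarchical time-series model smooths and extrapolates those
proportions: single ages within divisions, divisions within regions, and a
division-level Gaussian random walk over calendar time.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .config import (
    AdminRegister,
    McmcSettings,
    PriorSettings,
    RegistryError,
    ValidationError,
    DEFAULT_MIGRATION_MCMC,
)
from .gibbs import DenseEffect, GaussianLMM, GroupEffect, PosteriorDraws

log = logging.getLogger(__name__)

SERIES_COLUMNS = ["division", "age", "year", "in_count", "out_count", "net_count"]


def mwra_filter(records: pd.DataFrame) -> pd.DataFrame:
    """Married women of reproductive age: female, married/in-union, 15-49."""
    return records[
        (records.sex == "female")
        & (records.marital_status == "married")
        & records.age.between(15, 49)
    ]


def compute_flows(
    records: pd.DataFrame,
    register: AdminRegister,
    subset=mwra_filter,
) -> pd.DataFrame:
    """Weighted in-, out-, and net-migration counts by division and single age.

    For one census year: in(d) sums the person weights of subset members
    currently in d whose previous division differs; out(d) sums weights of
    members elsewhere who name d as their previous division; net = in - out.
    Rows with a missing previous division contribute to neither flow.
    """
    years = records.census_year.unique()
    if len(years) != 1:
        raise ValidationError(
            f"compute_flows expects a single census year, got {sorted(years)}"
        )
    year = int(years[0])
    sub = subset(records) if subset is not None else records
    for col in ("division_current", "division_previous"):
        for div in pd.unique(sub[col].dropna()):
            register.check_division(div)

    divisions = register.divisions
    ages = np.arange(15, 50)
    base = pd.MultiIndex.from_product(
        [divisions, ages], names=["division", "age"]
    ).to_frame(index=False)
    if len(sub) == 0:
        log.warning("compute_flows: empty subset for year %s", year)
        out = base.assign(year=year, in_count=0.0, out_count=0.0, net_count=0.0)
        return out[SERIES_COLUMNS]

    moved = sub[sub.division_previous.notna()]
    moved = moved[moved.division_previous != moved.division_current]
    ins = (
        moved.groupby(["division_current", "age"])["person_weight"]
        .sum()
        .rename("in_count")
    )
    outs = (
        moved.groupby(["division_previous", "age"])["person_weight"]
        .sum()
        .rename("out_count")
    )
    out = base.set_index(["division", "age"])
    out["in_count"] = ins.reindex(out.index, fill_value=0.0)
    out["out_count"] = outs.reindex(out.index, fill_value=0.0)
    out["net_count"] = out.in_count - out.out_count
    out = out.reset_index()
    out["year"] = year
    return out[SERIES_COLUMNS]


def validate_partition_map(pmap: pd.DataFrame) -> None:
    need = {"old_division", "new_division", "share"}
    if not need <= set(pmap.columns):
        raise ValidationError(f"partition map needs columns {sorted(need)}")
    if ((pmap.share < 0) | (pmap.share > 1)).any():
        raise ValidationError("partition map shares must lie in [0, 1]")
    sums = pmap.groupby("old_division")["share"].sum()
    bad = sums[(sums - 1.0).abs() > 1e-9]
    if len(bad):
        raise ValidationError(
            f"partition map shares must sum to 1 per old division; bad: "
            f"{bad.index.tolist()}"
        )


def harmonize(series: pd.DataFrame, pmap: pd.DataFrame) -> pd.DataFrame:
    """Proportionately partition counts from historical divisions onto the
    current register; grand totals are conserved exactly."""
    validate_partition_map(pmap)
    mapped = set(pmap.old_division.unique())
    present = set(series.division.unique())
    unmapped = present - mapped
    if unmapped:
        raise RegistryError(f"divisions missing from partition map: {sorted(unmapped)}")
    merged = series.merge(pmap, left_on="division", right_on="old_division")
    for col in ("in_count", "out_count", "net_count"):
        if col in merged.columns:
            merged[col] = merged[col] * merged["share"]
    merged["division"] = merged["new_division"]
    value_cols = [c for c in ("in_count", "out_count", "net_count") if c in series.columns]
    out = (
        merged.groupby(["division", "age", "year"], as_index=False)[value_cols].sum()
    )
    return out[["division", "age", "year", *value_cols]]


def age_proportions(series: pd.DataFrame) -> pd.DataFrame:
    """X1: each age's share of the division-year total net migration.

    Where the division-year total is zero the proportion is undefined; those
    cells are set to 0 and flagged (column ``x1_defined``), keeping the
    covariate usable without inventing a direction of flow.  Proportions may
    legitimately fall outside [0, 1] when age-specific nets have mixed signs.
    """
    out = series.copy()
    totals = out.groupby(["division", "year"])["net_count"].transform("sum")
    defined = np.abs(totals) > 1e-12
    x1 = np.zeros(len(out))
    x1[defined.to_numpy()] = (
        out.net_count[defined] / totals[defined]
    ).to_numpy()
    out["x1"] = x1
    out["x1_defined"] = defined.to_numpy()
    n_undef = (~defined).sum()
    if n_undef:
        log.warning(
            "age_proportions: %d cells in division-years with zero total net "
            "migration; X1 set to 0 there",
            int(n_undef),
        )
    return out


def fit_netmigration_model(
    series: pd.DataFrame,
    register: AdminRegister,
    mcmc: McmcSettings = DEFAULT_MIGRATION_MCMC,
    priors: PriorSettings = PriorSettings(),
    projection_years=(2000, 2030),
) -> PosteriorDraws:
    """Hierarchical time-series model for net-migration age proportions.

    X1(a,d,t) = intercept + region effect + division-within-region effect
    + age-within-division effect + division random walk over calendar years
    + noise, all Gaussian with half-normal scale hyperpriors.  Posterior
    trajectories are extrapolated through the projection years by
    propagating the random walk, giving ``x1_pred`` draws on the full
    (age, division, year) grid.
    """
    obs = series.dropna(subset=["x1"]).copy()
    obs_years = np.sort(obs.year.unique())
    if len(obs_years) < 2:
        raise ValidationError("need X1 observations at >= 2 time points")
    divisions = register.divisions
    regions = register.regions
    ages = np.sort(obs.age.unique())

    year_min = int(obs_years[0])
    year_last_obs = int(obs_years[-1])
    year_max = max(int(projection_years[1]), year_last_obs)
    rw_years = np.arange(year_min + 1, year_last_obs + 1)  # fitted increments

    div_idx = {d: i for i, d in enumerate(divisions)}
    reg_idx = {r: i for i, r in enumerate(regions)}
    dcode = obs.division.map(div_idx).to_numpy()
    rcode = obs.division.map(register.region_of).map(reg_idx).to_numpy()
    ad_levels = [(a, d) for d in divisions for a in ages]
    ad_idx = {k: i for i, k in enumerate(ad_levels)}
    adcode = np.array([ad_idx[(a, d)] for a, d in zip(obs.age, obs.division)])

    # random-walk design: column (d, s) is 1 for rows in d with year >= s
    Z = np.zeros((len(obs), len(divisions) * len(rw_years)))
    yrs = obs.year.to_numpy()
    for di in range(len(divisions)):
        for si, s in enumerate(rw_years):
            Z[(dcode == di) & (yrs >= s), di * len(rw_years) + si] = 1.0

    model = GaussianLMM(
        y=obs.x1.to_numpy(dtype=float),
        X=np.ones((len(obs), 1)),
        fixed_names=["intercept"],
        effects=[
            GroupEffect("region", rcode, len(regions), priors.scale_sd, regions),
            GroupEffect("division", dcode, len(divisions), priors.scale_sd, divisions),
            GroupEffect("age_div", adcode, len(ad_levels), priors.scale_sd, ad_levels),
            DenseEffect("rw", Z, priors.scale_sd),
        ],
        beta_prior_sd=priors.beta_sd,
        sigma_prior_sd=priors.sigma_sd,
    )
    draws = model.sample(mcmc.n_draws, mcmc.burn_in, mcmc.n_chains, mcmc.seed)

    # --- posterior X1 surface on the full grid, with RW extrapolation
    rng = np.random.default_rng(np.random.SeedSequence([mcmc.seed, 2**20]))
    C, K = draws.n_chains, draws.n_kept
    beta = draws.params["beta"][:, :, 0]
    u_reg = draws.params["u_region"]
    u_div = draws.params["u_division"]
    u_ad = draws.params["u_age_div"]
    u_rw = draws.params["u_rw"].reshape(C, K, len(divisions), len(rw_years))
    tau_rw = draws.params["tau_rw"]

    rw_level = np.concatenate(
        [np.zeros((C, K, len(divisions), 1)), np.cumsum(u_rw, axis=3)], axis=3
    )  # level at year_min .. year_last_obs
    n_future = year_max - year_last_obs
    if n_future > 0:
        steps = rng.standard_normal((C, K, len(divisions), n_future)) * tau_rw[
            :, :, None, None
        ]
        future = rw_level[:, :, :, -1:] + np.cumsum(steps, axis=3)
        rw_level = np.concatenate([rw_level, future], axis=3)

    # store predictions only for years downstream stages consume
    sel_years = sorted(
        set(int(y) for y in obs_years)
        | set(range(int(projection_years[0]), int(projection_years[1]) + 1))
    )
    cells = pd.MultiIndex.from_product(
        [ages, divisions, sel_years], names=["age", "division", "year"]
    )
    pred = np.empty((C, K, len(cells)), dtype=np.float32)
    for j, (a, d, t) in enumerate(cells):
        di = div_idx[d]
        ri = reg_idx[register.region_of(d)]
        adi = ad_idx[(a, d)]
        pred[:, :, j] = (
            beta
            + u_reg[:, :, ri]
            + u_div[:, :, di]
            + u_ad[:, :, adi]
            + rw_level[:, :, di, t - year_min]
        )
    draws.params["x1_pred"] = pred
    draws.coords["x1_pred"] = list(cells)
    return draws


def x1_prediction_frame(draws: PosteriorDraws) -> pd.DataFrame:
    """Posterior median and 95% CrI of X1 per (age, division, year)."""
    cells = draws.coords["x1_pred"]
    stacked = draws.stacked("x1_pred")
    med = np.median(stacked, axis=0)
    lo, hi = np.quantile(stacked, [0.025, 0.975], axis=0)
    out = pd.DataFrame(cells, columns=["age", "division", "year"])
    out["x1_median"] = med
    out["x1_lo"] = lo
    out["x1_hi"] = hi
    return out
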