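"""Age-specific fertility rates from retrospective birth histories.

Each woman's birth history (interview date, her own birth date, children's
birth dates, all CMC-encoded) is unrolled into month-level exposure by
single age and calendar cell; births are allocated to the cell containing
their CMC.  Rates are person-weighted, with the all-women factor applied
multiplicatively to both numerator and denominator so that rates computed on
the surveyed women represent all women of reproductive age.  A Bayesian
hierarchical model then smooths log-ASFR with a random walk over single
ages, exchangeable region intercepts, and a region-level random walk over
calendar time, interpolating and extrapolating to every year the population
model needs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import (
    McmcSettings,
    PriorSettings,
    ValidationError,
    DEFAULT_FERTILITY_MCMC,
)
from .gibbs import DenseEffect, GaussianLMM, GroupEffect, PosteriorDraws
from .synthetic import cmc, cmc_year

ASFR_COLUMNS = ["age", "region", "year", "births", "exposure", "asfr", "defined"]


def _validate_histories(h: pd.DataFrame) -> None:
    if (h.interview_cmc <= h.woman_birth_cmc).any():
        raise ValidationError("interview_cmc must exceed woman_birth_cmc")
    if (h.weight <= 0).any() or (h.all_women_factor <= 0).any():
        raise ValidationError("weights and all-women factors must be positive")
    for row in h.itertuples(index=False):
        if any(b > row.interview_cmc for b in row.child_birth_cmcs):
            raise ValidationError(
                f"woman {row.woman_id}: child birth after interview"
            )


def compute_asfr(
    histories: pd.DataFrame,
    window: tuple[int, int],
    age_range: tuple[int, int] = (15, 49),
    period_length: int = 1,
) -> pd.DataFrame:
    """Empirical ASFR surface by (single age, region, calendar cell).

    Exposure is counted in exact months: each month between a woman's 15th
    birthday (clipped to the window and the age range) and the month before
    interview contributes weight x all_women_factor / 12 woman-years to the
    (age, year) cell it falls in.  ``period_length`` > 1 pools calendar
    years into periods labelled by their midpoint year.  Cells with zero
    exposure are flagged undefined rather than set to 0.
    """
    _validate_histories(histories)
    y0, y1 = window
    a_lo, a_hi = age_range
    regions = sorted(histories.region.unique())
    ridx = {r: i for i, r in enumerate(regions)}

    n_ages = a_hi - a_lo + 1
    years = np.arange(y0, y1 + 1)
    n_years = len(years)
    exposure = np.zeros((n_ages, len(regions), n_years))
    births = np.zeros_like(exposure)

    iv = histories.interview_cmc.to_numpy()
    wb = histories.woman_birth_cmc.to_numpy()
    w = (histories.weight * histories.all_women_factor).to_numpy(dtype=float)
    rcode = histories.region.map(ridx).to_numpy()

    start = np.maximum(wb + a_lo * 12, cmc(y0, 1))
    stop = np.minimum.reduce([iv - 1, wb + (a_hi + 1) * 12 - 1, np.full_like(iv, cmc(y1, 12))])
    n_months = np.maximum(stop - start + 1, 0)
    keep = n_months > 0
    if keep.any():
        # flatten all woman-months: month = start_i + offset
        reps = n_months[keep]
        base = np.repeat(start[keep], reps)
        offs = np.concatenate([np.arange(k) for k in reps])
        months = base + offs
        wb_rep = np.repeat(wb[keep], reps)
        w_rep = np.repeat(w[keep], reps)
        r_rep = np.repeat(rcode[keep], reps)
        age_m = (months - wb_rep) // 12
        yr_m = cmc_year(months)
        ok = (age_m >= a_lo) & (age_m <= a_hi) & (yr_m >= y0) & (yr_m <= y1)
        np.add.at(
            exposure,
            (age_m[ok] - a_lo, r_rep[ok], yr_m[ok] - y0),
            w_rep[ok] / 12.0,
        )

    kids = histories[["woman_id", "region", "woman_birth_cmc", "child_birth_cmcs"]].copy()
    kids["w"] = w
    kids = kids.explode("child_birth_cmcs").dropna(subset=["child_birth_cmcs"])
    if len(kids):
        bc = kids.child_birth_cmcs.to_numpy(dtype=int)
        mage = (bc - kids.woman_birth_cmc.to_numpy()) // 12
        byr = cmc_year(bc)
        ok = (mage >= a_lo) & (mage <= a_hi) & (byr >= y0) & (byr <= y1)
        np.add.at(
            births,
            (mage[ok] - a_lo, kids.region.map(ridx).to_numpy()[ok], byr[ok] - y0),
            kids.w.to_numpy()[ok],
        )

    if period_length > 1:
        n_per = int(np.ceil(n_years / period_length))
        exp_p = np.zeros((n_ages, len(regions), n_per))
        bir_p = np.zeros_like(exp_p)
        labels = []
        for p in range(n_per):
            sl = slice(p * period_length, min((p + 1) * period_length, n_years))
            exp_p[:, :, p] = exposure[:, :, sl].sum(axis=2)
            bir_p[:, :, p] = births[:, :, sl].sum(axis=2)
            labels.append(int(np.mean(years[sl])))
        exposure, births, yr_labels = exp_p, bir_p, labels
    else:
        yr_labels = list(years)

    idx = pd.MultiIndex.from_product(
        [np.arange(a_lo, a_hi + 1), regions, yr_labels],
        names=["age", "region", "year"],
    )
    out = pd.DataFrame(index=idx).reset_index()
    out["births"] = births.ravel()
    out["exposure"] = exposure.ravel()
    defined = out.exposure > 0
    out["asfr"] = np.where(defined, out.births / np.where(defined, out.exposure, 1.0), np.nan)
    out["defined"] = defined
    return out[ASFR_COLUMNS]


def total_fertility_rate(surface: pd.DataFrame) -> pd.Series:
    """TFR per (region, year): sum of single-age ASFR over 15-49."""
    return surface.groupby(["region", "year"])["asfr"].sum(min_count=1)


def fit_asfr_model(
    surface: pd.DataFrame,
    mcmc: McmcSettings = DEFAULT_FERTILITY_MCMC,
    priors: PriorSettings = PriorSettings(),
    projection_years=(1976, 2030),
) -> PosteriorDraws:
    """Hierarchical log-ASFR model with posterior rate surfaces.

    log asfr(a,r,t) = intercept + age random walk + region intercept
    + region-level random walk over calendar years + noise.  Cells with zero
    exposure or zero births carry no likelihood contribution (the log link
    requires a positive empirical rate); with no data at all the posterior
    reproduces the prior, whose median rate is exp(asfr_log_mean).
    Posterior ``asfr_pred`` draws (positive by construction) cover every
    (age, region, year) in the prediction grid.
    """
    obs = surface[(surface.exposure > 0) & (surface.births > 0)].copy()
    regions = sorted(surface.region.unique())
    ages = np.sort(surface.age.unique())
    a_lo, a_hi = int(ages.min()), int(ages.max())
    y_lo, y_hi = int(projection_years[0]), int(projection_years[1])

    if len(obs):
        obs_years = np.sort(obs.year.unique())
        year_min = min(int(obs_years[0]), y_lo)
        year_last = int(obs_years[-1])
    else:
        year_min, year_last = y_lo, y_lo + 1
    year_last = max(year_last, year_min + 1)

    rw_years = np.arange(year_min + 1, year_last + 1)
    age_steps = np.arange(a_lo + 1, a_hi + 1)
    ridx = {r: i for i, r in enumerate(regions)}

    n = len(obs)
    y = np.log(obs.asfr.to_numpy(dtype=float)) if n else np.zeros(0)
    Za = np.zeros((n, len(age_steps)))
    Zt = np.zeros((n, len(regions) * len(rw_years)))
    if n:
        av = obs.age.to_numpy()
        tv = obs.year.to_numpy()
        rv = obs.region.map(ridx).to_numpy()
        for si, s in enumerate(age_steps):
            Za[av >= s, si] = 1.0
        for ri in range(len(regions)):
            for si, s in enumerate(rw_years):
                Zt[(rv == ri) & (tv >= s), ri * len(rw_years) + si] = 1.0
        rcode = rv
    else:
        rcode = np.zeros(0, dtype=int)

    model = GaussianLMM(
        y=y if n else np.zeros(1),
        X=np.ones((max(n, 1), 1)),
        fixed_names=["intercept"],
        effects=[
            GroupEffect("region", rcode if n else np.zeros(1, dtype=int),
                        len(regions), priors.scale_sd, regions),
            DenseEffect("age_rw", Za if n else np.zeros((1, len(age_steps))),
                        priors.scale_sd),
            DenseEffect("time_rw", Zt if n else np.zeros((1, len(regions) * len(rw_years))),
                        priors.scale_sd),
        ],
        beta_prior_mean=priors.asfr_log_mean,
        beta_prior_sd=priors.asfr_log_sd,
        sigma_prior_sd=priors.sigma_sd,
        likelihood=n > 0,
    )
    draws = model.sample(mcmc.n_draws, mcmc.burn_in, mcmc.n_chains, mcmc.seed)

    rng = np.random.default_rng(np.random.SeedSequence([mcmc.seed, 2**21]))
    C, K = draws.n_chains, draws.n_kept
    beta = draws.params["beta"][:, :, 0]
    u_reg = draws.params["u_region"]
    u_age = draws.params["u_age_rw"]
    u_time = draws.params["u_time_rw"].reshape(C, K, len(regions), len(rw_years))
    tau_t = draws.params["tau_time_rw"]

    age_level = np.concatenate(
        [np.zeros((C, K, 1)), np.cumsum(u_age, axis=2)], axis=2
    )  # per age a_lo..a_hi
    time_level = np.concatenate(
        [np.zeros((C, K, len(regions), 1)), np.cumsum(u_time, axis=3)], axis=3
    )  # per year year_min..year_last
    if y_hi > year_last:
        steps = rng.standard_normal((C, K, len(regions), y_hi - year_last)) * tau_t[
            :, :, None, None
        ]
        future = time_level[:, :, :, -1:] + np.cumsum(steps, axis=3)
        time_level = np.concatenate([time_level, future], axis=3)

    pred_years = np.arange(y_lo, y_hi + 1)
    cells = pd.MultiIndex.from_product(
        [list(ages), regions, list(pred_years)], names=["age", "region", "year"]
    )
    pred = np.empty((C, K, len(cells)), dtype=np.float32)
    for j, (a, r, t) in enumerate(cells):
        ri = ridx[r]
        lp = (
            beta
            + u_reg[:, :, ri]
            + age_level[:, :, a - a_lo]
            + time_level[:, :, ri, t - year_min]
        )
        pred[:, :, j] = np.exp(lp)
    draws.params["asfr_pred"] = pred
    draws.coords["asfr_pred"] = list(cells)
    return draws


def asfr_prediction_frame(draws: PosteriorDraws) -> pd.DataFrame:
    """Posterior median and 95% CrI of ASFR per (age, region, year)."""
    cells = draws.coords["asfr_pred"]
    stacked = draws.stacked("asfr_pred")
    out = pd.DataFrame(cells, columns=["age", "region", "year"])
    out["asfr_median"] = np.median(stacked, axis=0)
    lo, hi = np.quantile(stacked, [0.025, 0.975], axis=0)
    out["asfr_lo"] = lo
    out["asfr_hi"] = hi
    return out
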