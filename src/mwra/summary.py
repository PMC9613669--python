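"""Posterior summaries, convergence diagnostics, and sensitivity analyses.

Turns labelled posterior draws into the published quantities: per-unit
count medians with 95% credible intervals (2.5th/97.5th percentiles,
type-7 linear-interpolation percentile rule), annual rates of change, the
Gelman-Rubin split-R-hat statistic, posterior-predictive p-values, and the
two sensitivity exercises (predictor exclusion and hyperprior rescaling).

Unit-year point estimates follow the sum-of-medians convention (the sum
over ages 15-49 of per-age posterior medians); intervals are percentiles of
the per-draw age-summed totals.  The alternative median-of-sums point
estimate is reported alongside.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .config import AdminRegister, PriorSettings, ValidationError
from .gibbs import PosteriorDraws


# ---------------------------------------------------------------- summaries

def _unit_groups(cells: list, register: AdminRegister):
    """Map each draw cell (age, division, region, year) to the units that
    aggregate it: its division, its region, and the national total."""
    df = pd.DataFrame(cells, columns=["age", "division", "region", "year"])
    groups = []
    for (d, y), idx in df.groupby(["division", "year"]).groups.items():
        groups.append(("division", d, y, np.asarray(idx)))
    for (r, y), idx in df.groupby(["region", "year"]).groups.items():
        groups.append(("region", r, y, np.asarray(idx)))
    for y, idx in df.groupby("year").groups.items():
        groups.append(("national", "National", y, np.asarray(idx)))
    return groups


def summarize(
    draws: PosteriorDraws,
    register: AdminRegister,
    param: str = "pop_pred",
) -> pd.DataFrame:
    """Projection table: unit-year count medians and 95% CrIs.

    ``count_median`` sums per-age posterior medians over ages 15-49
    (sum-of-medians); ``count_median_of_sums`` is the median of per-draw
    age-summed totals; CrIs are the 2.5th/97.5th percentiles of those
    per-draw totals.
    """
    if param not in draws.coords:
        raise ValidationError(f"draws lack labels for {param!r}")
    cells = draws.coords[param]
    stacked = draws.stacked(param).astype(float)  # (S, n_cells)
    cell_medians = np.median(stacked, axis=0)
    rows = []
    for level, unit, year, idx in _unit_groups(cells, register):
        totals = stacked[:, idx].sum(axis=1)
        lo, hi = np.percentile(totals, [2.5, 97.5])
        rows.append(
            {
                "level": level,
                "unit": unit,
                "year": year,
                "count_median": float(cell_medians[idx].sum()),
                "count_median_of_sums": float(np.median(totals)),
                "cri_low": float(lo),
                "cri_high": float(hi),
            }
        )
    out = pd.DataFrame(rows).sort_values(["level", "unit", "year"]).reset_index(drop=True)
    return out


def unit_total_draws(
    draws: PosteriorDraws, register: AdminRegister, param: str = "pop_pred"
) -> dict[tuple[str, str, int], np.ndarray]:
    """Per-draw age-summed totals keyed by (level, unit, year)."""
    cells = draws.coords[param]
    stacked = draws.stacked(param).astype(float)
    return {
        (level, unit, year): stacked[:, idx].sum(axis=1)
        for level, unit, year, idx in _unit_groups(cells, register)
    }


# ------------------------------------------------------------- annual rates

def annual_rate_point(p1: float, p2: float, t1: int, t2: int) -> float:
    """Annual rate of change in percentage points per annum:
    100 * (P_t2 - P_t1) / (P_t1 * (t2 - t1))."""
    if p1 <= 0:
        raise ValidationError("annual rate undefined: starting population <= 0")
    if t2 <= t1:
        raise ValidationError("annual rate needs t2 > t1")
    return 100.0 * (p2 - p1) / (p1 * (t2 - t1))


def annual_rate(
    totals: dict[tuple[str, str, int], np.ndarray],
    period: tuple[int, int],
) -> pd.DataFrame:
    """Median and 95% CrI of per-draw annual rates of change over ``period``
    for every unit with draws at both endpoint years."""
    t1, t2 = period
    rows = []
    units = sorted({(lvl, u) for (lvl, u, y) in totals})
    for lvl, u in units:
        if (lvl, u, t1) not in totals or (lvl, u, t2) not in totals:
            continue
        p1 = totals[(lvl, u, t1)]
        p2 = totals[(lvl, u, t2)]
        ok = p1 > 0
        if not ok.all():
            if not ok.any():
                continue
            p1, p2 = p1[ok], p2[ok]
        rates = 100.0 * (p2 - p1) / (p1 * (t2 - t1))
        lo, hi = np.percentile(rates, [2.5, 97.5])
        rows.append(
            {
                "level": lvl,
                "unit": u,
                "period": f"{t1}-{t2}",
                "rate_median": float(np.median(rates)),
                "rate_cri_low": float(lo),
                "rate_cri_high": float(hi),
                "n_draws_skipped": int((~ok).sum()),
            }
        )
    return pd.DataFrame(rows)


# -------------------------------------------------------------- diagnostics

def gelman_rubin(chains: np.ndarray) -> float:
    """Split-R-hat: each chain is halved, then the classic between/within
    variance ratio is computed over the resulting half-chains."""
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2:
        raise ValidationError("gelman_rubin expects a (n_chains, n_draws) array")
    m, n = chains.shape
    if m < 2:
        raise ValidationError("gelman_rubin needs >= 2 chains")
    if np.all(chains == chains[0]):
        return 1.0  # identical chains: between-chain variance is exactly 0
    half = n // 2
    if half < 2:
        raise ValidationError("chains too short to split")
    splits = np.concatenate([chains[:, :half], chains[:, half : 2 * half]], axis=0)
    means = splits.mean(axis=1)
    variances = splits.var(axis=1, ddof=1)
    W = variances.mean()
    B = half * means.var(ddof=1)
    if W == 0 or B == 0:  # identical chains: no between-chain variance
        return 1.0
    var_hat = (half - 1) / half * W + B / half
    return float(np.sqrt(var_hat / W))


def effective_sample_size(chains: np.ndarray) -> float:
    """Bulk effective sample size (via arviz)."""
    import arviz as az

    return float(az.ess(np.asarray(chains, dtype=float)))


def diagnostics_report(draws: PosteriorDraws, params: list[str] | None = None) -> pd.DataFrame:
    """R-hat and ESS per scalar parameter (vector parameters elementwise)."""
    rows = []
    params = params or [
        p for p, a in draws.params.items() if a.ndim == 2 or a.shape[-1] <= 50
    ]
    for p in params:
        a = draws.params[p]
        if a.ndim == 2:
            rows.append({"parameter": p, "rhat": gelman_rubin(a),
                         "ess": effective_sample_size(a)})
        else:
            labels = draws.coords.get(p, range(a.shape[2]))
            for j, lab in enumerate(labels):
                rows.append({"parameter": f"{p}[{lab}]",
                             "rhat": gelman_rubin(a[:, :, j]),
                             "ess": effective_sample_size(a[:, :, j])})
    return pd.DataFrame(rows)


def ppp(
    frame: pd.DataFrame,
    draws: PosteriorDraws,
    seed: int = 0,
    zero_count_offset: float = 0.5,
) -> pd.DataFrame:
    """Posterior-predictive p-values for replicated log-count statistics.

    Per posterior draw, a replicated dataset is simulated from the fitted
    observation model Normal(log eta*, sigma^2); the PPP for a statistic is
    the fraction of draws whose replicated value is >= the observed one.
    Default statistics: mean and SD of cell log counts, and the largest
    absolute residual from the draw's own linear predictor.  Values below
    0.05 or above 0.95 indicate misfit.
    """
    y = frame["count"].to_numpy(dtype=float)
    y = np.where(y > 0, y, y + zero_count_offset)
    logy = np.log(y)
    mu = draws.stacked("log_eta_star").astype(float)  # (S, n)
    sigma = draws.stacked("sigma")[:, None]
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2**23]))
    yrep = mu + rng.standard_normal(mu.shape) * sigma

    stats = {
        "mean_log_count": (yrep.mean(axis=1), logy.mean()),
        "sd_log_count": (yrep.std(axis=1, ddof=1), logy.std(ddof=1)),
    }
    rows = []
    for name, (rep, obs) in stats.items():
        rows.append({"statistic": name, "ppp": float(np.mean(rep >= obs)),
                     "n_draws": rep.shape[0], "n_skipped": 0})
    # max absolute residual: observed side depends on each draw's mu
    rep_stat = np.abs(yrep - mu).max(axis=1)
    obs_stat = np.abs(logy[None, :] - mu).max(axis=1)
    rows.append(
        {
            "statistic": "max_abs_residual",
            "ppp": float(np.mean(rep_stat >= obs_stat)),
            "n_draws": mu.shape[0],
            "n_skipped": 0,
        }
    )
    return pd.DataFrame(rows)


# -------------------------------------------------------------- sensitivity

def sensitivity(
    frame: pd.DataFrame,
    register: AdminRegister,
    spec=None,
    prior_scale_factors: tuple[float, ...] = (10.0,),
    runs: tuple[str, ...] = ("baseline", "drop_x1", "drop_x2x3", "drop_all", "priors"),
) -> pd.DataFrame:
    """Refit under predictor exclusion and rescaled hyperpriors; report the
    median absolute and percentage differences in division-year fitted
    totals against the baseline run."""
    from . import population

    spec = spec or population.PopulationModelSpec()

    def totals_for(s) -> pd.Series:
        d = population.fit(frame, s)
        # log_eta_star draws: exponentiate per draw before aggregating
        cells = d.coords["log_eta_star"]
        stacked = np.exp(d.stacked("log_eta_star").astype(float))
        med = np.median(stacked, axis=0)
        df = pd.DataFrame(cells, columns=["age", "division", "region", "year"])
        df["m"] = med
        return df.groupby(["division", "year"])["m"].sum()

    base = totals_for(spec)
    rows = []
    variants: list[tuple[str, object]] = []
    import dataclasses

    for run in runs:
        if run == "baseline":
            variants.append(("baseline", spec))
        elif run == "drop_x1":
            variants.append(("drop_x1", dataclasses.replace(spec, include_x1=False)))
        elif run == "drop_x2x3":
            variants.append(("drop_x2x3", dataclasses.replace(spec, include_x2x3=False)))
        elif run == "drop_all":
            variants.append(
                ("drop_all", dataclasses.replace(spec, include_x1=False, include_x2x3=False))
            )
        elif run == "priors":
            for f in prior_scale_factors:
                variants.append(
                    (f"priors_x{f:g}", dataclasses.replace(spec, priors=spec.priors.scaled(f)))
                )
        else:
            raise ValidationError(f"unknown sensitivity run: {run!r}")

    for name, s in variants:
        alt = totals_for(s)
        diff = (alt - base).abs()
        pct = 100.0 * diff / base
        rows.append(
            {
                "run": name,
                "median_abs_diff": float(diff.median()),
                "median_pct_diff": float(pct.median()),
            }
        )
    return pd.DataFrame(rows)


# ------------------------------------------------- published reference table

def load_reference_estimates() -> pd.DataFrame:
    """Published regional/divisional MWRA median estimates for Cameroon,
    2000-2030, used for summary-arithmetic verification."""
    with resources.files("mwra.data").joinpath("cameroon_regional_mwra.csv").open() as f:
        return pd.read_csv(f)


def concentration_share(ref: pd.DataFrame, units: list[str], year: int) -> float:
    """Share (%) of the national median held by ``units`` in ``year``."""
    sel = ref[(ref.year == year) & ref.unit.isin(units)]
    nat = ref[(ref.year == year) & (ref.level == "national")]["median"].iloc[0]
    return float(100.0 * sel["median"].sum() / nat)


def division_share(ref: pd.DataFrame, division: str, year: int) -> float:
    """Division's share (%) of its region's median total in ``year``."""
    row = ref[(ref.unit == division) & (ref.year == year)].iloc[0]
    region_total = ref[(ref.unit == row.parent) & (ref.year == year)]["median"].iloc[0]
    return float(100.0 * row["median"] / region_total)
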