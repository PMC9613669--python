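"""Hierarchical log-linear population model and two-step projections.

Step one regresses observed log MWRA counts at the census years on the
demographic drivers,

    log eta(a,d,r,t) ~ Normal(log eta*(a,d,r,t), sigma^2)
    log eta* = b0 + b1 * X1 + b2 * X2 * X3 + u1(a,d,t) + u2(d,r,t)

with X1 the net-migration age proportion, X2 the age-specific fertility
rate, X3 the single-age survival probability (fertility and survival enter
as an interaction), u1/u2 exchangeable zero-mean normal varying effects over
their index sets, normal priors on the coefficients and half-normal priors
on all scales.  Step two predicts out-of-sample populations for 2000-2030 by
evaluating the linear predictor at covariate values supplied by the driver
models' own posteriors (paired draw-wise), drawing fresh varying effects and
residuals for unseen times.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import (
    AdminRegister,
    CoverageError,
    McmcSettings,
    PriorSettings,
    ValidationError,
    DEFAULT_POPULATION_MCMC,
)
from .gibbs import GaussianLMM, GroupEffect, PosteriorDraws

log = logging.getLogger(__name__)

FRAME_COLUMNS = ["age", "division", "region", "year", "count", "x1", "x2", "x3"]


@dataclass
class PopulationModelSpec:
    """Priors, MCMC sizes, and degenerate-data handling for the fit."""

    priors: PriorSettings = field(default_factory=PriorSettings)
    mcmc: McmcSettings = field(default_factory=lambda: DEFAULT_POPULATION_MCMC)
    zero_count_offset: float = 0.5  # persons added before logging zero counts
    include_x1: bool = True
    include_x2x3: bool = True


def census_mwra_counts(records: pd.DataFrame, register: AdminRegister) -> pd.DataFrame:
    """Person-weighted MWRA counts per (age, division, census year)."""
    from .migration import mwra_filter

    sub = mwra_filter(records)
    for div in sub.division_current.unique():
        register.check_division(div)
    counts = (
        sub.groupby(["age", "division_current", "census_year"])["person_weight"]
        .sum()
        .rename("count")
        .reset_index()
        .rename(columns={"division_current": "division", "census_year": "year"})
    )
    return counts


def covariate_correlations(frame: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlations between the covariates (including the fertility x
    survival interaction); constant columns yield NaN and are flagged."""
    cols = {
        "x1": frame.x1,
        "x2": frame.x2,
        "x3": frame.x3,
        "x2*x3": frame.x2 * frame.x3,
    }
    mat = pd.DataFrame(cols)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = mat.corr()
    for name, col in cols.items():
        if np.isclose(col.std(), 0.0):
            log.warning("covariate %s is constant; correlations undefined", name)
    return corr


def build_frame(
    census_counts: pd.DataFrame,
    migration_series: pd.DataFrame,
    asfr_surface: pd.DataFrame,
    survival_surface: pd.DataFrame,
    register: AdminRegister,
) -> pd.DataFrame:
    """Join observed counts with the three covariate sources into a model
    frame; region-level ASFR broadcasts to its divisions and national
    survival broadcasts to every unit.  Raises CoverageError naming missing
    cells if any covariate fails to cover the frame's index set."""
    frame = census_counts.copy()
    frame["region"] = frame.division.map(register.region_of)

    mig = migration_series.rename(columns={"x1": "_x1"})[
        ["division", "age", "year", "_x1"]
    ]
    frame = frame.merge(mig, on=["division", "age", "year"], how="left")

    asfr = asfr_surface.rename(
        columns={"asfr": "_x2", "asfr_median": "_x2", "x2": "_x2"}
    )
    keep = [c for c in ("age", "region", "year", "_x2") if c in asfr.columns]
    frame = frame.merge(asfr[keep].drop_duplicates(["age", "region", "year"]),
                        on=["age", "region", "year"], how="left")

    surv = survival_surface.rename(columns={"px1": "_x3", "x3": "_x3"})
    frame = frame.merge(
        surv[["age", "year", "_x3"]].drop_duplicates(["age", "year"]),
        on=["age", "year"], how="left",
    )

    for src, col in (("migration", "_x1"), ("asfr", "_x2"), ("survival", "_x3")):
        missing = frame[frame[col].isna()]
        if len(missing):
            cells = missing[["age", "division", "year"]].head(20).to_dict("records")
            raise CoverageError(
                f"{src} covariate missing for {len(missing)} cells, e.g. {cells}"
            )
    frame = frame.rename(columns={"_x1": "x1", "_x2": "x2", "_x3": "x3"})
    if not np.isfinite(frame[["x1", "x2", "x3"]].to_numpy()).all():
        raise ValidationError("covariates must be finite")
    corr = covariate_correlations(frame)
    log.info("covariate correlations:\n%s", corr.round(3))
    frame.attrs["covariate_correlations"] = corr
    return frame[FRAME_COLUMNS]


def _cell_labels(frame: pd.DataFrame):
    u1 = list(zip(frame.age, frame.division, frame.year))
    u2 = list(zip(frame.division, frame.year))
    return u1, u2


def fit(frame: pd.DataFrame, spec: PopulationModelSpec | None = None) -> PosteriorDraws:
    """Sample the posterior of the population model given census observations.

    Returns draws for the coefficients, varying effects, and scales, plus
    per-cell ``log_eta_star`` draws for the fitted cells.  Non-convergence
    (split R-hat >= 1.1) is flagged on the result, not raised.
    """
    spec = spec or PopulationModelSpec()
    if len(frame) < 2:
        raise ValidationError("degenerate frame: need more than one cell")
    if frame.year.nunique() < 2:
        raise ValidationError("need observations at >= 2 census time points")
    y = frame["count"].to_numpy(dtype=float)
    if (y < 0).any():
        raise ValidationError("counts must be non-negative")
    nz = y <= 0
    if nz.any():
        log.warning("fit: %d zero counts offset by +%g before logging",
                    int(nz.sum()), spec.zero_count_offset)
        y = y + nz * spec.zero_count_offset
    logy = np.log(y)

    cols = [np.ones(len(frame))]
    names = ["beta0"]
    if spec.include_x1:
        cols.append(frame.x1.to_numpy(dtype=float))
        names.append("beta1")
    if spec.include_x2x3:
        cols.append((frame.x2 * frame.x3).to_numpy(dtype=float))
        names.append("beta2")
    X = np.column_stack(cols)

    u1_keys, u2_keys = _cell_labels(frame)
    u1_levels = sorted(set(u1_keys))
    u2_levels = sorted(set(u2_keys))
    u1_map = {k: i for i, k in enumerate(u1_levels)}
    u2_map = {k: i for i, k in enumerate(u2_levels)}
    c1 = np.array([u1_map[k] for k in u1_keys])
    c2 = np.array([u2_map[k] for k in u2_keys])

    model = GaussianLMM(
        y=logy,
        X=X,
        fixed_names=names,
        effects=[
            GroupEffect("u1", c1, len(u1_levels), spec.priors.scale_sd, u1_levels),
            GroupEffect("u2", c2, len(u2_levels), spec.priors.scale_sd, u2_levels),
        ],
        beta_prior_sd=spec.priors.beta_sd,
        sigma_prior_sd=spec.priors.sigma_sd,
    )
    draws = model.sample(spec.mcmc.n_draws, spec.mcmc.burn_in,
                         spec.mcmc.n_chains, spec.mcmc.seed)

    # fitted linear predictor per draw and cell (exact sum of components)
    beta = draws.params["beta"]
    lp = np.einsum("ckp,np->ckn", beta, X)
    lp += draws.params["u_u1"][:, :, c1]
    lp += draws.params["u_u2"][:, :, c2]
    draws.params["log_eta_star"] = lp.astype(np.float32)
    cells = list(zip(frame.age, frame.division, frame.region, frame.year))
    draws.coords["log_eta_star"] = cells
    draws.coords["fit_design"] = names
    draws.diagnostics["n_obs"] = len(frame)
    return draws


def project(
    draws: PosteriorDraws,
    future_frame: pd.DataFrame,
    x1_draws: np.ndarray | None = None,
    x2_draws: np.ndarray | None = None,
    include_random_effects: bool = True,
    include_residual: bool = True,
    seed: int = 0,
) -> PosteriorDraws:
    """Out-of-sample population predictions for the cells of ``future_frame``.

    ``future_frame`` must carry (age, division, region, year, x1, x2, x3);
    the x1/x2 point columns are overridden per-draw when ``x1_draws`` /
    ``x2_draws`` (total-draws x cells arrays from the driver models) are
    given, pairing covariate draws with parameter draws by draw index
    (recycled modulo length when counts differ).  Fresh u1 (per cell) and u2
    (per division-year) effects and residuals are drawn for unseen times
    unless switched off.  Returns draws with ``pop_pred`` counts per cell.
    """
    for col in ("age", "division", "region", "year", "x1", "x2", "x3"):
        if col not in future_frame.columns:
            raise CoverageError(f"future covariate column missing: {col}")
    if future_frame[["x1", "x2", "x3"]].isna().any().any():
        bad = future_frame[future_frame[["x1", "x2", "x3"]].isna().any(axis=1)]
        raise CoverageError(
            f"future covariates missing for {len(bad)} cells, e.g. "
            f"{bad[['age', 'division', 'year']].head(10).to_dict('records')}"
        )
    C, K = draws.n_chains, draws.n_kept
    S = C * K
    n_cells = len(future_frame)
    names = draws.coords["fit_design"]
    beta = draws.stacked("beta")  # (S, p)
    b = {name: beta[:, i] for i, name in enumerate(names)}

    x1 = future_frame.x1.to_numpy(dtype=float)[None, :]
    x2 = future_frame.x2.to_numpy(dtype=float)[None, :]
    x3 = future_frame.x3.to_numpy(dtype=float)[None, :]
    if x1_draws is not None:
        idx = np.arange(S) % x1_draws.shape[0]
        x1 = x1_draws[idx]
    if x2_draws is not None:
        idx = np.arange(S) % x2_draws.shape[0]
        x2 = x2_draws[idx]

    lp = np.broadcast_to(b["beta0"][:, None], (S, n_cells)).copy()
    if "beta1" in b:
        lp += b["beta1"][:, None] * x1
    if "beta2" in b:
        lp += b["beta2"][:, None] * (x2 * x3)

    rng = np.random.default_rng(np.random.SeedSequence([seed, 2**22]))
    if include_random_effects:
        tau1 = draws.stacked("tau_u1")
        tau2 = draws.stacked("tau_u2")
        # u2 is shared by all ages within a division-year
        dy = list(zip(future_frame.division, future_frame.year))
        dy_levels = sorted(set(dy))
        dy_code = np.array([dy_levels.index(k) for k in dy])
        u2_new = rng.standard_normal((S, len(dy_levels))) * tau2[:, None]
        lp += rng.standard_normal((S, n_cells)) * tau1[:, None]
        lp += u2_new[:, dy_code]
    if include_residual:
        sigma = draws.stacked("sigma")
        lp += rng.standard_normal((S, n_cells)) * sigma[:, None]

    pop = np.exp(lp).reshape(C, K, n_cells).astype(np.float32)
    cells = list(zip(future_frame.age, future_frame.division,
                     future_frame.region, future_frame.year))
    out = PosteriorDraws(
        params={"pop_pred": pop, "log_pop_pred": np.log(pop)},
        coords={"pop_pred": cells, "log_pop_pred": cells},
        diagnostics=dict(draws.diagnostics),
        warnings=list(draws.warnings),
    )
    return out
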