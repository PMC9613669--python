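"""Single-age, single-year survival probabilities from abridged life tables.

Abridged life tables give five-year survival probabilities 5px on five-year
age groups and five-year calendar periods.  The population model needs a
survival covariate (X3) on a single-age, single-year grid, obtained here by
bilinear interpolation: each 5px value is anchored at its age-group midpoint
(x + 2.5) and period midpoint, interpolated linearly along age within each
period, then linearly along calendar year, extrapolating linearly beyond the
outermost anchors.

The default mode interpolates the 5px values directly onto the single-age
grid (labelled px1 in the output).  ``mode="fifth-root"`` first converts
5px -> 5px**(1/5), the standard constant-hazard reduction of a five-year
probability to an annual one, before interpolating.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .config import ValidationError

log = logging.getLogger(__name__)

LIFETABLE_COLUMNS = ["period_start_year", "age_group_start", "px5"]
PERIOD_LENGTH = 5
AGE_GROUP_LENGTH = 5

_EPS = 1e-6


def _interp_extrap(x: np.ndarray, xp: np.ndarray, fp: np.ndarray) -> np.ndarray:
    """Piecewise-linear interpolation with linear extrapolation at both ends."""
    x = np.asarray(x, dtype=float)
    xp = np.asarray(xp, dtype=float)
    fp = np.asarray(fp, dtype=float)
    y = np.interp(x, xp, fp)
    lo = x < xp[0]
    if lo.any():
        slope = (fp[1] - fp[0]) / (xp[1] - xp[0])
        y[lo] = fp[0] + slope * (x[lo] - xp[0])
    hi = x > xp[-1]
    if hi.any():
        slope = (fp[-1] - fp[-2]) / (xp[-1] - xp[-2])
        y[hi] = fp[-1] + slope * (x[hi] - xp[-1])
    return y


def interpolate_survival(
    table: pd.DataFrame,
    ages: np.ndarray | None = None,
    years: np.ndarray | None = None,
    mode: str = "direct",
) -> pd.DataFrame:
    """Convert an abridged life table to a single-age, single-year surface.

    Parameters
    ----------
    table : DataFrame with columns (period_start_year, age_group_start, px5)
        on a complete (period x age-group) grid.
    ages, years : target single-age and single-year grids
        (defaults: 15..49 and 1976..2030).
    mode : "direct" interpolates 5px values as-is; "fifth-root" converts to
        annual probabilities 5px**(1/5) first.

    Returns
    -------
    DataFrame with columns (age, year, px1), one row per grid point.
    """
    if ages is None:
        ages = np.arange(15, 50)
    if years is None:
        years = np.arange(1976, 2031)
    ages = np.asarray(ages)
    years = np.asarray(years)
    if mode not in ("direct", "fifth-root"):
        raise ValidationError(f"unknown interpolation mode: {mode!r}")
    missing = [c for c in LIFETABLE_COLUMNS if c not in table.columns]
    if missing:
        raise ValidationError(f"life table missing columns: {missing}")
    vals = table["px5"].to_numpy(dtype=float)
    if np.any(~np.isfinite(vals)) or np.any(vals <= 0) or np.any(vals > 1):
        raise ValidationError("life table px5 values must lie in (0, 1]")

    grid = table.pivot_table(
        index="age_group_start", columns="period_start_year", values="px5"
    )
    if grid.isna().any().any():
        raise ValidationError("life table grid is incomplete (missing cells)")
    if grid.shape[0] < 2 or grid.shape[1] < 2:
        raise ValidationError("need at least two age groups and two periods")

    values = grid.to_numpy(dtype=float)
    if mode == "fifth-root":
        values = values ** (1.0 / AGE_GROUP_LENGTH)

    age_anchors = grid.index.to_numpy(dtype=float) + AGE_GROUP_LENGTH / 2.0
    year_anchors = grid.columns.to_numpy(dtype=float) + PERIOD_LENGTH / 2.0 - 0.5
    # 5-year period [t, t+4] has midpoint t+2

    # age pass: one column per period, evaluated on the single-age grid
    by_age = np.empty((len(ages), values.shape[1]))
    for j in range(values.shape[1]):
        by_age[:, j] = _interp_extrap(ages.astype(float), age_anchors, values[:, j])
    # year pass: one row per single age, evaluated on the single-year grid
    out = np.empty((len(ages), len(years)))
    for i in range(len(ages)):
        out[i, :] = _interp_extrap(years.astype(float), year_anchors, by_age[i, :])

    n_clip = int(np.sum((out <= 0) | (out > 1)))
    if n_clip:
        log.warning("survival interpolation clipped %d values into (0, 1]", n_clip)
        out = np.clip(out, _EPS, 1.0)

    idx = pd.MultiIndex.from_product([ages, years], names=["age", "year"])
    return pd.DataFrame({"px1": out.ravel()}, index=idx).reset_index()


def survival_lookup(surface: pd.DataFrame) -> pd.DataFrame:
    """Index a survival surface by (age, year) for fast joins."""
    return surface.set_index(["age", "year"])["px1"]
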