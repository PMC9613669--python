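"""Population model: frame assembly, posterior algebra, projections."""

import numpy as np
import pandas as pd
import pytest

from mwra.config import CoverageError, McmcSettings, PriorSettings, ValidationError
from mwra import population
from mwra.population import PopulationModelSpec, build_frame, census_mwra_counts


def test_frame_roundtrips_generator_truth(small_config, small_truth, small_frame):
    """Every covariate cell in the assembled frame equals the generator's
    stored truth exactly."""
    t = small_truth.frame.set_index(["age", "division", "year"])
    f = small_frame.set_index(["age", "division", "year"])
    sub = t.loc[f.index]
    np.testing.assert_array_equal(f.x1.to_numpy(), sub.x1.to_numpy())
    np.testing.assert_array_equal(f.x2.to_numpy(), sub.x2.to_numpy())
    np.testing.assert_array_equal(f.x3.to_numpy(), sub.x3.to_numpy())
    assert "covariate_correlations" in small_frame.attrs


def test_missing_asfr_division_raises_coverage_error(
    small_config, small_truth, small_census
):
    reg = small_config.register
    counts = census_mwra_counts(small_census, reg)
    asfr = small_truth.as_asfr_surface()
    asfr = asfr[asfr.region != "R2"]  # drop a whole region's fertility
    with pytest.raises(CoverageError, match="asfr"):
        build_frame(
            counts,
            small_truth.as_migration_series(),
            asfr,
            small_truth.as_survival_surface(),
            reg,
        )


def test_constant_covariates_flagged_but_join_succeeds(small_config, small_census):
    reg = small_config.register
    counts = census_mwra_counts(small_census, reg)
    years = sorted(counts.year.unique())
    idx = pd.MultiIndex.from_product(
        [range(15, 50), reg.divisions, years], names=["age", "division", "year"]
    ).to_frame(index=False)
    mig = idx.assign(x1=0.5)
    asfr = idx.assign(region=idx.division.map(reg.region_of), asfr=0.2)[
        ["age", "region", "year", "asfr"]
    ].drop_duplicates()
    surv = idx.assign(px1=0.9)[["age", "year", "px1"]].drop_duplicates()
    frame = build_frame(counts, mig, asfr, surv, reg)
    corr = frame.attrs["covariate_correlations"]
    assert corr.isna().all().all()


def _intercept_frame(reg, b0=7.0):
    rows = []
    for d in reg.divisions:
        for a in range(15, 20):
            for t in (1976, 1987, 2005):
                rows.append(
                    {
                        "age": a,
                        "division": d,
                        "region": reg.region_of(d),
                        "year": t,
                        "count": float(np.exp(b0)),
                        "x1": 0.1,
                        "x2": 0.2,
                        "x3": 0.95,
                    }
                )
    return pd.DataFrame(rows)


def test_intercept_only_limit(small_config):
    """With identical counts everywhere and tight scales, every predicted
    log-population must sit within 0.01 of the common log count."""
    reg = small_config.register
    frame = _intercept_frame(reg, b0=7.0)
    spec = PopulationModelSpec(
        priors=PriorSettings(scale_sd=1e-3, sigma_sd=1e-3),
        mcmc=McmcSettings(1500, 500, 2, 1),
        include_x1=False,
        include_x2x3=False,
    )
    draws = population.fit(frame, spec)
    med = np.median(draws.stacked("log_eta_star"), axis=0)
    assert np.abs(med - 7.0).max() < 0.01


def test_posterior_respects_loglinear_algebra(small_frame):
    """Per draw, stored log eta* must equal b0 + b1 X1 + b2 X2 X3 + u1 + u2
    (exact identity up to storage precision)."""
    spec = PopulationModelSpec(mcmc=McmcSettings(500, 200, 2, 2))
    draws = population.fit(small_frame, spec)
    f = small_frame
    beta = draws.params["beta"]
    lp = (
        beta[:, :, [0]]
        + beta[:, :, [1]] * f.x1.to_numpy()[None, None, :]
        + beta[:, :, [2]] * (f.x2 * f.x3).to_numpy()[None, None, :]
    )
    u1_levels = {k: i for i, k in enumerate(draws.coords["u_u1"])}
    u2_levels = {k: i for i, k in enumerate(draws.coords["u_u2"])}
    c1 = [u1_levels[(a, d, t)] for a, d, t in zip(f.age, f.division, f.year)]
    c2 = [u2_levels[(d, t)] for d, t in zip(f.division, f.year)]
    lp += draws.params["u_u1"][:, :, c1] + draws.params["u_u2"][:, :, c2]
    np.testing.assert_allclose(
        draws.params["log_eta_star"], lp, rtol=0, atol=1e-5
    )


def test_two_seeds_agree_within_posterior_sd(small_frame):
    d1 = population.fit(
        small_frame, PopulationModelSpec(mcmc=McmcSettings(2000, 700, 2, 11))
    )
    d2 = population.fit(
        small_frame, PopulationModelSpec(mcmc=McmcSettings(2000, 700, 2, 99))
    )
    for j in range(3):
        m1 = np.median(d1.stacked("beta")[:, j])
        m2 = np.median(d2.stacked("beta")[:, j])
        sd = d1.stacked("beta")[:, j].std()
        assert abs(m1 - m2) < 0.5 * sd


def test_projection_is_deterministic_linear_predictor_without_effects(small_frame):
    spec = PopulationModelSpec(mcmc=McmcSettings(600, 200, 2, 3))
    draws = population.fit(small_frame, spec)
    fut = small_frame.copy()
    fut["year"] = 2030
    base = population.project(
        draws, fut, include_random_effects=False, include_residual=False
    )
    # frozen covariates: repeating the same cells at a later year changes
    # nothing in the linear predictor
    fut2 = fut.copy()
    fut2["year"] = 2031
    again = population.project(
        draws, fut2, include_random_effects=False, include_residual=False
    )
    np.testing.assert_array_equal(
        base.params["pop_pred"], again.params["pop_pred"]
    )
    assert (base.params["pop_pred"] > 0).all()

    # doubling X2*X3 shifts each draw's log prediction by beta2 * delta
    fut3 = fut.copy()
    fut3["x2"] = fut3.x2 * 2.0
    doubled = population.project(
        draws, fut3, include_random_effects=False, include_residual=False
    )
    shift = np.log(doubled.stacked("pop_pred").astype(float)) - np.log(
        base.stacked("pop_pred").astype(float)
    )
    beta2 = draws.stacked("beta")[:, 2]
    delta = (fut.x2 * fut.x3).to_numpy()
    expected = beta2[:, None] * delta[None, :]
    np.testing.assert_allclose(shift, expected, atol=1e-3)


def test_missing_future_covariate_raises(small_frame):
    spec = PopulationModelSpec(mcmc=McmcSettings(400, 150, 2, 3))
    draws = population.fit(small_frame, spec)
    fut = small_frame.copy()
    fut.loc[fut.index[3], "x2"] = np.nan
    with pytest.raises(CoverageError):
        population.project(draws, fut)
    with pytest.raises(CoverageError, match="x3"):
        population.project(draws, fut.drop(columns=["x3"]))


def test_zero_counts_offset_and_degenerate_frames(small_frame):
    frame = small_frame.copy()
    frame.loc[frame.index[0], "count"] = 0.0
    spec = PopulationModelSpec(mcmc=McmcSettings(400, 150, 2, 4))
    draws = population.fit(frame, spec)  # must not raise on the zero count
    assert draws.n_kept == 250
    with pytest.raises(ValidationError):
        population.fit(frame.iloc[:1], spec)
    with pytest.raises(ValidationError):
        population.fit(frame[frame.year == frame.year.iloc[0]], spec)
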