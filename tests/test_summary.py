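"""Summaries, rates, convergence diagnostics, posterior-predictive checks."""

import numpy as np
import pandas as pd
import pytest

from mwra.config import AdminRegister, McmcSettings, ValidationError
from mwra.gibbs import PosteriorDraws
from mwra import population, summary
from mwra.summary import (
    annual_rate,
    annual_rate_point,
    gelman_rubin,
    ppp,
    summarize,
    unit_total_draws,
)

REG = AdminRegister({"A": "R1", "B": "R1"})


def _draws_for(cells, values):
    """values: (n_draws, n_cells) -> PosteriorDraws with 2 pseudo-chains."""
    v = np.asarray(values, dtype=float)
    half = v.shape[0] // 2
    arr = np.stack([v[:half], v[half : 2 * half]])
    return PosteriorDraws(params={"pop_pred": arr}, coords={"pop_pred": cells})


def test_constant_draws_collapse_cri():
    ages = list(range(15, 50))
    cells = [(a, "A", "R1", 2030) for a in ages]
    d = _draws_for(cells, np.full((100, len(cells)), 7.0))
    out = summarize(d, REG).set_index(["level", "unit"])
    row = out.loc[("division", "A")]
    assert row.count_median == pytest.approx(35 * 7.0)
    assert row.cri_low == pytest.approx(35 * 7.0)
    assert row.cri_high == pytest.approx(35 * 7.0)
    # aggregation consistency: national equals the sum over regions
    nat = out.loc[("national", "National")].count_median
    regions = out.loc["region"].count_median.sum()
    assert nat == pytest.approx(regions)


def _percentile_oracle(xs, q):
    """Sort-based linear-interpolation (type-7) percentile."""
    xs = np.sort(np.asarray(xs, dtype=float))
    h = (len(xs) - 1) * q / 100.0
    lo = int(np.floor(h))
    hi = min(lo + 1, len(xs) - 1)
    return xs[lo] + (h - lo) * (xs[hi] - xs[lo])


def test_percentiles_match_sort_oracle():
    xs = [1.0, 2.0, 3.0, 4.0, 100.0]
    cells = [(20, "A", "R1", 2030)]
    d = _draws_for(cells, np.array(xs)[:, None])
    # median of {1,2,3,4,100} is 3 under any sensible rule
    assert float(np.median(np.asarray(xs))) == 3.0
    for q in (2.5, 50.0, 97.5):
        assert np.percentile(np.asarray(xs), q) == pytest.approx(
            _percentile_oracle(xs, q)
        )
    rng = np.random.default_rng(0)
    big = rng.lognormal(0, 1, 10_000)
    for q in (2.5, 25.0, 50.0, 97.5):
        assert np.percentile(big, q) == pytest.approx(_percentile_oracle(big, q))


def test_symmetric_draws_median_close_to_mean(rng):
    cells = [(20, "A", "R1", 2030)]
    x = rng.normal(50.0, 5.0, 4000)
    d = _draws_for(cells, x[:, None])
    out = summarize(d, REG)
    assert out.count_median.iloc[0] == pytest.approx(x.mean(), abs=0.5)


def test_sum_of_medians_below_median_of_sums_for_right_skew(rng):
    """For independent right-skewed cell draws the sum of cell medians lies
    below the median of the cell sums (both are reported)."""
    cells = [(a, "A", "R1", 2030) for a in range(15, 25)]
    x = rng.lognormal(3.0, 1.0, size=(2000, 10))
    d = _draws_for(cells, x)
    out = summarize(d, REG).set_index(["level", "unit"]).loc[("division", "A")]
    assert out.count_median < out.count_median_of_sums
    assert out.cri_low <= out.count_median_of_sums <= out.cri_high


def test_annual_rate_point_formula():
    # printed endpoint medians for the East region reproduce the printed rate
    assert round(annual_rate_point(109_582, 208_402, 2000, 2030), 2) == 3.01
    assert annual_rate_point(100.0, 100.0, 2000, 2030) == 0.0
    assert annual_rate_point(100.0, 200.0, 2000, 2010) == pytest.approx(10.0)
    with pytest.raises(ValidationError):
        annual_rate_point(0.0, 10.0, 2000, 2030)
    with pytest.raises(ValidationError):
        annual_rate_point(10.0, 10.0, 2030, 2000)


def test_annual_rate_from_draws(rng):
    cells = [(20, "A", "R1", 2000), (20, "A", "R1", 2030)]
    p1 = rng.normal(100.0, 1.0, 2000)
    p2 = p1 * 2.0
    d = _draws_for(cells, np.column_stack([p1, p2]))
    totals = unit_total_draws(d, REG)
    out = annual_rate(totals, (2000, 2030)).set_index(["level", "unit"])
    row = out.loc[("division", "A")]
    expected = 100.0 * 1.0 / 30.0  # doubling over 30 years
    assert row.rate_median == pytest.approx(expected, abs=0.01)
    assert row.rate_cri_low <= row.rate_median <= row.rate_cri_high


def test_gelman_rubin_identical_chains_is_one(rng):
    x = rng.normal(size=2000)
    assert gelman_rubin(np.tile(x, (2, 1))) == 1.0


def test_gelman_rubin_stationary_below_threshold(rng):
    chains = rng.normal(size=(2, 2000))
    assert gelman_rubin(chains) < 1.05


def test_gelman_rubin_flags_divergent_chains(rng):
    chains = np.stack([rng.normal(0, 1, 1000), rng.normal(10, 1, 1000)])
    assert gelman_rubin(chains) > 1.1 * 3


def test_gelman_rubin_agrees_with_arviz_near_convergence(rng):
    import arviz as az

    chains = rng.normal(size=(4, 1000))
    assert gelman_rubin(chains) == pytest.approx(float(az.rhat(chains)), abs=0.01)


def test_gelman_rubin_input_validation():
    with pytest.raises(ValidationError):
        gelman_rubin(np.zeros((1, 100)))
    with pytest.raises(ValidationError):
        gelman_rubin(np.zeros(100))


def _fitted_small_model(small_frame, seed=5):
    spec = population.PopulationModelSpec(mcmc=McmcSettings(1300, 300, 2, seed))
    return population.fit(small_frame, spec), spec


def test_ppp_centred_for_well_specified_model(small_frame):
    draws, _ = _fitted_small_model(small_frame)
    out = ppp(small_frame, draws, seed=1).set_index("statistic")
    for stat in ("mean_log_count", "sd_log_count"):
        assert 0.05 < out.loc[stat, "ppp"] < 0.95


def test_ppp_extremes():
    cells = [(20, "A", "R1", 2005)]
    n = 50
    frame = pd.DataFrame(
        {
            "age": 20,
            "division": "A",
            "region": "R1",
            "year": 2005,
            "count": np.exp(np.linspace(4.9, 5.1, n)),
        }
    )
    mu = np.full((2, 100, n), 5.0, dtype=float)
    sig = np.full((2, 100), 0.01)
    d = PosteriorDraws(
        params={"log_eta_star": mu, "sigma": sig},
        coords={"log_eta_star": [(20, "A", "R1", 2005)] * n},
    )
    # observed far above every replicate -> PPP 0 for the mean statistic
    high = frame.copy()
    high["count"] = high["count"] * np.exp(3.0)
    out = ppp(high, d, seed=2).set_index("statistic")
    assert out.loc["mean_log_count", "ppp"] == 0.0
    # observed far below -> PPP 1
    low = frame.copy()
    low["count"] = low["count"] * np.exp(-3.0)
    out = ppp(low, d, seed=2).set_index("statistic")
    assert out.loc["mean_log_count", "ppp"] == 1.0


def test_effective_sample_size_sane(rng):
    iid = rng.normal(size=(2, 1000))
    assert summary.effective_sample_size(iid) > 1000
    sticky = np.cumsum(rng.normal(size=(2, 1000)), axis=1)
    assert summary.effective_sample_size(sticky) < 200


def test_reference_table_identities_loadable():
    ref = summary.load_reference_estimates()
    assert {"unit", "level", "parent", "year", "median"} <= set(ref.columns)
    nat = ref[(ref.level == "national") & (ref.year == 2030)]["median"].iloc[0]
    assert nat == 6_124_480
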