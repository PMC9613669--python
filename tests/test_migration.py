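"""Net-migration flows, harmonization, age proportions, and the
hierarchical time-series model."""

import numpy as np
import pandas as pd
import pytest

from mwra.config import (
    AdminRegister,
    McmcSettings,
    PriorSettings,
    RegistryError,
    ValidationError,
)
from mwra import migration
from mwra.migration import age_proportions, compute_flows, harmonize


REG = AdminRegister({"A": "R1", "B": "R1", "C": "R2"})


def _rows(entries):
    """entries: (age, cur, prev, weight)"""
    return pd.DataFrame(
        [
            {
                "census_year": 2005,
                "age": a,
                "sex": "female",
                "marital_status": "married",
                "division_current": cur,
                "division_previous": prev,
                "person_weight": w,
            }
            for a, cur, prev, w in entries
        ]
    )


def test_single_mover_hand_count():
    recs = _rows([(20, "A", "B", 10.0)])
    out = compute_flows(recs, REG).set_index(["division", "age"])
    assert out.loc[("A", 20), "net_count"] == 10.0
    assert out.loc[("B", 20), "net_count"] == -10.0
    assert out.net_count.sum() == 0.0


def test_stayers_produce_zero_flows():
    recs = _rows([(20, "A", "A", 10.0), (25, "B", "B", 5.0)])
    out = compute_flows(recs, REG)
    assert (out[["in_count", "out_count", "net_count"]] == 0).all().all()


def test_missing_previous_division_ignored():
    recs = _rows([(20, "A", None, 10.0), (20, "A", "B", 10.0)])
    out = compute_flows(recs, REG).set_index(["division", "age"])
    assert out.loc[("A", 20), "in_count"] == 10.0


def test_flows_match_bruteforce_oracle(rng):
    """500 random rows: flows must equal a brute-force double loop over
    every ordered division pair."""
    divs = list(REG.divisions)
    n = 500
    recs = _rows(
        [
            (
                int(rng.integers(15, 50)),
                divs[rng.integers(3)],
                divs[rng.integers(3)],
                float(rng.integers(1, 20)),
            )
            for _ in range(n)
        ]
    )
    out = compute_flows(recs, REG).set_index(["division", "age"])

    # oracle: loop over ordered pairs (origin, destination)
    expect_in = {(d, a): 0.0 for d in divs for a in range(15, 50)}
    expect_out = {(d, a): 0.0 for d in divs for a in range(15, 50)}
    for r in recs.itertuples(index=False):
        for o in divs:
            for d in divs:
                if o == d:
                    continue
                if r.division_previous == o and r.division_current == d:
                    expect_in[(d, r.age)] += r.person_weight
                    expect_out[(o, r.age)] += r.person_weight
    for key in expect_in:
        assert out.loc[key, "in_count"] == pytest.approx(expect_in[key])
        assert out.loc[key, "out_count"] == pytest.approx(expect_out[key])
    assert out.net_count.sum() == pytest.approx(0.0)


def test_hierarchical_consistency_on_synthetic_census(small_config, small_census):
    """Closed-system zero-sum and the published consistency check: age-level
    nets sum to division totals, division totals sum to region totals."""
    reg = small_config.register
    for year, block in small_census.groupby("census_year"):
        series = compute_flows(block, reg)
        assert series.net_count.sum() == pytest.approx(0.0)
        div_tot = series.groupby("division").net_count.sum()
        region_tot = div_tot.groupby(
            div_tot.index.map(reg.region_of)
        ).sum()
        assert region_tot.sum() == pytest.approx(0.0)


def test_unknown_division_raises():
    recs = _rows([(20, "Z", "A", 10.0)])
    with pytest.raises(RegistryError, match="Z"):
        compute_flows(recs, REG)


def test_multiple_years_rejected():
    recs = _rows([(20, "A", "B", 10.0)])
    recs.loc[0, "census_year"] = 1987
    recs = pd.concat([recs, _rows([(20, "A", "B", 1.0)])])
    with pytest.raises(ValidationError):
        compute_flows(recs, REG)


def test_empty_subset_warns_and_returns_zeros():
    recs = _rows([(20, "A", "B", 10.0)])
    recs["sex"] = "male"
    out = compute_flows(recs, REG)
    assert (out.net_count == 0).all()


# ----------------------------------------------------------- harmonization

def _series(values):
    """values: dict {(division, age): net}"""
    rows = [
        {"division": d, "age": a, "year": 1976, "in_count": max(v, 0.0),
         "out_count": max(-v, 0.0), "net_count": v}
        for (d, a), v in values.items()
    ]
    return pd.DataFrame(rows)


def test_identity_map_is_noop():
    s = _series({("A", 20): 100.0, ("B", 20): -100.0})
    pmap = pd.DataFrame(
        {"old_division": ["A", "B"], "new_division": ["A", "B"], "share": [1.0, 1.0]}
    )
    out = harmonize(s, pmap).set_index(["division", "age"])
    assert out.loc[("A", 20), "net_count"] == 100.0
    assert out.loc[("B", 20), "net_count"] == -100.0


def test_proportional_split():
    s = _series({("A", 20): 100.0})
    pmap = pd.DataFrame(
        {"old_division": ["A", "A"], "new_division": ["A1", "A2"], "share": [0.6, 0.4]}
    )
    out = harmonize(s, pmap).set_index(["division", "age"])
    assert out.loc[("A1", 20), "net_count"] == pytest.approx(60.0)
    assert out.loc[("A2", 20), "net_count"] == pytest.approx(40.0)


def test_random_partition_conserves_totals(rng):
    for _ in range(10):
        vals = {
            (d, a): float(rng.normal(0, 50))
            for d in "ABC"
            for a in rng.choice(np.arange(15, 50), size=6, replace=False)
        }
        s = _series(vals)
        rows = []
        for d in "ABC":
            shares = rng.dirichlet(np.ones(3))
            for j, sh in enumerate(shares):
                rows.append({"old_division": d, "new_division": f"N{j}", "share": sh})
        pmap = pd.DataFrame(rows)
        out = harmonize(s, pmap)
        assert out.net_count.sum() == pytest.approx(s.net_count.sum(), abs=1e-9)
        assert out.in_count.sum() == pytest.approx(s.in_count.sum(), abs=1e-9)


def test_bad_shares_rejected():
    s = _series({("A", 20): 100.0})
    pmap = pd.DataFrame(
        {"old_division": ["A", "A"], "new_division": ["A1", "A2"], "share": [0.6, 0.6]}
    )
    with pytest.raises(ValidationError, match="sum to 1"):
        harmonize(s, pmap)


def test_unmapped_division_rejected():
    s = _series({("A", 20): 100.0, ("B", 20): 1.0})
    pmap = pd.DataFrame(
        {"old_division": ["A"], "new_division": ["A"], "share": [1.0]}
    )
    with pytest.raises(RegistryError, match="B"):
        harmonize(s, pmap)


# --------------------------------------------------------- age proportions

def test_age_proportion_arithmetic():
    s = _series({("A", 15): 2.0, ("A", 16): 3.0})
    out = age_proportions(s).set_index("age")
    assert out.loc[15, "x1"] == pytest.approx(0.4)
    assert out.loc[16, "x1"] == pytest.approx(0.6)


def test_all_zero_nets_flagged_undefined():
    s = _series({("A", 15): 0.0, ("A", 16): 0.0})
    out = age_proportions(s)
    assert (~out.x1_defined).all()
    assert (out.x1 == 0.0).all()


def test_mixed_sign_nets_can_exceed_unit_interval():
    s = _series({("A", 15): 4.0, ("A", 16): -2.0})
    out = age_proportions(s).set_index("age")
    assert out.loc[15, "x1"] == pytest.approx(2.0)
    assert out.loc[16, "x1"] == pytest.approx(-1.0)
    assert out.x1.sum() == pytest.approx(1.0)


# ------------------------------------------------------------------- model

def _constant_series(reg, ages, years, value):
    rows = []
    for d in reg.divisions:
        for a in ages:
            for t in years:
                rows.append({"division": d, "age": a, "year": t,
                             "net_count": np.nan, "x1": value})
    return pd.DataFrame(rows)


def test_constant_x1_recovered_at_all_horizons():
    reg = AdminRegister.uniform(2, 2)
    series = _constant_series(reg, range(15, 20), (1976, 1987, 2005), 0.1)
    draws = migration.fit_netmigration_model(
        series, reg, McmcSettings(1200, 400, 2, 5), projection_years=(2000, 2030)
    )
    pf = migration.x1_prediction_frame(draws)
    assert np.abs(pf.x1_median - 0.1).max() < 0.02


def test_single_cell_matches_conjugate_oracle():
    """One division, one age, constant data and vanishing effect scales:
    the fit reduces to a normal-mean model whose posterior mean has the
    conjugate closed form."""
    reg = AdminRegister({"A": "R1", "B": "R1"})
    obs = pd.DataFrame(
        {
            "division": "A",
            "age": 20,
            "year": [1976, 1987, 2005],
            "net_count": np.nan,
            "x1": [0.21, 0.2, 0.19],
        }
    )
    pri = PriorSettings(beta_sd=0.5, scale_sd=1e-3, sigma_sd=0.05)
    draws = migration.fit_netmigration_model(
        obs, reg, McmcSettings(3000, 1000, 2, 6), priors=pri,
        projection_years=(2005, 2006),
    )
    b = draws.stacked("beta")[:, 0]
    sig = float(np.median(draws.stacked("sigma")))
    y = np.array([0.21, 0.2, 0.19])
    prec = len(y) / sig**2 + 1.0 / 0.5**2
    expected = (y.sum() / sig**2) / prec
    assert abs(b.mean() - expected) < 0.02


def test_linear_trend_calibration():
    """Linear-in-time truth with small noise: the true 2030 extrapolation
    falls inside the posterior 95% CrI in >= 90% of replicates."""
    reg = AdminRegister.uniform(1, 2)
    years = [1976, 1987, 2005]
    ages = range(15, 18)
    master = np.random.SeedSequence(42)
    n_rep, hits = 30, 0
    for i, s in enumerate(master.spawn(n_rep)):
        r = np.random.default_rng(s)
        slope = 0.002
        rows = []
        for d in reg.divisions:
            for a in ages:
                base = 0.1 + 0.01 * (a - 15)
                for t in years:
                    rows.append(
                        {
                            "division": d,
                            "age": a,
                            "year": t,
                            "net_count": np.nan,
                            "x1": base + slope * (t - 1976) + r.normal(0, 0.005),
                        }
                    )
        series = pd.DataFrame(rows)
        draws = migration.fit_netmigration_model(
            series, reg, McmcSettings(700, 250, 2, seed=i),
            projection_years=(2030, 2030),
        )
        cells = draws.coords["x1_pred"]
        j = cells.index((15, reg.divisions[0], 2030))
        target = 0.1 + slope * (2030 - 1976)
        x = draws.stacked("x1_pred")[:, j]
        lo, hi = np.percentile(x, [2.5, 97.5])
        hits += lo <= target <= hi
    assert hits >= 0.9 * n_rep


def test_too_few_time_points_rejected():
    reg = AdminRegister.uniform(1, 2)
    series = _constant_series(reg, range(15, 18), (2005,), 0.1)
    with pytest.raises(ValidationError):
        migration.fit_netmigration_model(series, reg, McmcSettings(500, 100, 2))
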