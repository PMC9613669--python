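"""End-to-end pipeline: simulate -> migration -> fertility -> survival ->
fit -> project -> summarize -> diagnose -> sensitivity.

Each stage reads the previous stage's artifacts from the run directory,
derives its own RNG seed deterministically from the master seed, and logs a
stage-tagged line; a manifest records the configuration hash, per-stage
seeds, and a checksum for every output file.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import fertility, migration, population, summary, survival, synthetic
from .config import (
    ConfigurationError,
    McmcSettings,
    PriorSettings,
    SyntheticWorldConfig,
    derive_stage_seed,
    DEFAULT_FERTILITY_MCMC,
    DEFAULT_MIGRATION_MCMC,
    DEFAULT_POPULATION_MCMC,
)

log = logging.getLogger("mwra.pipeline")

STAGES = (
    "simulate",
    "migration",
    "fertility",
    "survival",
    "fit",
    "project",
    "summarize",
    "diagnose",
    "sensitivity",
)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    out_dir: str = "run"
    world: SyntheticWorldConfig = field(default_factory=SyntheticWorldConfig)
    priors: PriorSettings = field(default_factory=PriorSettings)
    migration_mcmc: McmcSettings = field(default_factory=lambda: DEFAULT_MIGRATION_MCMC)
    fertility_mcmc: McmcSettings = field(default_factory=lambda: DEFAULT_FERTILITY_MCMC)
    population_mcmc: McmcSettings = field(default_factory=lambda: DEFAULT_POPULATION_MCMC)
    projection_years: tuple[int, int] = (2000, 2030)
    rate_periods: tuple[tuple[int, int], ...] = ((2000, 2030), (2020, 2030))
    partition_map: str | None = None  # CSV path; required if census divisions
    # predate the current register
    fertility_period_length: int = 5
    sensitivity_prior_factor: float = 10.0
    run_sensitivity: bool = True
    seed: int = 0

    def __post_init__(self):
        y0, y1 = self.projection_years
        if y0 >= y1:
            raise ConfigurationError("projection_years must be ordered")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = {}
        for key, val in raw.items():
            if key == "world":
                val = {
                    k: tuple(v) if isinstance(v, list) else v for k, v in val.items()
                }
                kwargs["world"] = SyntheticWorldConfig(**val)
            elif key == "priors":
                kwargs["priors"] = PriorSettings(**val)
            elif key.endswith("_mcmc"):
                kwargs[key] = McmcSettings(**val)
            elif key in ("projection_years",):
                kwargs[key] = tuple(val)
            elif key == "rate_periods":
                kwargs[key] = tuple(tuple(p) for p in val)
            else:
                kwargs[key] = val
        return cls(**kwargs)

    def config_hash(self) -> str:
        blob = json.dumps(_jsonable(dataclasses.asdict(self)), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages in dependency order; returns a manifest dict.

    Any stage failure raises :class:`StageError` naming the stage; artifacts
    written before the failure are retained in the run directory.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stage_seeds": {s: derive_stage_seed(config.seed, s) for s in STAGES},
        "stages": {},
        "outputs": {},
    }
    state: dict = {}

    for stage in STAGES:
        if stage == "sensitivity" and not config.run_sensitivity:
            continue
        log.info("[%s] starting", stage)
        try:
            info = _STAGE_FUNCS[stage](config, out, state)
        except Exception as exc:  # noqa: BLE001 - stage name must surface
            log.error("[%s] failed: %s", stage, exc)
            _write_manifest(out, manifest)
            raise StageError(stage, exc) from exc
        manifest["stages"][stage] = info or {}
        log.info("[%s] done", stage)

    for f in sorted(out.glob("*")):
        if f.is_file() and f.name != "manifest.json":
            manifest["outputs"][f.name] = _checksum(f)
    try:
        import importlib.metadata as im

        manifest["versions"] = {
            p: im.version(p) for p in ("numpy", "scipy", "pandas", "arviz")
        }
    except Exception:  # pragma: no cover
        pass
    _write_manifest(out, manifest)
    return manifest


def _write_manifest(out: Path, manifest: dict) -> None:
    (out / "manifest.json").write_text(json.dumps(_jsonable(manifest), indent=2))


# ------------------------------------------------------------------- stages

def _stage_simulate(config: RunConfig, out: Path, state: dict):
    world = dataclasses.replace(
        config.world,
        seed=derive_stage_seed(config.seed, "simulate"),
        projection_years=config.projection_years,
    )
    state["world"] = world
    state["truth"] = synthetic.make_ground_truth(world)
    state["census"] = synthetic.generate_census(world, state["truth"])
    state["births"] = synthetic.generate_birth_histories(
        world, state["truth"].as_asfr_surface()
    )
    state["census"].to_csv(out / "census.csv", index=False)
    births_flat = state["births"].copy()
    births_flat["child_birth_cmcs"] = births_flat.child_birth_cmcs.map(
        lambda xs: ";".join(str(x) for x in xs)
    )
    births_flat.to_csv(out / "births.csv", index=False)
    state["truth"].lifetable.to_csv(out / "lifetable.csv", index=False)
    (out / "truth.json").write_text(
        json.dumps(
            {
                "betas_total": list(state["truth"].betas_total),
                "identity_gap": state["truth"].linear_predictor_identity_gap(),
            },
            indent=2,
        )
    )
    return {"n_census_rows": len(state["census"]), "n_women": len(state["births"])}


def _stage_migration(config: RunConfig, out: Path, state: dict):
    world = state["world"]
    register = world.register
    census = state["census"]
    old_years = []
    if config.partition_map is not None:
        pmap = pd.read_csv(config.partition_map)
        migration.validate_partition_map(pmap)
        old_years = sorted(
            set(census.census_year.unique())
            - {int(census.census_year.max())}
        )
    pieces = []
    for year, block in census.groupby("census_year"):
        try:
            series = migration.compute_flows(block, register)
        except Exception as exc:
            from .config import RegistryError

            if isinstance(exc, RegistryError) and config.partition_map is None:
                raise ConfigurationError(
                    "partition_map: census contains divisions outside the "
                    f"current register and no partition map was given ({exc})"
                ) from exc
            raise
        if config.partition_map is not None and year in old_years:
            series = migration.harmonize(series, pmap)
        pieces.append(series)
    series = pd.concat(pieces, ignore_index=True)
    unknown = set(series.division.unique()) - set(register.divisions)
    if unknown:
        raise ConfigurationError(
            "partition_map: census divisions outside the current register "
            f"({sorted(unknown)}); provide a partition map"
        )
    series = migration.age_proportions(series)
    series.to_csv(out / "migration_series.csv", index=False)
    state["migration_series"] = series
    mcmc = config.migration_mcmc.with_seed(derive_stage_seed(config.seed, "migration"))
    draws = migration.fit_netmigration_model(
        series, register, mcmc, config.priors, config.projection_years
    )
    state["netmig_draws"] = draws
    pred = migration.x1_prediction_frame(draws)
    pred.to_csv(out / "x1_surface.csv", index=False)
    _write_posterior_json(out / "netmig_posterior.json", draws)
    return {"rhat_max": draws.diagnostics.get("rhat_max"), "warnings": draws.warnings}


def _stage_fertility(config: RunConfig, out: Path, state: dict):
    world = state["world"]
    y0 = min(world.census_years)
    y1 = max(world.survey_years)
    empirical = fertility.compute_asfr(
        state["births"],
        window=(y0, y1),
        age_range=(world.age_min, world.age_max),
        period_length=config.fertility_period_length,
    )
    empirical.to_csv(out / "asfr_empirical.csv", index=False)
    state["asfr_empirical"] = empirical
    mcmc = config.fertility_mcmc.with_seed(derive_stage_seed(config.seed, "fertility"))
    draws = fertility.fit_asfr_model(
        empirical, mcmc, config.priors,
        projection_years=(y0, config.projection_years[1]),
    )
    state["asfr_draws"] = draws
    pred = fertility.asfr_prediction_frame(draws)
    pred.to_csv(out / "asfr_surface.csv", index=False)
    state["asfr_pred"] = pred
    _write_posterior_json(out / "asfr_posterior.json", draws)
    return {"rhat_max": draws.diagnostics.get("rhat_max"), "warnings": draws.warnings}


def _stage_survival(config: RunConfig, out: Path, state: dict):
    world = state["world"]
    surface = survival.interpolate_survival(
        state["truth"].lifetable,
        ages=world.ages,
        years=np.arange(min(world.census_years), config.projection_years[1] + 1),
    )
    surface.to_csv(out / "survival_surface.csv", index=False)
    state["survival_surface"] = surface
    return {"n_cells": len(surface)}


def _stage_fit(config: RunConfig, out: Path, state: dict):
    world = state["world"]
    register = world.register
    counts = population.census_mwra_counts(state["census"], register)
    asfr_point = state["asfr_pred"].rename(columns={"asfr_median": "asfr"})
    frame = population.build_frame(
        counts,
        state["migration_series"],
        asfr_point[["age", "region", "year", "asfr"]],
        state["survival_surface"],
        register,
    )
    state["frame"] = frame
    spec = population.PopulationModelSpec(
        priors=config.priors,
        mcmc=config.population_mcmc.with_seed(derive_stage_seed(config.seed, "fit")),
    )
    state["pop_spec"] = spec
    draws = population.fit(frame, spec)
    state["pop_draws"] = draws
    frame.to_csv(out / "model_frame.csv", index=False)
    corr = frame.attrs["covariate_correlations"]
    _write_posterior_json(
        out / "population_posterior.json", draws,
        extra={"covariate_correlations": corr.to_dict()},
    )
    return {"rhat_max": draws.diagnostics.get("rhat_max"), "warnings": draws.warnings}


def _stage_project(config: RunConfig, out: Path, state: dict):
    world = state["world"]
    register = world.register
    y0, y1 = config.projection_years
    years = list(range(y0, y1 + 1))
    ages = list(world.ages)
    cells = pd.MultiIndex.from_product(
        [ages, register.divisions, years], names=["age", "division", "year"]
    ).to_frame(index=False)
    cells["region"] = cells.division.map(register.region_of)

    mig_cells = pd.DataFrame(
        state["netmig_draws"].coords["x1_pred"], columns=["age", "division", "year"]
    )
    mig_cells["pos"] = np.arange(len(mig_cells))
    asfr_cells = pd.DataFrame(
        state["asfr_draws"].coords["asfr_pred"], columns=["age", "region", "year"]
    )
    asfr_cells["pos"] = np.arange(len(asfr_cells))

    cells = cells.merge(mig_cells, on=["age", "division", "year"], how="left",
                        suffixes=("", "_mig")).rename(columns={"pos": "pos_mig"})
    cells = cells.merge(asfr_cells, on=["age", "region", "year"], how="left").rename(
        columns={"pos": "pos_asfr"}
    )
    surv = state["survival_surface"].set_index(["age", "year"])["px1"]
    cells["x3"] = [surv.get((a, t), np.nan) for a, t in zip(cells.age, cells.year)]
    if cells[["pos_mig", "pos_asfr", "x3"]].isna().any().any():
        bad = cells[cells[["pos_mig", "pos_asfr", "x3"]].isna().any(axis=1)]
        raise population.CoverageError(
            f"future covariates missing for {len(bad)} cells, e.g. "
            f"{bad[['age', 'division', 'year']].head(10).to_dict('records')}"
        )
    x1_draws = state["netmig_draws"].stacked("x1_pred")[
        :, cells.pos_mig.to_numpy(dtype=int)
    ]
    x2_draws = state["asfr_draws"].stacked("asfr_pred")[
        :, cells.pos_asfr.to_numpy(dtype=int)
    ]
    cells["x1"] = np.median(x1_draws, axis=0)
    cells["x2"] = np.median(x2_draws, axis=0)
    proj = population.project(
        state["pop_draws"],
        cells[["age", "division", "region", "year", "x1", "x2", "x3"]],
        x1_draws=x1_draws,
        x2_draws=x2_draws,
        seed=derive_stage_seed(config.seed, "project"),
    )
    state["proj_draws"] = proj
    return {"n_cells": len(cells)}


def _stage_summarize(config: RunConfig, out: Path, state: dict):
    register = state["world"].register
    table = summary.summarize(state["proj_draws"], register)
    table.to_csv(out / "projections.csv", index=False)
    state["projections"] = table
    totals = summary.unit_total_draws(state["proj_draws"], register)
    rates = pd.concat(
        [summary.annual_rate(totals, p) for p in config.rate_periods],
        ignore_index=True,
    )
    rates.to_csv(out / "rates.csv", index=False)
    state["rates"] = rates
    return {"n_rows": len(table)}


def _stage_diagnose(config: RunConfig, out: Path, state: dict):
    report = summary.diagnostics_report(
        state["pop_draws"],
        params=["beta", "sigma", "tau_u1", "tau_u2"],
    )
    ppp_table = summary.ppp(
        state["frame"], state["pop_draws"],
        seed=derive_stage_seed(config.seed, "diagnose"),
    )
    payload = {
        "convergence": report.to_dict("records"),
        "ppp": ppp_table.to_dict("records"),
    }
    (out / "diagnostics.json").write_text(json.dumps(_jsonable(payload), indent=2))
    state["diagnostics"] = payload
    _trace_plots(out, state)
    return {
        "rhat_max": float(report.rhat.max()),
        "ppp": {r["statistic"]: r["ppp"] for r in payload["ppp"]},
    }


def _trace_plots(out: Path, state: dict):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    draws = state["pop_draws"]
    beta = draws.params["beta"]
    names = draws.coords["beta"]
    fig, axes = plt.subplots(len(names), 1, figsize=(7, 2 * len(names)), squeeze=False)
    for j, name in enumerate(names):
        for c in range(beta.shape[0]):
            axes[j, 0].plot(beta[c, :, j], lw=0.4)
        axes[j, 0].set_ylabel(name)
    fig.tight_layout()
    fig.savefig(out / "trace_beta.png", dpi=80)
    plt.close(fig)


def _stage_sensitivity(config: RunConfig, out: Path, state: dict):
    report = summary.sensitivity(
        state["frame"],
        state["world"].register,
        spec=state["pop_spec"],
        prior_scale_factors=(config.sensitivity_prior_factor,),
    )
    (out / "sensitivity.json").write_text(
        json.dumps(_jsonable(report.to_dict("records")), indent=2)
    )
    state["sensitivity"] = report
    return report.set_index("run")["median_pct_diff"].to_dict()


def _write_posterior_json(path: Path, draws, extra: dict | None = None):
    payload = {
        "n_chains": draws.n_chains,
        "n_kept": draws.n_kept,
        "warnings": draws.warnings,
        "rhat_max": draws.diagnostics.get("rhat_max"),
        "params": {},
    }
    for name, arr in draws.params.items():
        if arr.ndim == 2:
            payload["params"][name] = {
                "median": float(np.median(arr)),
                "q2.5": float(np.quantile(arr, 0.025)),
                "q97.5": float(np.quantile(arr, 0.975)),
            }
    if extra:
        payload.update(extra)
    path.write_text(json.dumps(_jsonable(payload), indent=2))


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "migration": _stage_migration,
    "fertility": _stage_fertility,
    "survival": _stage_survival,
    "fit": _stage_fit,
    "project": _stage_project,
    "summarize": _stage_summarize,
    "diagnose": _stage_diagnose,
    "sensitivity": _stage_sensitivity,
}
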