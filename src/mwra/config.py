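"""Configuration objects, the administrative register, and shared errors."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np


class ConfigurationError(ValueError):
    """A configuration field is missing or invalid; message names the field."""


class ValidationError(ValueError):
    """Input data violate a documented invariant."""


class RegistryError(KeyError):
    """A division or region id is not in the administrative register."""


class CoverageError(ValueError):
    """A covariate source does not cover every cell required by a model frame."""


@dataclass(frozen=True)
class AdminRegister:
    """Nested administrative units: each division belongs to exactly one region.

    Mirrors Cameroon's two-level hierarchy (divisions nested in regions)."""

    division_to_region: dict[str, str]

    @property
    def divisions(self) -> list[str]:
        return sorted(self.division_to_region)

    @property
    def regions(self) -> list[str]:
        return sorted(set(self.division_to_region.values()))

    def region_of(self, division: str) -> str:
        try:
            return self.division_to_region[division]
        except KeyError:
            raise RegistryError(f"unknown division id: {division!r}") from None

    def check_division(self, division) -> None:
        if division not in self.division_to_region:
            raise RegistryError(f"unknown division id: {division!r}")

    @classmethod
    def uniform(cls, n_regions: int, divisions_per_region: int) -> "AdminRegister":
        mapping = {}
        for r in range(n_regions):
            region = f"R{r + 1}"
            for d in range(divisions_per_region):
                mapping[f"R{r + 1}D{d + 1}"] = region
        return cls(mapping)


@dataclass
class McmcSettings:
    """MCMC run sizes. ``n_draws`` counts iterations per chain including
    burn-in; kept draws per chain = n_draws - burn_in."""

    n_draws: int = 10_000
    burn_in: int = 3_000
    n_chains: int = 2
    seed: int = 0
    sampler: str = "blocked-gibbs"

    def __post_init__(self):
        if not (self.n_draws > self.burn_in >= 0):
            raise ConfigurationError("mcmc: need n_draws > burn_in >= 0")
        if self.n_chains < 2:
            raise ConfigurationError("mcmc: n_chains must be >= 2 for R-hat")

    def with_seed(self, seed: int) -> "McmcSettings":
        return McmcSettings(self.n_draws, self.burn_in, self.n_chains, seed, self.sampler)


# MCMC sizes used for the three models: 5,000 iterations for fertility and
# 10,000 for net-migration and population, burn-in 3,000 each.
DEFAULT_FERTILITY_MCMC = McmcSettings(n_draws=5_000, burn_in=3_000)
DEFAULT_MIGRATION_MCMC = McmcSettings(n_draws=10_000, burn_in=3_000)
DEFAULT_POPULATION_MCMC = McmcSettings(n_draws=10_000, burn_in=3_000)


@dataclass
class SyntheticWorldConfig:
    """Parameters of the synthetic demographic world.

    The generated world mimics the real inputs: person-weighted census
    microdata (10% samples), retrospective birth histories in CMC date
    encoding, and abridged life tables on five-year age groups and periods.
    """

    n_regions: int = 2
    divisions_per_region: int = 2
    census_years: tuple[int, ...] = (1976, 1987, 2005)
    age_min: int = 15
    age_max: int = 49
    base_population_scale: float = 500.0  # mean MWRA per (age, division) cell
    true_betas: tuple[float, float, float] = (0.0, 2.0, 4.0)
    migration_intensity: float = 0.08  # fraction moving per inter-census interval
    asfr_peak: float = 0.24  # births per woman-year at the modal age
    survival_level: float = 0.985  # 5px at age group 15-19, first period
    noise_sd: float = 0.05  # log-scale population noise (epsilon)
    u1_sd: float = 0.04  # age-division-time random effect sd
    u2_sd: float = 0.04  # division-region-time random effect sd
    sample_fraction: float = 0.10  # census sampling fraction; weight = 1/fraction
    count_noise: str = "poisson"  # or "lognormal"
    marital_logistic: tuple[float, float] = (0.25, 22.0)  # (slope, midpoint age)
    missing_previous_frac: float = 0.0  # share of rows with unknown previous unit
    survey_years: tuple[int, ...] = (1991, 1998, 2004, 2011, 2018)
    n_women_per_survey: int = 1_000
    projection_years: tuple[int, int] = (2000, 2030)
    seed: int = 0

    def __post_init__(self):
        for name in ("n_regions", "divisions_per_region", "n_women_per_survey"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1")
        if not (15 <= self.age_min <= self.age_max <= 49):
            raise ConfigurationError("age_min/age_max must satisfy 15 <= min <= max <= 49")
        if len(self.census_years) < 2:
            raise ConfigurationError("census_years: need at least two censuses")
        if not 0.0 <= self.migration_intensity <= 1.0:
            raise ConfigurationError("migration_intensity must be in [0, 1]")
        for name in ("survival_level", "sample_fraction"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ConfigurationError(f"{name} must be in (0, 1]")
        if self.asfr_peak < 0 or self.asfr_peak > 1:
            raise ConfigurationError("asfr_peak must be in [0, 1]")
        for name in ("base_population_scale", "noise_sd", "u1_sd", "u2_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")
        if not 0.0 <= self.missing_previous_frac < 1.0:
            raise ConfigurationError("missing_previous_frac must be in [0, 1)")
        if self.count_noise not in ("poisson", "lognormal"):
            raise ConfigurationError("count_noise must be 'poisson' or 'lognormal'")

    @property
    def ages(self) -> np.ndarray:
        return np.arange(self.age_min, self.age_max + 1)

    @property
    def register(self) -> AdminRegister:
        return AdminRegister.uniform(self.n_regions, self.divisions_per_region)

    @property
    def person_weight(self) -> float:
        return 1.0 / self.sample_fraction

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class PriorSettings:
    """Hyperpriors shared by the hierarchical models: independent normals on
    coefficients and half-normals on every scale parameter."""

    beta_sd: float = 10.0
    scale_sd: float = 1.0
    sigma_sd: float = 1.0
    # log-ASFR intercept prior; exp(asfr_log_mean) is the prior-median rate
    asfr_log_mean: float = -3.9
    asfr_log_sd: float = 1.5

    def __post_init__(self):
        for name in ("beta_sd", "scale_sd", "sigma_sd", "asfr_log_sd"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")

    def scaled(self, factor: float) -> "PriorSettings":
        return PriorSettings(
            beta_sd=self.beta_sd * factor,
            scale_sd=self.scale_sd * factor,
            sigma_sd=self.sigma_sd * factor,
            asfr_log_mean=self.asfr_log_mean,
            asfr_log_sd=self.asfr_log_sd * factor,
        )


def derive_stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31, so stages can be re-run
    independently of one another."""
    ss = np.random.SeedSequence([master_seed, abs(hash_stage(stage))])
    return int(ss.generate_state(1)[0] % (2**31))


def hash_stage(stage: str) -> int:
    # stable across processes (unlike built-in hash on str)
    h = 0
    for ch in stage:
        h = (h * 131 + ord(ch)) % (2**31)
    return h
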