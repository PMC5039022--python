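"""Synthetic aerial-survey scenarios with the statistical structure the
analysis pipeline assumes.

The generator emulates a systematic reconnaissance flight programme over
semi-arid rangeland counties: 5 km x 5 km sampling units, ~5.7% sampling
intensity, irregular survey years with gaps, overdispersed (NB2) unit-level
counts, declining wildlife and rising sheep-and-goat (shoat) populations, and
county covariate histories (exponential human population growth, linear
warming trends with interannual noise, weakly declining rainfall).

Truth is kept in a ledger so recovery tests can compare estimates against the
generating values.  All randomness flows through named substreams of a single
seed, so each stage can be regenerated independently and reproducibly.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import aggregate

__all__ = [
    "SpeciesSpec",
    "ScenarioConfig",
    "SyntheticTruth",
    "default_scenario",
    "substream",
    "build_truth",
    "simulate_survey",
    "simulate_units",
    "simulate_estimates",
    "simulate_covariates",
    "truth_summary",
    "write_scenario",
    "DEFAULT_UNIT_WEIGHTS",
]

#: Per-animal unit weights (kg) used to convert counts to biomass.
#: Synthetic defaults in the range of published rangeland herbivore unit
#: weights; NOT a canonical table -- supply your own for real analyses.
DEFAULT_UNIT_WEIGHTS = {
    "cattle": 180.0,
    "shoats": 30.0,
    "zebra": 200.0,
    "gazelle": 15.0,
    "wildebeest": 123.0,
    "giraffe": 750.0,
}


@dataclass(frozen=True)
class SpeciesSpec:
    """One simulated population: initial density and trend shape.

    trend: 'exponential' (abundance * exp(-rate * years), rate > 0 declines),
    'flat', or 'logistic' (increase toward carry_mult times the initial
    abundance at logistic rate ``rate``).
    """

    name: str
    density: float                  # animals / km^2 at the start year
    trend: str = "flat"
    rate: float = 0.0
    group: str = "wildlife"
    carry_mult: float = 2.0

    def __post_init__(self) -> None:
        if self.density < 0:
            raise ValueError(f"{self.name}: density must be >= 0")
        if self.trend not in ("exponential", "flat", "logistic"):
            raise ValueError(f"{self.name}: unknown trend {self.trend!r}")
        if self.trend == "logistic" and self.carry_mult <= 1:
            raise ValueError(f"{self.name}: carry_mult must exceed 1")

    def abundance(self, area: float, years_elapsed: float) -> float:
        n0 = self.density * area
        if self.trend == "flat" or n0 == 0:
            return n0
        if self.trend == "exponential":
            return n0 * np.exp(-self.rate * years_elapsed)
        cap = self.carry_mult * n0
        return cap / (1.0 + (cap / n0 - 1.0) * np.exp(-self.rate * years_elapsed))


@dataclass(frozen=True)
class ScenarioConfig:
    """Full description of a simulated monitoring programme."""

    county_areas: dict[str, float]
    species: tuple[SpeciesSpec, ...]
    survey_years: tuple[int, ...]
    start_year: int = 1977
    nb_shape_k: float = 5.0
    unit_area: float = 25.0              # km^2 (5 km x 5 km)
    sampling_fraction: float = 0.057
    units_per_survey: Optional[int] = None
    unit_area_cv: float = 0.0            # >0 simulates unequal unit areas
    covariate_years: tuple[int, int] = (1960, 2016)
    pop_1962: dict[str, float] = field(default_factory=dict)
    pop_growth_rate: float = 0.0335      # /yr, ~4.8-fold over 1962-2009
    rainfall_mean: float = 600.0         # mm
    rainfall_slope: float = -1.2         # mm / yr
    rainfall_sd: float = 80.0
    tmax_mean: float = 28.0              # deg C
    tmax_slope: float = 0.024            # deg C / yr (1.3 degC over 54 yr)
    tmin_mean: float = 16.0
    tmin_slope: float = 0.021
    temp_sd: float = 0.3
    pct_protected: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.sampling_fraction <= 1:
            raise ValueError("sampling_fraction must be in (0, 1]")
        if self.nb_shape_k <= 0:
            raise ValueError("nb_shape_k must be positive")
        if not self.survey_years:
            raise ValueError("survey_years is empty")
        for county, Z in self.county_areas.items():
            if Z <= 0:
                raise ValueError(f"county {county}: nonpositive area")
            N = int(Z // self.unit_area)
            n = self.n_units(county)
            if n > N:
                raise ValueError(
                    f"county {county}: design requires n={n} > N={N} units"
                )

    def total_units(self, county: str) -> int:
        return int(self.county_areas[county] // self.unit_area)

    def n_units(self, county: str) -> int:
        if self.units_per_survey is not None:
            return self.units_per_survey
        return max(2, int(round(self.sampling_fraction * self.total_units(county))))


def default_scenario(seed: int = 0, **overrides) -> ScenarioConfig:
    """The reference scenario: three counties, four species, 1977-2016.

    Wildlife decline exponentially at 0.0288/yr (~67.5% over 39 years),
    cattle decline gently, shoats increase logistically; surveys skip seven
    years to mimic irregular monitoring.  Overrides may come from a parsed
    YAML config: species given as mappings are coerced to
    :class:`SpeciesSpec` and survey_years to a tuple.
    """
    if "species" in overrides:
        overrides["species"] = tuple(
            sp if isinstance(sp, SpeciesSpec) else SpeciesSpec(**sp)
            for sp in overrides["species"]
        )
    if "survey_years" in overrides:
        overrides["survey_years"] = tuple(int(y) for y in overrides["survey_years"])
    gaps = {1982, 1986, 1992, 1999, 2003, 2008, 2012}
    cfg = ScenarioConfig(
        county_areas={"Amaro": 9000.0, "Baruk": 23000.0, "Chalbi": 45000.0},
        species=(
            SpeciesSpec("cattle", 9.0, "exponential", 0.0074, "livestock"),
            SpeciesSpec("shoats", 8.0, "logistic", 0.05, "livestock"),
            SpeciesSpec("zebra", 1.2, "exponential", 0.0288, "wildlife"),
            SpeciesSpec("gazelle", 2.0, "exponential", 0.0288, "wildlife"),
        ),
        survey_years=tuple(y for y in range(1977, 2017) if y not in gaps),
        pop_1962={"Amaro": 150_000.0, "Baruk": 320_000.0, "Chalbi": 90_000.0},
        pct_protected={"Amaro": 18.0, "Baruk": 7.5, "Chalbi": 2.0},
        seed=seed,
    )
    return replace(cfg, **overrides) if overrides else cfg


def substream(seed: int, *parts) -> np.random.Generator:
    """Named, order-independent random substream of a master seed."""
    keys = [zlib.crc32(str(p).encode()) for p in parts]
    return np.random.default_rng(np.random.SeedSequence([int(seed) % 2**31, *keys]))


@dataclass
class SyntheticTruth:
    """Generating values behind a scenario: abundances and covariates."""

    abundance: pd.DataFrame      # county, species, year, abundance
    covariates: pd.DataFrame     # county, year, covariate columns


def build_truth(config: ScenarioConfig) -> SyntheticTruth:
    yr_lo, yr_hi = min(config.survey_years), max(config.survey_years)
    recs = []
    for county, area in config.county_areas.items():
        for sp in config.species:
            for year in range(yr_lo, yr_hi + 1):
                recs.append(
                    {
                        "county": county, "species": sp.name, "year": year,
                        "abundance": sp.abundance(area, year - config.start_year),
                    }
                )
    return SyntheticTruth(
        abundance=pd.DataFrame(recs), covariates=simulate_covariates(config)
    )


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, k: float) -> np.ndarray:
    """NB2 draws via the gamma-Poisson mixture (valid for non-integer k)."""
    mean = np.asarray(mean, dtype=float)
    lam = np.where(mean > 0, rng.gamma(k, np.maximum(mean, 1e-300) / k), 0.0)
    return rng.poisson(lam)


def simulate_survey(
    config: ScenarioConfig, county: str, year: int
) -> pd.DataFrame:
    """Unit-level counts for one survey: one row per (unit, species).

    Columns: county, date (decimal year), unit_id, unit_area_km2, species,
    count, plus design constants zone_area_km2 and total_units_N.  Counts are
    NB2 with mean = true density x unit area and shape ``nb_shape_k``.
    """
    if year not in config.survey_years:
        raise ValueError(f"{year} is not a survey year")
    if county not in config.county_areas:
        raise KeyError(f"unknown county {county!r}")
    Z = config.county_areas[county]
    N = config.total_units(county)
    n = config.n_units(county)
    rng = substream(config.seed, "survey", county, year)
    date = year + float(rng.uniform(0.1, 0.9))

    if config.unit_area_cv > 0:
        shape = 1.0 / config.unit_area_cv**2
        areas = rng.gamma(shape, config.unit_area / shape, size=n)
    else:
        areas = np.full(n, config.unit_area)

    frames = []
    for sp in config.species:
        true_density = sp.abundance(Z, year - config.start_year) / Z
        counts = _nb_counts(rng, true_density * areas, config.nb_shape_k)
        frames.append(
            pd.DataFrame(
                {
                    "county": county, "date": date,
                    "unit_id": np.arange(1, n + 1),
                    "unit_area_km2": areas, "species": sp.name, "count": counts,
                    "zone_area_km2": Z, "total_units_N": N,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def simulate_units(config: ScenarioConfig) -> pd.DataFrame:
    """All surveys of the scenario stacked into one unit-level table."""
    frames = [
        simulate_survey(config, county, year)
        for county in config.county_areas
        for year in config.survey_years
    ]
    return pd.concat(frames, ignore_index=True)


def simulate_estimates(config: ScenarioConfig) -> pd.DataFrame:
    """Survey-level population estimates drawn NB2 around the truth.

    The estimate-level granularity used by trend-model tests: one row per
    (county, species, survey date) with columns county, species, date,
    estimate, se.  The SE column carries the nominal design SE
    (estimate / sqrt(n_units)), provided for schema completeness.
    """
    recs = []
    for county, Z in config.county_areas.items():
        for year in config.survey_years:
            rng = substream(config.seed, "estimates", county, year)
            date = year + float(rng.uniform(0.1, 0.9))
            for sp in config.species:
                true_abund = sp.abundance(Z, year - config.start_year)
                est = int(_nb_counts(rng, np.array([true_abund]), config.nb_shape_k)[0])
                recs.append(
                    {
                        "county": county, "species": sp.name, "date": date,
                        "estimate": est,
                        "se": est / np.sqrt(config.n_units(county)),
                    }
                )
    return pd.DataFrame(recs)


def simulate_covariates(config: ScenarioConfig) -> pd.DataFrame:
    """County-year covariate histories.

    Human population follows exact exponential growth between anchor years;
    temperatures are linear warming trends plus Gaussian noise; rainfall is a
    mean plus linear trend plus noise, floored at a small positive value.
    """
    yr_lo, yr_hi = config.covariate_years
    if yr_hi < yr_lo:
        raise ValueError("empty covariate year range")
    years = np.arange(yr_lo, yr_hi + 1)
    frames = []
    for county, Z in config.county_areas.items():
        rng = substream(config.seed, "covariates", county)
        pop0 = config.pop_1962.get(county, 10.0 * Z)
        pop = pop0 * np.exp(config.pop_growth_rate * (years - 1962))
        rain = (
            config.rainfall_mean
            + config.rainfall_slope * (years - yr_lo)
            + (rng.normal(0.0, config.rainfall_sd, years.size)
               if config.rainfall_sd > 0 else 0.0)
        )
        tmax = (
            config.tmax_mean
            + config.tmax_slope * (years - yr_lo)
            + (rng.normal(0.0, config.temp_sd, years.size)
               if config.temp_sd > 0 else 0.0)
        )
        tmin = (
            config.tmin_mean
            + config.tmin_slope * (years - yr_lo)
            + (rng.normal(0.0, config.temp_sd, years.size)
               if config.temp_sd > 0 else 0.0)
        )
        frames.append(
            pd.DataFrame(
                {
                    "county": county, "year": years,
                    "human_population": pop, "human_density": pop / Z,
                    "annual_rainfall": np.maximum(rain, 1.0),
                    "tmax_mean": tmax, "tmin_mean": tmin,
                    "pct_protected": config.pct_protected.get(county, 5.0),
                    "county_area_km2": Z,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def truth_summary(
    truth: SyntheticTruth,
    period_a: tuple[int, int],
    period_b: tuple[int, int],
) -> pd.Series:
    """True percent change per species between two periods.

    Uses the same arithmetic as the pipeline: period means of the
    cross-county total abundance, then 100 * (B - A) / A.
    """
    df = truth.abundance
    for lo, hi in (period_a, period_b):
        if not ((df["year"] >= lo) & (df["year"] <= hi)).any():
            raise ValueError(f"period {lo}-{hi} outside the simulated range")
    total = df.groupby(["species", "year"])["abundance"].sum().reset_index()
    out = {}
    for species, grp in total.groupby("species"):
        mean_a = grp[grp["year"].between(*period_a)]["abundance"].mean()
        mean_b = grp[grp["year"].between(*period_b)]["abundance"].mean()
        out[species] = aggregate.percent_change(mean_a, mean_b)
    return pd.Series(out, name="true_percent_change")


def write_scenario(config: ScenarioConfig, outdir) -> dict[str, str]:
    """Materialize a scenario as the pipeline's CSV inputs.

    Writes units.csv, design.csv, estimates.csv, covariates.csv, truth.csv;
    returns the path of each.
    """
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    units = simulate_units(config)
    design = (
        units[["county", "date", "zone_area_km2", "total_units_N"]]
        .drop_duplicates()
        .reset_index(drop=True)
    )
    truth = build_truth(config)
    paths = {}
    tables = {
        "units": units.drop(columns=["zone_area_km2", "total_units_N"]),
        "design": design,
        "estimates": simulate_estimates(config),
        "covariates": truth.covariates,
        "truth": truth.abundance,
    }
    for name, df in tables.items():
        path = outdir / f"{name}.csv"
        df.to_csv(path, index=False)
        paths[name] = str(path)
    return paths
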