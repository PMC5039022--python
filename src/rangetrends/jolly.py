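"""Jolly's Method 2 population estimation for aerial strip transects.

Design-based ratio estimation for systematic reconnaissance flights in which
transects (and hence sampling units) may have unequal areas.  With zone area
Z, N sampling units in the zone, n sampled units with areas z_i and animal
counts y_i, the density ratio is R_hat = sum(y) / sum(z), the population total
Y_hat = Z * R_hat, and

    Var(Y_hat) = N (N - n) / n * (s_y^2 - 2 R_hat s_zy + R_hat^2 s_z^2)

with s_y^2, s_z^2 the sample variances of counts and unit areas and s_zy their
sample covariance (all with n - 1 denominators).  The N (N - n) / n factor is
the finite-population correction: a complete census (n = N) has zero variance,
as does a sample in which counts are exactly proportional to unit areas.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["SurveySample", "PopulationEstimate", "jolly_method2", "estimate_all"]


@dataclass(frozen=True)
class SurveySample:
    """Unit-level counts for one species in one survey of one census zone."""

    zone_area: float            # Z, km^2
    total_units: int            # N, sampling units in the zone
    unit_areas: np.ndarray      # z_i, km^2, one per sampled unit
    counts: np.ndarray          # y_i, animals counted per sampled unit
    county: str = ""
    species: str = ""
    survey_date: Optional[str] = None

    def __post_init__(self) -> None:
        z = np.asarray(self.unit_areas, dtype=float)
        y = np.asarray(self.counts, dtype=float)
        object.__setattr__(self, "unit_areas", z)
        object.__setattr__(self, "counts", y)
        if z.ndim != 1 or y.shape != z.shape or z.size < 1:
            raise ValueError("counts and unit areas must be 1-D and equally long")
        if np.any(z <= 0):
            raise ValueError("unit areas must be positive")
        if np.any(y < 0):
            raise ValueError("counts must be nonnegative")
        if z.size > self.total_units:
            raise ValueError(
                f"sampled units n={z.size} exceed total units N={self.total_units}"
            )
        if z.sum() > self.zone_area * (1 + 1e-9):
            raise ValueError("sampled area exceeds zone area")

    @property
    def n(self) -> int:
        return self.counts.size


@dataclass(frozen=True)
class PopulationEstimate:
    """Population total, SE and density for one species x county x date."""

    estimate: float             # Y_hat, animals
    se: float                   # SE(Y_hat), animals
    density: float              # R_hat, animals / km^2
    county: str = ""
    species: str = ""
    survey_date: Optional[str] = None
    n_units: int = 0
    variance_clamped: bool = False


def jolly_method2(sample: SurveySample) -> PopulationEstimate:
    """Estimate a population total and its standard error from one sample.

    Requires n >= 2 for a finite variance; with n == 1 the estimate is still
    returned but the variance is undefined and reported as NaN.  A negative
    variance (possible in finite samples) is clamped to zero with a warning.
    """
    y, z = sample.counts, sample.unit_areas
    n, N, Z = sample.n, sample.total_units, sample.zone_area
    total_z = z.sum()
    if total_z == 0:
        raise ZeroDivisionError("total sampled area is zero; density undefined")

    R_hat = y.sum() / total_z
    Y_hat = Z * R_hat

    if n < 2:
        logger.warning(
            "n=1 sample for %s/%s: variance undefined", sample.county, sample.species
        )
        return PopulationEstimate(
            estimate=Y_hat, se=float("nan"), density=R_hat,
            county=sample.county, species=sample.species,
            survey_date=sample.survey_date, n_units=n,
        )

    s_y2 = np.var(y, ddof=1)
    s_z2 = np.var(z, ddof=1)
    s_zy = np.cov(z, y, ddof=1)[0, 1]
    var = N * (N - n) / n * (s_y2 - 2.0 * R_hat * s_zy + R_hat**2 * s_z2)
    clamped = False
    if var < 0:
        logger.warning(
            "negative variance %.3g clamped to 0 for %s/%s on %s",
            var, sample.county, sample.species, sample.survey_date,
        )
        var, clamped = 0.0, True
    return PopulationEstimate(
        estimate=Y_hat, se=float(np.sqrt(var)), density=R_hat,
        county=sample.county, species=sample.species,
        survey_date=sample.survey_date, n_units=n, variance_clamped=clamped,
    )


def estimate_all(units: pd.DataFrame, design: pd.DataFrame) -> pd.DataFrame:
    """Apply Jolly's Method 2 to every (county, survey date, species) group.

    Parameters
    ----------
    units : long table with columns
        county, date, unit_id, unit_area_km2, species, count.
    design : one row per (county, date) with columns
        county, date, zone_area_km2, total_units_N.

    Returns
    -------
    DataFrame with columns county, species, date, estimate, se, density,
    n_units -- the survey-level estimates schema consumed by the trend model.
    """
    required = {"county", "date", "unit_id", "unit_area_km2", "species", "count"}
    missing = required - set(units.columns)
    if missing:
        raise ValueError(f"units table missing columns: {sorted(missing)}")
    dkey = design.set_index(["county", "date"])

    rows = []
    for (county, date, species), grp in units.groupby(
        ["county", "date", "species"], sort=True
    ):
        try:
            drow = dkey.loc[(county, date)]
        except KeyError:
            raise KeyError(
                f"no design constants (Z, N) for survey county={county!r} date={date!r}"
            ) from None
        sample = SurveySample(
            zone_area=float(drow["zone_area_km2"]),
            total_units=int(drow["total_units_N"]),
            unit_areas=grp["unit_area_km2"].to_numpy(),
            counts=grp["count"].to_numpy(),
            county=str(county), species=str(species), survey_date=str(date),
        )
        est = jolly_method2(sample)
        rows.append(
            {
                "county": county, "species": species, "date": date,
                "estimate": est.estimate, "se": est.se,
                "density": est.density, "n_units": est.n_units,
            }
        )
    return pd.DataFrame(rows)
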