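"""Aggregation of survey-level series: annual means, "national" sums,
period averages, percentage changes, and biomass rollups.

The conventions here mirror standard multi-county monitoring summaries:
estimates for years with multiple surveys are averaged to one value per
species per year; yearly values are summed across counties (model predictions
filling unsurveyed county-years) to an approximate national series; the
national series is averaged over reference periods and changes are expressed
as a percentage of the baseline-period mean.  Biomass is counts times
per-animal unit weight (kg), aggregated by group (wildlife vs livestock) and
distributed proportionally across counties.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd

__all__ = [
    "PeriodSpec",
    "annualize",
    "national_sum",
    "period_mean",
    "percent_change",
    "annualized_rate",
    "biomass_rollup",
    "county_shares",
]


@dataclass(frozen=True)
class PeriodSpec:
    """A labelled inclusive year range, with optional per-county end years.

    County overrides extend (or shorten) the period end for counties whose
    survey record runs later, e.g. a 2011-2013 reference period extended to
    2016 for a county surveyed through 2016.
    """

    label: str
    start_year: int
    end_year: int
    county_end_overrides: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.start_year > self.end_year:
            raise ValueError(f"period {self.label}: start > end")
        for county, end in self.county_end_overrides.items():
            if end < self.start_year:
                raise ValueError(f"override end {end} for {county} precedes start")

    def end_for(self, county: Optional[str]) -> int:
        if county is None:
            return self.end_year
        return int(self.county_end_overrides.get(county, self.end_year))

    def years_for(self, county: Optional[str] = None) -> range:
        return range(self.start_year, self.end_for(county) + 1)


def annualize(series: pd.DataFrame, value_col: str = "estimate") -> pd.DataFrame:
    """Average to one value per (county, species, year).

    Rows flagged ``include=False`` (graphically identified outliers supplied
    as an exclusion list) are dropped before averaging.  Single-survey years
    pass through unchanged.
    """
    if series.empty:
        raise ValueError("empty input series")
    df = series.copy()
    if "include" in df.columns:
        df = df[df["include"].astype(bool)]
    if "year" not in df.columns:
        df["year"] = df["date"].map(_year_of)
    out = (
        df.groupby(["county", "species", "year"], sort=True)[value_col]
        .mean()
        .reset_index()
    )
    return out


def national_sum(annual: pd.DataFrame, value_col: str = "estimate") -> pd.DataFrame:
    """Sum annual values across counties to a species x year total.

    Every county must contribute a value for every (species, year) it appears
    for; a missing county-year is an error (the trend model is expected to
    have filled unsurveyed years), never a silent zero.
    """
    counties = sorted(annual["county"].unique())
    pivot = annual.pivot_table(
        index=["species", "year"], columns="county", values=value_col, aggfunc="sum"
    )
    gaps = pivot.isna()
    if gaps.to_numpy().any():
        sp, yr = pivot.index[gaps.any(axis=1)][0]
        county = gaps.columns[gaps.loc[(sp, yr)]][0]
        raise ValueError(
            f"missing contribution: county={county!r} has no value for "
            f"species={sp!r} year={yr} (predict unsurveyed years first)"
        )
    out = pivot[counties].sum(axis=1).rename(value_col).reset_index()
    return out


def period_mean(
    annual: pd.DataFrame, period: PeriodSpec, value_col: str = "estimate"
) -> pd.Series:
    """Mean value per species over a reference period.

    If the table carries a ``county`` column, per-county end-year overrides
    are honored before any cross-county summation by the caller; each county
    contributes the mean over its own period window, and counties are summed.
    """
    if "county" in annual.columns:
        parts = []
        for county, grp in annual.groupby("county"):
            yrs = period.years_for(str(county))
            sel = grp[grp["year"].isin(yrs)]
            if sel.empty:
                raise ValueError(
                    f"period {period.label} has no overlap with county {county!r}"
                )
            parts.append(sel.groupby("species")[value_col].mean())
        return pd.concat(parts, axis=1).sum(axis=1, min_count=1).rename(value_col)
    sel = annual[annual["year"].isin(period.years_for(None))]
    if sel.empty:
        raise ValueError(f"period {period.label} has no overlap with the series")
    return sel.groupby("species")[value_col].mean().rename(value_col)


def percent_change(mean_a: float, mean_b: float) -> float:
    """Signed percent change from baseline mean_a to mean_b.

    100 * (b - a) / a; asymmetric by construction (baseline-referenced).
    """
    if mean_a <= 0:
        raise ValueError(f"baseline mean must be positive, got {mean_a}")
    return 100.0 * (mean_b - mean_a) / mean_a


def annualized_rate(total_percent: float, span_years: float) -> float:
    """Linear per-year average rate: total percent change / span in years."""
    if span_years <= 0:
        raise ValueError("span must be positive")
    return total_percent / span_years


def biomass_rollup(
    annual: pd.DataFrame,
    weights: Mapping[str, float],
    groups: Mapping[str, str],
    periods: list[PeriodSpec],
    value_col: str = "estimate",
) -> pd.DataFrame:
    """Aggregate biomass by group and period, with ratios and shares.

    Parameters
    ----------
    annual : per (county, species, year) abundance table.
    weights : species -> unit weight in kg per animal (must cover all species).
    groups : species -> group label (e.g. 'wildlife' / 'livestock').
    periods : reference periods over which yearly biomass is averaged.

    Returns a table with one row per (period, group): total biomass in kg,
    the group's share of all-group biomass (%), and the ratio of each group's
    biomass to every other group appended as columns 'ratio_to_<group>'.
    """
    species = sorted(annual["species"].unique())
    missing_w = [s for s in species if s not in weights]
    if missing_w:
        raise KeyError(f"no unit weight for species: {missing_w}")
    missing_g = [s for s in species if s not in groups]
    if missing_g:
        raise KeyError(f"no group assignment for species: {missing_g}")
    for s, w in weights.items():
        if s in species and w <= 0:
            raise ValueError(f"unit weight for {s} must be positive")

    df = annual.copy()
    df["biomass_kg"] = df[value_col] * df["species"].map(weights)
    df["group"] = df["species"].map(groups)

    rows = []
    for period in periods:
        pm = period_mean(
            df.rename(columns={"biomass_kg": "pm_value"}),
            period,
            value_col="pm_value",
        ).to_frame("biomass_kg")
        pm["group"] = pm.index.map(groups)
        by_group = pm.groupby("group")["biomass_kg"].sum()
        total = by_group.sum()
        for group, kg in by_group.items():
            row = {
                "period": period.label,
                "group": group,
                "biomass_kg": kg,
                "share_pct": 100.0 * kg / total,
            }
            for other, okg in by_group.items():
                if other != group:
                    row[f"ratio_to_{other}"] = kg / okg
            rows.append(row)
    return pd.DataFrame(rows)


def county_shares(
    annual: pd.DataFrame,
    weights: Mapping[str, float],
    period: PeriodSpec,
    value_col: str = "estimate",
) -> pd.DataFrame:
    """Proportional distribution of each species' biomass among counties.

    Shares sum to 100% per species within the period.
    """
    df = annual.copy()
    df["biomass_kg"] = df[value_col] * df["species"].map(weights)
    parts = []
    for county, grp in df.groupby("county"):
        yrs = period.years_for(str(county))
        sel = grp[grp["year"].isin(yrs)]
        if sel.empty:
            continue
        pm = sel.groupby("species")["biomass_kg"].mean().rename(county)
        parts.append(pm)
    wide = pd.concat(parts, axis=1).fillna(0.0)
    totals = wide.sum(axis=1)
    if (totals <= 0).any():
        bad = totals.index[totals <= 0].tolist()
        raise ValueError(f"zero total biomass in period {period.label}: {bad}")
    shares = wide.div(totals, axis=0) * 100.0
    out = shares.reset_index().melt(
        id_vars="species", var_name="county", value_name="share_pct"
    )
    out.insert(0, "period", period.label)
    return out


def _year_of(date) -> int:
    if isinstance(date, (int, np.integer)):
        return int(date)
    if isinstance(date, float):
        return int(np.floor(date))
    return pd.Timestamp(date).year
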