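"""End-to-end orchestration: simulate -> estimate -> trend -> aggregate ->
covariates, with a manifest for bit-stable reruns.

Each stage reads and writes plain CSV so any step can be replaced by real
survey data with the same schema.  The manifest records the seed, input
hashes, package version and per-stage timing; rerunning with the same config
and seed reproduces identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import aggregate as agg
from . import covariates as cov
from . import jolly, simulate, trend

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "StageError",
    "run_pipeline",
    "report",
    "trend_stage",
    "aggregate_stage",
    "covariate_stage",
]


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Pipeline configuration (loadable from YAML)."""

    outdir: str = "run"
    seed: int = 0
    simulate_scenario: bool = True
    units_csv: Optional[str] = None
    design_csv: Optional[str] = None
    estimates_csv: Optional[str] = None
    covariates_csv: Optional[str] = None
    exclusions_csv: Optional[str] = None
    spline_m: int = 20
    spline_d: int = 3
    spline_r: int = 3
    periods: list[dict] = field(default_factory=lambda: [
        {"label": "baseline", "start_year": 1977, "end_year": 1980},
        {"label": "recent", "start_year": 2011, "end_year": 2013},
    ])
    unit_weights: dict[str, float] = field(
        default_factory=lambda: dict(simulate.DEFAULT_UNIT_WEIGHTS)
    )
    groups: dict[str, str] = field(default_factory=dict)
    selection_criterion: str = "aicc"
    scenario_overrides: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def period_specs(self) -> list[agg.PeriodSpec]:
        return [
            agg.PeriodSpec(
                label=p["label"], start_year=p["start_year"],
                end_year=p["end_year"],
                county_end_overrides=p.get("county_end_overrides", {}),
            )
            for p in self.periods
        ]


def trend_stage(
    estimates: pd.DataFrame,
    spline_m: int = 20,
    spline_d: int = 3,
    spline_r: int = 3,
) -> tuple[pd.DataFrame, dict, list[str]]:
    """Fit the SGLMM per county and predict every year in the record.

    Returns (predictions, per-county diagnostics, warnings).
    """
    if "include" not in estimates.columns:
        estimates = estimates.assign(include=True)
    preds, diagnostics, warns = [], {}, []
    yr_range = (
        int(np.floor(estimates["date"].map(trend.decimal_year).min())),
        int(np.floor(estimates["date"].map(trend.decimal_year).max())),
    )
    for county, grp in estimates.groupby("county"):
        ds = trend.TrendDataset(grp)
        spec = trend.SplineSpec(
            domain=(
                float(ds.frame["t"].min()) - 1e-9,
                max(float(ds.frame["t"].max()), yr_range[1] + trend.JUNE_FRACTION)
                + 1e-9,
            ),
            m=spline_m, d=spline_d, r=spline_r,
        )
        mm = trend.assemble_design(ds, spec, predict_year_range=yr_range)
        fit = trend.fit_pql(mm)
        warns.extend(f"{county}: {w}" for w in fit.warnings)
        diagnostics[str(county)] = {
            "variance_components": fit.variance_components,
            "iterations": fit.n_iter,
            "dropped_species": mm.dropped_species,
        }
        preds.append(trend.predict_years(fit))
    return pd.concat(preds, ignore_index=True), diagnostics, warns


def aggregate_stage(
    annual: pd.DataFrame,
    periods: list[agg.PeriodSpec],
    weights: dict[str, float],
    groups: dict[str, str],
) -> dict[str, pd.DataFrame]:
    """National sums, period changes, biomass summary and county shares."""
    national = agg.national_sum(annual)
    period_means = {p.label: agg.period_mean(annual, p) for p in periods}
    changes = []
    if len(periods) >= 2:
        base = periods[0]
        for later in periods[1:]:
            for sp in period_means[base.label].index:
                changes.append(
                    {
                        "species": sp, "from": base.label, "to": later.label,
                        "mean_base": period_means[base.label][sp],
                        "mean_later": period_means[later.label][sp],
                        "percent_change": round(
                            agg.percent_change(
                                period_means[base.label][sp],
                                period_means[later.label][sp],
                            ),
                            1,
                        ),
                    }
                )
    rollup = agg.biomass_rollup(annual, weights, groups, periods)
    shares = pd.concat(
        [agg.county_shares(annual, weights, p) for p in periods],
        ignore_index=True,
    )
    return {
        "national_trends": national,
        "period_changes": pd.DataFrame(changes),
        "biomass_summary": rollup,
        "county_shares": shares,
    }


def covariate_stage(
    annual: pd.DataFrame,
    covariates_df: pd.DataFrame,
    criterion: str = "aicc",
    covariate_cols: tuple[str, ...] = (
        "human_density", "annual_rainfall", "tmax_mean", "tmin_mean",
    ),
) -> tuple[dict[str, pd.DataFrame], list[str]]:
    """Climate trend tests, univariate density curves, forward selection."""
    warns: list[str] = []
    clim_rows = []
    for county, grp in covariates_df.groupby("county"):
        for var in ("annual_rainfall", "tmax_mean", "tmin_mean"):
            res = cov.climate_trend_test(grp["year"], grp[var])
            clim_rows.append({"county": county, "variable": var, **res})

    merged = annual.merge(covariates_df, on=["county", "year"], how="inner")
    uni_rows, sel_rows = [], []
    for sp, grp in merged.groupby("species"):
        usable = [c for c in covariate_cols if grp[c].std(ddof=0) > 0]
        for cname in usable:
            try:
                fit = cov.select_density_form(
                    grp["estimate"], grp[cname], grp["county_area_km2"]
                )
            except (RuntimeError, ValueError) as err:
                warns.append(f"univariate fit {sp}/{cname} failed: {err}")
                continue
            peak = cov.peak_location(fit) if fit.form == "quadratic" else None
            uni_rows.append(
                {
                    "species": sp, "covariate": cname, "form": fit.form,
                    "aicc": fit.aicc,
                    **{f"coef_{k}": v for k, v in fit.params.items()},
                    "peak": peak,
                }
            )
        try:
            sel = cov.forward_select(
                grp["estimate"], grp[usable], grp["county_area_km2"],
                criterion=criterion,
            )
        except (RuntimeError, ValueError) as err:
            warns.append(f"forward selection for {sp} failed: {err}")
            continue
        for step in sel.trace:
            sel_rows.append({"species": sp, **step})
    return (
        {
            "climate_trends": pd.DataFrame(clim_rows),
            "univariate_fits": pd.DataFrame(uni_rows),
            "selection_trace": pd.DataFrame(sel_rows),
        },
        warns,
    )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write(df: pd.DataFrame, path: Path, manifest: dict) -> None:
    df.to_csv(path, index=False, float_format="%.10g")
    manifest["outputs"][path.name] = _sha256(path)


def run_pipeline(config: RunConfig) -> Path:
    """Execute all stages; returns the run directory.

    Halts with :class:`StageError` naming the failed stage.  A rerun with an
    identical config and seed produces byte-identical CSVs.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__, "seed": config.seed,
        "inputs": {}, "outputs": {}, "warnings": [], "timing_s": {},
    }

    def timed(stage):
        class _T:
            def __enter__(self):
                self.t0 = time.perf_counter()
                return self

            def __exit__(self, exc_type, exc, tb):
                manifest["timing_s"][stage] = round(time.perf_counter() - self.t0, 3)
                if exc is not None and not isinstance(exc, StageError):
                    raise StageError(stage, exc) from exc
        return _T()

    # --- simulate ---------------------------------------------------------
    with timed("simulate"):
        if config.simulate_scenario:
            scenario = simulate.default_scenario(
                seed=config.seed, **config.scenario_overrides
            )
            paths = simulate.write_scenario(scenario, outdir / "inputs")
            units = pd.read_csv(paths["units"])
            design = pd.read_csv(paths["design"])
            covariates_df = pd.read_csv(paths["covariates"])
            groups = config.groups or {
                sp.name: sp.group for sp in scenario.species
            }
            for name, p in paths.items():
                manifest["inputs"][f"{name}.csv"] = _sha256(Path(p))
        else:
            if not (config.units_csv and config.design_csv):
                raise ValueError("units_csv and design_csv required when not simulating")
            units = pd.read_csv(config.units_csv)
            design = pd.read_csv(config.design_csv)
            covariates_df = (
                pd.read_csv(config.covariates_csv) if config.covariates_csv else None
            )
            groups = dict(config.groups)
            for p in (config.units_csv, config.design_csv, config.covariates_csv):
                if p:
                    manifest["inputs"][Path(p).name] = _sha256(Path(p))

    # --- estimate ---------------------------------------------------------
    with timed("estimate"):
        estimates = jolly.estimate_all(units, design)
        if config.exclusions_csv:
            excl = pd.read_csv(config.exclusions_csv)
            key = ["county", "species", "date"]
            estimates = estimates.merge(
                excl[key].assign(_excluded=True), on=key, how="left"
            )
            estimates["include"] = estimates.pop("_excluded").isna()
        else:
            estimates["include"] = True
        _write(estimates, outdir / "estimates.csv", manifest)

    # --- trend ------------------------------------------------------------
    with timed("trend"):
        predictions, diagnostics, warns = trend_stage(
            estimates, config.spline_m, config.spline_d, config.spline_r
        )
        manifest["warnings"].extend(warns)
        _write(predictions, outdir / "trend_predictions.csv", manifest)
        (outdir / "fit_diagnostics.json").write_text(
            json.dumps(diagnostics, indent=2, default=float)
        )

    # --- aggregate --------------------------------------------------------
    with timed("aggregate"):
        annual = predictions.rename(columns={"pred": "estimate"})[
            ["county", "species", "year", "estimate"]
        ]
        weights = {
            s: config.unit_weights.get(s, simulate.DEFAULT_UNIT_WEIGHTS.get(s))
            for s in annual["species"].unique()
        }
        if None in weights.values():
            missing = [s for s, w in weights.items() if w is None]
            raise KeyError(f"no unit weight configured for species: {missing}")
        tables = aggregate_stage(annual, config.period_specs(), weights, groups)
        for name, df in tables.items():
            _write(df, outdir / f"{name}.csv", manifest)

    # --- covariates -------------------------------------------------------
    with timed("covariates"):
        if covariates_df is not None:
            tables, warns = covariate_stage(
                annual, covariates_df, criterion=config.selection_criterion
            )
            manifest["warnings"].extend(warns)
            for name, df in tables.items():
                _write(df, outdir / f"{name}.csv", manifest)

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return outdir


def report(run_dir) -> dict[str, pd.DataFrame]:
    """Headline tables from a completed run directory.

    Returns the national percent-change table and the biomass summary; raises
    if the run is incomplete.  A pure function of the run directory contents.
    """
    run_dir = Path(run_dir)
    needed = ["period_changes.csv", "biomass_summary.csv", "national_trends.csv"]
    for name in needed:
        if not (run_dir / name).exists():
            raise FileNotFoundError(f"incomplete run: {name} missing in {run_dir}")
    changes = pd.read_csv(run_dir / "period_changes.csv")
    biomass = pd.read_csv(run_dir / "biomass_summary.csv")
    tables = {"period_changes": changes, "biomass_summary": biomass}
    shares_path = run_dir / "county_shares.csv"
    if shares_path.exists():
        tables["county_shares"] = pd.read_csv(shares_path)
    return tables
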