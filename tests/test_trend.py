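"""SGLMM trend model: NB pmf, design assembly, PQL fitting, prediction."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

from rangetrends import simulate, trend
from rangetrends.splines import SplineSpec

from conftest import model_generated_dataset


class TestNbLogpmf:
    def test_geometric_special_case(self):
        # k=1 is geometric: P(0) = k/(mu+k) = 1/3 at mu=2
        assert np.exp(trend.nb_logpmf(0, 2.0, 1.0)) == pytest.approx(1 / 3)

    def test_poisson_limit(self):
        # log-pmf deviation is ~ (y-mu)^2 / 2k, so stay in the body
        y = np.arange(0, 16)
        nb = trend.nb_logpmf(y, 5.0, 1e6)
        poi = stats.poisson.logpmf(y, 5.0)
        assert np.abs(nb - poi).max() < 1e-4

    @pytest.mark.parametrize("mu,k", [(0.5, 0.3), (2.0, 1.0), (40.0, 5.0)])
    def test_normalization(self, mu, k):
        y = np.arange(0, 2000)
        assert np.exp(trend.nb_logpmf(y, mu, k)).sum() == pytest.approx(1.0, abs=1e-8)

    def test_invalid_y_rejected(self):
        with pytest.raises(ValueError):
            trend.nb_logpmf(-1, 2.0, 1.0)
        with pytest.raises(ValueError):
            trend.nb_logpmf(1.5, 2.0, 1.0)


class TestDecimalYear:
    def test_calendar_conversion(self):
        assert trend.decimal_year("1980-01-01") == pytest.approx(1980.0)
        assert trend.decimal_year("1980-12-31") == pytest.approx(1980.9973, abs=1e-3)

    def test_numeric_passthrough(self):
        assert trend.decimal_year(1995.45) == 1995.45


def _grid_dataset(n_surveys, missing_years, p, start=1977):
    """Dates with n_surveys surveys and the given missing years."""
    rng = np.random.default_rng(0)
    years = []
    yr = start
    while len(years) < n_surveys:
        if yr not in missing_years:
            years.append(yr)
        yr += 1
    dates = [y + 0.3 for y in years]
    # duplicate some years to reach n_surveys if needed
    while len(dates) < n_surveys:
        dates.append(years[0] + 0.7)
    rows = [
        {
            "county": "N",
            "species": f"sp{i:02d}",
            "date": d,
            "estimate": float(rng.integers(50, 5000)),
        }
        for d in dates
        for i in range(p)
    ]
    return trend.TrendDataset(pd.DataFrame(rows))


class TestAssembleDesign:
    def test_reference_bookkeeping_540_rows_273_random(self):
        """34 surveys + 11 unsurveyed years, 12 species: n = 540 grid rows;
        random-effect vector has 21 + 252 = 273 entries; fixed part has
        12 intercepts + 12 slopes."""
        # 34 surveys in 27 distinct years of 1977-2014, 11 years missing
        missing = {1980, 1984, 1988, 1991, 1995, 1999, 2002, 2005, 2008, 2011, 2013}
        surveyed = [y for y in range(1977, 2015) if y not in missing]
        assert len(surveyed) == 27
        dates = [y + 0.3 for y in surveyed] + [y + 0.7 for y in surveyed[:7]]
        assert len(dates) == 34
        rng = np.random.default_rng(1)
        rows = [
            {"county": "N", "species": f"sp{i:02d}", "date": d,
             "estimate": float(rng.integers(50, 5000))}
            for d in dates for i in range(12)
        ]
        ds = trend.TrendDataset(pd.DataFrame(rows))
        spec = SplineSpec(domain=(1977.0, 2014.9))
        mm = trend.assemble_design(ds, spec, predict_year_range=(1977, 2014))
        assert len(mm.grid) == (34 + 11) * 12 == 540
        assert mm.Z_common.shape == (540, 21)
        assert mm.Z_species.shape == (540, 252)
        assert mm.n_random == 273
        assert mm.X.shape == (540, 24)

    def test_single_species_block_equals_common_block(self):
        ds = _grid_dataset(6, set(), p=1)
        mm = trend.assemble_design(ds, SplineSpec(domain=(1976.9, 1983.9), m=2))
        np.testing.assert_allclose(mm.Z_species, mm.Z_common)

    def test_single_species_single_date_not_estimable(self):
        df = pd.DataFrame(
            [{"county": "N", "species": "a", "date": 1980.3, "estimate": 10.0}]
        )
        with pytest.raises(ValueError, match="2 distinct"):
            trend.assemble_design(trend.TrendDataset(df))

    def test_all_zero_species_dropped_with_record(self):
        df = pd.DataFrame(
            [
                {"county": "N", "species": s, "date": d, "estimate": e}
                for d in (1980.3, 1985.3, 1990.3)
                for s, e in (("a", 100.0), ("b", 0.0))
            ]
        )
        mm = trend.assemble_design(
            trend.TrendDataset(df), SplineSpec(domain=(1980.0, 1990.5), m=2)
        )
        assert mm.species == ["a"]
        assert mm.dropped_species == ["b"]

    def test_multiple_counties_rejected(self):
        df = pd.DataFrame(
            [
                {"county": c, "species": "a", "date": 1980.3, "estimate": 10.0}
                for c in ("A", "B")
            ]
        )
        with pytest.raises(ValueError, match="per county"):
            trend.TrendDataset(df)


class TestFitPql:
    def test_zero_variance_limit_matches_plain_nb_glm(self, small_scenario):
        """With both spline variance components pinned at zero and k fixed,
        PQL reduces to IRLS for the NB GLM of estimates on the fixed design
        with the species-mean offset (coefficients agree to 1e-6)."""
        est = simulate.simulate_estimates(small_scenario)
        ds = trend.TrendDataset(est)
        lo, hi = float(ds.frame.t.min()), float(ds.frame.t.max())
        mm = trend.assemble_design(
            ds, SplineSpec(domain=(lo - 1e-9, hi + 1e-9), m=6),
            fixed_species_slopes=False,
        )
        k = 4.0
        fit = trend.fit_pql(mm, fixed_k=k, fixed_variance=(0.0, 0.0))
        glm = sm.GLM(
            mm.y,
            mm.X[mm.fit_mask],
            family=sm.families.NegativeBinomial(alpha=1 / k),
            offset=mm.offset[mm.fit_mask],
        ).fit()
        np.testing.assert_allclose(fit.beta, glm.params, atol=1e-6)

    def test_constant_counts_single_species_flat_trend(self):
        df = pd.DataFrame(
            [
                {"county": "N", "species": "a", "date": y + 0.4, "estimate": 200.0}
                for y in range(1980, 2000)
            ]
        )
        ds = trend.TrendDataset(df)
        mm = trend.assemble_design(
            ds, SplineSpec(domain=(1980.0, 1999.9), m=4)
        )
        fit = trend.fit_pql(mm)
        pred = trend.predict_years(fit)
        assert pred["pred"].max() / pred["pred"].min() < 1.001
        assert fit.var_u1 <= 1e-8 and fit.var_u2 <= 1e-8

    def test_three_variance_components(self, fitted_trend):
        _, fit = fitted_trend
        assert set(fit.variance_components) == {"var_u1", "var_u2", "k"}

    def test_nonconvergence_raises_with_trace(self, small_scenario):
        est = simulate.simulate_estimates(small_scenario)
        ds = trend.TrendDataset(est)
        lo, hi = float(ds.frame.t.min()), float(ds.frame.t.max())
        mm = trend.assemble_design(ds, SplineSpec(domain=(lo - 1e-9, hi + 1e-9), m=6))
        with pytest.raises(trend.PQLConvergenceError) as excinfo:
            trend.fit_pql(mm, max_iter=1)
        assert excinfo.value.trace
        assert excinfo.value.last_fit is not None

    def test_offset_absorbs_species_scale(self, small_scenario):
        """Scaling one species' estimates by 10 changes its offset, not its
        fitted percent change (invariance up to NB rounding noise)."""
        est = simulate.simulate_estimates(small_scenario)

        def pct_changes(frame):
            ds = trend.TrendDataset(frame)
            lo, hi = float(ds.frame.t.min()), float(ds.frame.t.max())
            mm = trend.assemble_design(
                ds, SplineSpec(domain=(lo - 1e-9, hi + 1e-9), m=6)
            )
            fit = trend.fit_pql(mm)
            pred = trend.predict_years(fit)
            out = {}
            for sp, g in pred.groupby("species"):
                a = g[g.year.between(1977, 1980)].pred.mean()
                b = g[g.year.between(2011, 2016)].pred.mean()
                out[sp] = 100 * (b - a) / a
            return out

        base = pct_changes(est)
        scaled_frame = est.copy()
        sel = scaled_frame.species == "zebra"
        scaled_frame.loc[sel, "estimate"] *= 10
        scaled = pct_changes(scaled_frame)
        for sp in base:
            assert scaled[sp] == pytest.approx(base[sp], rel=1e-3, abs=0.05)

    def test_row_order_invariance(self, small_scenario):
        est = simulate.simulate_estimates(small_scenario)
        shuffled = est.sample(frac=1.0, random_state=9).reset_index(drop=True)

        def predictions(frame):
            ds = trend.TrendDataset(frame)
            lo, hi = float(ds.frame.t.min()), float(ds.frame.t.max())
            mm = trend.assemble_design(
                ds, SplineSpec(domain=(lo - 1e-9, hi + 1e-9), m=6)
            )
            fit = trend.fit_pql(mm)
            return (
                trend.predict_years(fit)
                .sort_values(["species", "year"])
                .reset_index(drop=True)
            )

        pd.testing.assert_frame_equal(
            predictions(est), predictions(shuffled), rtol=1e-6
        )


class TestPredictYears:
    def test_band_contains_point(self, fitted_trend):
        _, fit = fitted_trend
        pred = trend.predict_years(fit)
        assert (pred.lo95 <= pred.pred).all()
        assert (pred.pred <= pred.hi95).all()
        assert (pred.lo95 > 0).all()

    def test_observed_year_uses_survey_date_not_june(self, fitted_trend):
        mm, fit = fitted_trend
        grid = mm.grid
        observed_years = set(grid.loc[grid.is_observed, "year"])
        survey_dates = set(np.round(grid.loc[grid.is_observed, "t"], 9))
        for yr in observed_years:
            t_vals = grid.loc[grid.year == yr, "t"].unique()
            assert all(round(t, 9) in survey_dates for t in t_vals)
        missing = sorted(set(grid.year) - observed_years)
        assert missing  # scenario has gap years
        for yr in missing:
            t_vals = grid.loc[grid.year == yr, "t"].unique()
            assert np.allclose(t_vals, yr + trend.JUNE_FRACTION, atol=1e-9)

    def test_extrapolation_refused(self, fitted_trend):
        _, fit = fitted_trend
        with pytest.raises(ValueError, match="refusing to extrapolate"):
            trend.predict_years(fit, years=[2050])

    def test_pointwise_coverage_of_model_generated_data(self):
        """Pointwise 95% bands cover the generating mean between 90% and 99%
        of the time on dense, weakly overdispersed data simulated from the
        model itself."""
        cover = []
        for seed in range(200):
            est, truth, spec = model_generated_dataset(seed)
            ds = trend.TrendDataset(est)
            mm = trend.assemble_design(ds, spec)
            fit = trend.fit_pql(mm)
            pred = trend.predict_years(fit)
            m = pred.merge(truth, on=["species", "year"])
            cover.append(((m.mu >= m.lo95) & (m.mu <= m.hi95)).mean())
        assert 0.90 <= np.mean(cover) <= 0.99
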