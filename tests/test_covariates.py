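"""Covariate analyses: census interpolation, climate trends, NB density
curves, constant-variance fits, forward selection under strong hierarchy."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize

from rangetrends import covariates as cov


class TestInterpolateCensus:
    def test_anchor_reproduction(self):
        assert cov.interpolate_census(1000, 1962, 5000, 2009, 1962) == pytest.approx(1000)
        assert cov.interpolate_census(1000, 1962, 5000, 2009, 2009) == pytest.approx(5000)

    def test_doubling(self):
        p2 = 1000 * 2 ** (20 / 10)  # doubling every 10 years, anchors 20 apart
        assert cov.interpolate_census(1000, 2000, p2, 2020, 2010) == pytest.approx(2000)

    def test_rangelands_1979_closed_form(self):
        # anchors 2,604,900 (1962) and 12,582,028 (2009) -> ~4.60e6 in 1979
        val = cov.interpolate_census(2_604_900, 1962, 12_582_028, 2009, 1979)
        assert val == pytest.approx(4.60e6, rel=0.005)

    def test_multiplicative_consistency_of_chained_interpolation(self):
        p79 = cov.interpolate_census(2_604_900, 1962, 12_582_028, 2009, 1979)
        direct = cov.interpolate_census(2_604_900, 1962, 12_582_028, 2009, 1995)
        chained = cov.interpolate_census(p79, 1979, 12_582_028, 2009, 1995)
        assert chained == pytest.approx(direct, rel=1e-12)

    def test_nonpositive_population_rejected(self):
        with pytest.raises(ValueError):
            cov.interpolate_census(0, 1962, 100, 2009, 1980)


class TestClimateTrendTest:
    def test_perfect_line_exact_slope_tiny_p(self):
        years = np.arange(1960, 2014)
        res = cov.climate_trend_test(years, 15.0 + 0.02 * (years - 1960))
        assert res["slope"] == pytest.approx(0.02, rel=1e-9)
        assert res["p_value"] < 1e-12

    def test_constant_year_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            cov.climate_trend_test([2000, 2000, 2000], [1.0, 2.0, 3.0])

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError):
            cov.climate_trend_test([2000, 2001], [1.0, 2.0])

    def test_slope_recovery_on_noisy_series(self):
        rng = np.random.default_rng(0)
        years = np.arange(1960, 2014)
        slopes = []
        for _ in range(200):
            vals = 28 + 0.02 * (years - 1960) + rng.normal(0, 0.3, years.size)
            slopes.append(cov.climate_trend_test(years, vals)["slope"])
        mc_se = np.std(slopes, ddof=1) / np.sqrt(len(slopes))
        assert abs(np.mean(slopes) - 0.02) < 3 * mc_se


def simulate_nb_counts(rng, eta, k):
    mu = np.exp(eta)
    return rng.poisson(rng.gamma(k, mu / k))


class TestDensityCurve:
    def test_constant_covariate_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            cov.fit_density_curve([1, 2, 3], [5.0, 5.0, 5.0], [10.0] * 3)

    def test_loglinear_recovery_within_2se(self):
        """True beta recovered within 2 SEs in most replicates."""
        rng = np.random.default_rng(1)
        n, beta_true = 300, 0.4
        hits = 0
        n_rep = 25
        for _ in range(n_rep):
            x = rng.uniform(-2, 2, n)
            areas = rng.uniform(5, 50, n)
            y = simulate_nb_counts(rng, 1.0 + beta_true * x + np.log(areas), k=3.0)
            fit = cov.fit_density_curve(y, x, areas, "linear")
            se = fit.bse["beta"]
            hits += abs(fit.params["beta"] - beta_true) < 2 * se
        assert hits >= int(0.8 * n_rep)

    def test_aicc_prefers_quadratic_under_quadratic_truth(self):
        rng = np.random.default_rng(2)
        n = 500
        wins = 0
        n_rep = 20
        for _ in range(n_rep):
            x = rng.uniform(-2, 2, n)
            areas = np.full(n, 20.0)
            y = simulate_nb_counts(
                rng, 0.5 + 0.8 * x - 0.6 * x**2 + np.log(areas), k=4.0
            )
            best = cov.select_density_form(y, x, areas)
            wins += best.form == "quadratic"
        assert wins >= int(0.85 * n_rep)

    def test_aicc_parameter_count_includes_shape(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(-1, 1, 200)
        y = simulate_nb_counts(rng, 1.0 + 0.3 * x + np.log(20.0), k=3.0)
        fit = cov.fit_density_curve(y, x, np.full(200, 20.0), "linear")
        q = 3  # intercept, beta, NB shape
        expected = -2 * fit.loglike + 2 * q + 2 * q * (q + 1) / (200 - q - 1)
        assert fit.aicc == pytest.approx(expected)


class TestPeakLocation:
    def make_fit(self, beta, gamma):
        return cov.RegressionFit(
            params={"intercept": 0.0, "beta": beta, "gamma": gamma},
            form="quadratic", family="negbin", loglike=0.0, aicc=0.0,
        )

    def test_simple_peak(self):
        assert cov.peak_location(self.make_fit(2.0, -0.5)) == pytest.approx(2.0)

    def test_zero_beta_peaks_at_zero(self):
        assert cov.peak_location(self.make_fit(0.0, -0.5)) == 0.0

    def test_no_interior_maximum_returns_none(self):
        assert cov.peak_location(self.make_fit(1.0, 0.2)) is None

    def test_grid_search_oracle(self):
        rng = np.random.default_rng(4)
        grid = np.linspace(-50, 50, 20001)
        for _ in range(10):
            beta = rng.uniform(-2, 2)
            gamma = rng.uniform(-1.0, -0.05)
            peak = cov.peak_location(self.make_fit(beta, gamma))
            curve = np.exp(beta * grid + gamma * grid**2)
            assert abs(grid[np.argmax(curve)] - peak) <= (grid[1] - grid[0]) + 1e-12


class TestConstantVarianceCurve:
    def test_noiseless_exact_recovery(self):
        x = np.linspace(-2, 2, 60)
        y = np.exp(1.2 + 0.5 * x - 0.3 * x**2)
        fit = cov.fit_constant_variance_curve(y, x, "quadratic")
        assert fit.params["intercept"] == pytest.approx(1.2, abs=1e-6)
        assert fit.params["beta"] == pytest.approx(0.5, abs=1e-6)
        assert fit.params["gamma"] == pytest.approx(-0.3, abs=1e-6)

    def test_constant_response(self):
        x = np.linspace(0, 10, 30)
        y = np.full(30, 7.0)
        fit = cov.fit_constant_variance_curve(y, x, "quadratic")
        assert fit.params["beta"] == pytest.approx(0.0, abs=1e-8)
        assert fit.params["gamma"] == pytest.approx(0.0, abs=1e-8)
        assert fit.params["intercept"] == pytest.approx(np.log(7.0), abs=1e-8)

    def test_matches_independent_optimizer(self):
        """Same minimum as scipy's trust-region nonlinear least squares
        started elsewhere (independent optimizer cross-check)."""
        rng = np.random.default_rng(5)
        for seed in range(5):
            x = np.linspace(-1.5, 1.5, 50)
            y = np.exp(0.8 + 0.4 * x - 0.5 * x**2) + rng.normal(0, 0.1, 50)

            fit = cov.fit_constant_variance_curve(y, x, "quadratic")

            def resid(b):
                return np.exp(b[0] + b[1] * x + b[2] * x**2) - y

            oracle = optimize.least_squares(
                resid, [0.0, 0.0, -0.1], method="trf", xtol=1e-14, ftol=1e-14
            )
            ours = np.sum(resid(
                [fit.params["intercept"], fit.params["beta"], fit.params["gamma"]]
            ) ** 2)
            assert ours == pytest.approx(np.sum(oracle.fun**2), abs=1e-6)


def make_covariate_frame(rng, n, names=("hum", "liv", "prot", "rain", "tmax", "tmin")):
    return pd.DataFrame({c: rng.uniform(0, 10, n) for c in names})


class TestForwardSelect:
    def test_strong_hierarchy_never_violated(self):
        """Interactions and squares may enter only after their main effects,
        regardless of the data (randomized responses)."""
        rng = np.random.default_rng(6)
        for rep in range(5):
            n = 150
            X = make_covariate_frame(rng, n, names=("a", "b", "c"))
            y = rng.poisson(5.0, n)
            res = cov.forward_select(y, X, np.full(n, 20.0), criterion="aic")
            seen = set()
            for eff in res.selected:
                if "^2" in eff:
                    assert eff[:-2] in seen
                elif ":" in eff:
                    a, b = eff.split(":")
                    assert a in seen and b in seen
                seen.add(eff)

    def test_recovers_interaction_model(self):
        """Truth a + b + a:b at n = 1000: exact model recovered in most
        replicates under BIC."""
        rng = np.random.default_rng(7)
        n, n_rep, exact = 1000, 30, 0
        for _ in range(n_rep):
            X = make_covariate_frame(rng, n, names=("a", "b", "c", "d"))
            s = (X - X.mean()) / X.std(ddof=0)
            eta = 1.0 + 0.4 * s["a"] - 0.4 * s["b"] + 0.35 * s["a"] * s["b"] + np.log(20.0)
            y = simulate_nb_counts(rng, eta.to_numpy(), k=5.0)
            res = cov.forward_select(y, X, np.full(n, 20.0), criterion="bic")
            exact += sorted(res.selected) == ["a", "a:b", "b"]
        assert exact >= int(0.8 * n_rep)

    def test_pure_noise_selects_little_under_bic(self):
        rng = np.random.default_rng(8)
        small = 0
        n_rep = 20
        for _ in range(n_rep):
            n = 300
            X = make_covariate_frame(rng, n, names=("a", "b", "c", "d"))
            y = simulate_nb_counts(rng, np.full(n, 1.0 + np.log(20.0)), k=5.0)
            res = cov.forward_select(y, X, np.full(n, 20.0), criterion="bic")
            small += len(res.selected) <= 1
        assert small >= int(0.85 * n_rep)

    def test_standardized_and_original_scale_predictions_agree(self):
        rng = np.random.default_rng(9)
        n = 400
        X = make_covariate_frame(rng, n, names=("a", "b"))
        s = (X - X.mean()) / X.std(ddof=0)
        eta = 0.5 + 0.5 * s["a"] - 0.3 * s["b"] + 0.2 * s["a"] * s["b"] + np.log(20.0)
        y = simulate_nb_counts(rng, eta.to_numpy(), k=5.0)
        res = cov.forward_select(y, X, np.full(n, 20.0), criterion="aic")

        std = (X - pd.Series(res.means)) / pd.Series(res.sds)
        eta_std = np.full(n, res.params_standardized["intercept"])
        for eff, c in res.params_standardized.items():
            if eff == "intercept":
                continue
            eta_std = eta_std + c * cov._effect_column(eff, std)

        eta_orig = np.full(n, res.params_original["intercept"])
        for term, c in res.params_original.items():
            if term == "intercept":
                continue
            if "^2" in term:
                col = X[term[:-2]] ** 2
            elif ":" in term:
                a, b = term.split(":")
                col = X[a] * X[b]
            else:
                col = X[term]
            eta_orig = eta_orig + c * col.to_numpy()

        np.testing.assert_allclose(eta_orig, eta_std, atol=1e-8)

    def test_empty_candidates_returns_empty_model(self):
        rng = np.random.default_rng(10)
        y = rng.poisson(5.0, 50)
        with pytest.raises(ValueError, match="constant"):
            cov.forward_select(y, pd.DataFrame({"a": np.ones(50)}), np.full(50, 10.0))
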