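import numpy as np
import pandas as pd
import pytest

from rangetrends import simulate, trend
from rangetrends.splines import SplineSpec


@pytest.fixture(scope="session")
def small_scenario():
    """One county, four species, the default survey calendar."""
    return simulate.default_scenario(
        seed=7,
        county_areas={"Solo": 23000.0},
    )


@pytest.fixture(scope="session")
def fitted_trend(small_scenario):
    """A converged SGLMM fit on estimate-level synthetic data."""
    est = simulate.simulate_estimates(small_scenario)
    ds = trend.TrendDataset(est)
    lo, hi = float(ds.frame["t"].min()), float(ds.frame["t"].max())
    spec = SplineSpec(domain=(lo - 1e-9, hi + 1e-9), m=10)
    mm = trend.assemble_design(ds, spec)
    fit = trend.fit_pql(mm)
    return mm, fit


def model_generated_dataset(seed, n_species=2, m=10, k=1000.0,
                            var_u1=0.002, var_u2=0.001, years=(1977, 2016)):
    """Simulate estimates from the trend model itself (truth in its span).

    Returns (estimates frame, true mean table, spline spec) for coverage and
    recovery checks where the model must be correctly specified.
    """
    rng = np.random.default_rng(seed)
    dates = np.arange(years[0], years[1] + 1) + 0.5
    species = [chr(ord("a") + i) for i in range(n_species)]
    base = pd.DataFrame(
        [
            {"county": "Solo", "species": s, "date": d, "estimate": 1000.0}
            for d in dates
            for s in species
        ]
    )
    ds = trend.TrendDataset(base)
    spec = SplineSpec(domain=(dates.min() - 1e-9, dates.max() + 1e-9), m=m)
    mm = trend.assemble_design(ds, spec)
    p = len(mm.species)
    ds1 = mm.Z_common.shape[1]
    beta = np.concatenate([rng.normal(0, 0.3, p), rng.normal(0, 0.01, p)])
    u1 = rng.normal(0, np.sqrt(var_u1), ds1)
    u2 = rng.normal(0, np.sqrt(var_u2), ds1 * p)
    eta = mm.X @ beta + mm.Z_common @ u1 + mm.Z_species @ u2 + mm.offset
    mu = np.exp(eta)
    y = rng.poisson(rng.gamma(k, mu / k))
    est = base.copy()
    est["estimate"] = y.astype(float)
    truth = pd.DataFrame(
        {
            "species": base["species"],
            "year": base["date"].astype(int),
            "mu": mu,
        }
    )
    return est, truth, spec
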