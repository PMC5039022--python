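"""Anthropogenic and environmental covariate analyses.

Contents:

* intercensal interpolation of human population on an exponential growth path
  (r = ln(p2/p1) / t between census anchors);
* OLS tests for linear climate trends (warming slopes, rainfall decline);
* univariate negative-binomial density regressions with a log county-area
  offset, AICc choice between linear and quadratic forms, and the peak
  covariate value -beta/(2*gamma) of a log-quadratic response curve;
* constant-variance nonlinear (exp-polynomial) curve fits;
* forward model selection over standardized main effects, their squares and
  pairwise interactions under the strong-hierarchy (heredity) constraint.

Wording throughout targets association ("most strongly correlated"), not
causation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
import statsmodels.api as sm
from statsmodels.discrete.discrete_model import NegativeBinomial

logger = logging.getLogger(__name__)

__all__ = [
    "RegressionFit",
    "SelectionResult",
    "interpolate_census",
    "climate_trend_test",
    "fit_density_curve",
    "select_density_form",
    "peak_location",
    "fit_constant_variance_curve",
    "forward_select",
]


def interpolate_census(
    p1: float, year1: float, p2: float, year2: float, target_year: float
) -> float:
    """Population in a non-census year from two census anchors.

    Assumes exponential growth: r = ln(p2/p1)/(year2-year1) and
    P(t) = p1 * exp(r * (t - year1)).  Exact at both anchors and
    multiplicatively consistent across chained interpolations.
    """
    if p1 <= 0 or p2 <= 0:
        raise ValueError("census populations must be positive")
    if not year1 < year2:
        raise ValueError("census years must be ordered year1 < year2")
    r = np.log(p2 / p1) / (year2 - year1)
    return float(p1 * np.exp(r * (target_year - year1)))


def climate_trend_test(years: Sequence[float], values: Sequence[float]) -> dict:
    """OLS linear trend of an annual climate series with a two-sided t-test.

    Returns slope (units per year), its standard error, and the p-value.
    """
    years = np.asarray(years, dtype=float)
    values = np.asarray(values, dtype=float)
    if years.size < 3:
        raise ValueError("need at least 3 years for a trend test")
    if np.ptp(years) == 0:
        raise ValueError("year vector is constant")
    res = stats.linregress(years, values)
    return {
        "slope": float(res.slope),
        "se": float(res.stderr),
        "p_value": float(res.pvalue),
        "intercept": float(res.intercept),
    }


@dataclass
class RegressionFit:
    """A fitted density-covariate regression with information criteria."""

    params: dict[str, float]            # named mean-model coefficients
    form: str                           # 'linear' | 'quadratic'
    family: str                         # 'negbin' | 'constant-variance'
    loglike: float
    aicc: float
    nb_shape: Optional[float] = None    # k; Var = mu (1 + mu/k)
    scale: Optional[float] = None       # residual variance (constant-variance fits)
    n_obs: int = 0
    bse: dict[str, float] = field(default_factory=dict)


def _aicc(llf: float, q: int, n: int) -> float:
    """Corrected AIC; q counts every estimated parameter incl. NB shape."""
    if n - q - 1 <= 0:
        return np.inf
    return -2.0 * llf + 2.0 * q + 2.0 * q * (q + 1) / (n - q - 1)


def _nb_fit(y: np.ndarray, X: np.ndarray, offset: np.ndarray):
    """NB2 maximum-likelihood fit with a BFGS -> Nelder-Mead fallback.

    Convergence is checked explicitly, so the optimizer's own warnings are
    suppressed here.
    """
    import warnings

    model = NegativeBinomial(y, X, offset=offset, loglike_method="nb2")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = model.fit(disp=0, method="bfgs", maxiter=500)
            if not res.mle_retvals.get("converged", True):
                raise RuntimeError("bfgs not converged")
        except Exception:
            res = model.fit(disp=0, method="nm", maxiter=5000, maxfun=5000)
            if not res.mle_retvals.get("converged", True):
                raise RuntimeError(
                    "negative-binomial fit failed to converge "
                    f"(final llf {res.llf:.4g})"
                )
    return res


def fit_density_curve(
    counts: Sequence[float],
    covariate: Sequence[float],
    county_areas: Sequence[float],
    form: str = "linear",
) -> RegressionFit:
    """NB regression of counts on a covariate with log(county area) offset.

    The offset converts modelled counts to densities (animals per km^2).
    ``form='quadratic'`` adds the squared covariate; AICc uses
    q = mean parameters + 1 for the NB shape.
    """
    y = np.round(np.asarray(counts, dtype=float))
    x = np.asarray(covariate, dtype=float)
    areas = np.asarray(county_areas, dtype=float)
    if np.any(y < 0):
        raise ValueError("counts must be nonnegative")
    if form not in ("linear", "quadratic"):
        raise ValueError(f"unknown form {form!r}")
    if np.ptp(x) == 0:
        raise ValueError("covariate is constant; curve not identifiable")
    cols = {"intercept": np.ones_like(x), "beta": x}
    if form == "quadratic":
        if np.unique(x).size < 3:
            raise ValueError("quadratic form needs >= 3 distinct covariate values")
        cols["gamma"] = x**2
    X = np.column_stack(list(cols.values()))
    res = _nb_fit(y, X, offset=np.log(areas))
    names = list(cols.keys())
    params = dict(zip(names, res.params[: len(names)]))
    alpha = float(res.params[-1])
    q = len(names) + 1
    return RegressionFit(
        params=params,
        form=form,
        family="negbin",
        loglike=float(res.llf),
        aicc=_aicc(float(res.llf), q, y.size),
        nb_shape=1.0 / alpha if alpha > 0 else np.inf,
        n_obs=y.size,
        bse=dict(zip(names, res.bse[: len(names)])),
    )


def select_density_form(
    counts: Sequence[float],
    covariate: Sequence[float],
    county_areas: Sequence[float],
) -> RegressionFit:
    """Fit linear and quadratic NB curves; return the smaller-AICc fit."""
    lin = fit_density_curve(counts, covariate, county_areas, "linear")
    try:
        quad = fit_density_curve(counts, covariate, county_areas, "quadratic")
    except (ValueError, RuntimeError):
        return lin
    return quad if quad.aicc < lin.aicc else lin


def peak_location(fit: RegressionFit) -> Optional[float]:
    """Covariate value maximizing a log-quadratic density curve: -beta/(2 gamma).

    Returns None for gamma >= 0 (monotone curve, no interior maximum).  A
    negative computed peak means density is maximal at zero covariate
    (avoidance of the pressure the covariate measures).
    """
    if fit.form != "quadratic" or "gamma" not in fit.params:
        raise ValueError("peak location requires a quadratic fit")
    gamma = fit.params["gamma"]
    if gamma >= 0:
        return None
    return -fit.params["beta"] / (2.0 * gamma)


def fit_constant_variance_curve(
    response: Sequence[float],
    covariate: Sequence[float],
    form: str = "quadratic",
) -> RegressionFit:
    """Least-squares fit of response = exp(b0 + b1 x [+ b2 x^2]) + error.

    Homoscedastic alternative to the NB curve for continuous responses
    (biomass densities) where count-model confidence bands are too wide.
    The exp-polynomial mean matches the log-link NB mean curve.
    """
    y = np.asarray(response, dtype=float)
    x = np.asarray(covariate, dtype=float)
    if form not in ("linear", "quadratic"):
        raise ValueError(f"unknown form {form!r}")
    deg = 1 if form == "linear" else 2
    # warm start from a log-scale polynomial fit
    ylog = np.log(np.clip(y, max(y[y > 0].min() * 1e-3, 1e-12), None))
    b0 = np.polynomial.polynomial.polyfit(x, ylog, deg)

    def resid(b):
        return np.exp(np.polynomial.polynomial.polyval(x, b)) - y

    sol = optimize.least_squares(resid, b0, method="lm", max_nfev=10000)
    if not sol.success:
        raise RuntimeError(
            f"nonlinear fit diverged (residual norm {np.linalg.norm(sol.fun):.4g})"
        )
    names = ["intercept", "beta", "gamma"][: deg + 1]
    n = y.size
    sse = float(np.sum(sol.fun**2))
    sigma2 = sse / n
    llf = -0.5 * n * (np.log(2 * np.pi * sigma2) + 1.0)
    q = (deg + 1) + 1  # mean parameters + residual variance
    return RegressionFit(
        params=dict(zip(names, sol.x)),
        form=form,
        family="constant-variance",
        loglike=llf,
        aicc=_aicc(llf, q, n),
        scale=sigma2,
        n_obs=n,
    )


@dataclass
class SelectionResult:
    """Outcome of forward selection under strong hierarchy."""

    selected: list[str]                 # effect names in entry order
    trace: list[dict]                   # per-step criterion bookkeeping
    criterion: str
    final_criterion: float
    params_standardized: dict[str, float]
    params_original: dict[str, float]
    nb_shape: Optional[float]
    means: dict[str, float]
    sds: dict[str, float]


def _candidate_effects(names: Sequence[str]) -> list[str]:
    mains = list(names)
    squares = [f"{a}^2" for a in mains]
    inters = [f"{a}:{b}" for a, b in combinations(sorted(mains), 2)]
    return mains + squares + inters


def _eligible(effect: str, selected: set[str]) -> bool:
    """Strong hierarchy: squares need their main, interactions both mains."""
    if "^2" in effect:
        return effect[:-2] in selected
    if ":" in effect:
        a, b = effect.split(":")
        return a in selected and b in selected
    return True


def _effect_column(effect: str, std: pd.DataFrame) -> np.ndarray:
    if "^2" in effect:
        return std[effect[:-2]].to_numpy() ** 2
    if ":" in effect:
        a, b = effect.split(":")
        return (std[a] * std[b]).to_numpy()
    return std[effect].to_numpy()


def _criterion_value(res, q: int, n: int, criterion: str) -> float:
    llf = float(res.llf)
    if criterion == "aic":
        return -2 * llf + 2 * q
    if criterion == "aicc":
        return _aicc(llf, q, n)
    if criterion == "bic":
        return -2 * llf + q * np.log(n)
    raise ValueError(f"unknown criterion {criterion!r}")


def forward_select(
    counts: Sequence[float],
    covariates: pd.DataFrame,
    county_areas: Sequence[float],
    criterion: str = "aicc",
) -> SelectionResult:
    """Forward selection of density covariates under strong hierarchy.

    Candidates are the standardized main effects of every covariate column,
    their squares, and all pairwise interactions.  Starting from the
    intercept-only NB model, at each step the hierarchy-eligible effect with
    the largest criterion improvement enters; selection stops when no
    eligible effect improves the criterion.  Ties break toward the larger
    improvement, then alphabetically.  Coefficients are reported on both the
    standardized and the original covariate scales.
    """
    y = np.round(np.asarray(counts, dtype=float))
    areas = np.asarray(county_areas, dtype=float)
    offset = np.log(areas)
    n = y.size
    names = list(covariates.columns)
    means = {c: float(covariates[c].mean()) for c in names}
    sds = {c: float(covariates[c].std(ddof=0)) for c in names}
    for c in names:
        if sds[c] == 0:
            raise ValueError(f"covariate {c!r} is constant")
    std = (covariates - pd.Series(means)) / pd.Series(sds)

    candidates = _candidate_effects(names)
    selected: list[str] = []
    trace: list[dict] = []

    def fit_effects(effects: list[str]):
        X = np.column_stack(
            [np.ones(n)] + [_effect_column(e, std) for e in effects]
        )
        res = _nb_fit(y, X, offset=offset)
        q = X.shape[1] + 1  # + NB shape
        return res, _criterion_value(res, q, n, criterion)

    res, current = fit_effects([])
    trace.append({"step": 0, "entered": None, "criterion": current})

    while True:
        best = None
        for eff in candidates:
            if eff in selected or not _eligible(eff, set(selected)):
                continue
            try:
                cand_res, value = fit_effects(selected + [eff])
            except RuntimeError:
                logger.warning("candidate %s failed to converge; skipped", eff)
                continue
            improvement = current - value
            key = (improvement, eff)  # larger improvement, then alphabetical
            if improvement > 0 and (
                best is None
                or improvement > best[0] + 1e-12
                or (abs(improvement - best[0]) <= 1e-12 and eff < best[1])
            ):
                best = (improvement, eff, cand_res, value)
        if best is None:
            break
        _, eff, res, current = best
        selected.append(eff)
        trace.append({"step": len(selected), "entered": eff, "criterion": current})

    coef_names = ["intercept"] + selected
    params_std = dict(zip(coef_names, res.params[: len(coef_names)]))
    alpha = float(res.params[-1])
    return SelectionResult(
        selected=selected,
        trace=trace,
        criterion=criterion,
        final_criterion=current,
        params_standardized=params_std,
        params_original=_destandardize(params_std, means, sds),
        nb_shape=1.0 / alpha if alpha > 0 else np.inf,
        means=means,
        sds=sds,
    )


def _destandardize(
    params_std: dict[str, float], means: dict[str, float], sds: dict[str, float]
) -> dict[str, float]:
    """Expand coefficients on standardized terms to original-scale terms.

    Substitutes s_i = (x_i - m_i)/sd_i into each degree-<=2 term and collects
    the polynomial coefficients over {1, x_i, x_i^2, x_i x_j}.
    """
    out: dict[str, float] = {"intercept": params_std.get("intercept", 0.0)}

    def add(term: str, value: float) -> None:
        out[term] = out.get(term, 0.0) + value

    for eff, c in params_std.items():
        if eff == "intercept":
            continue
        if "^2" in eff:
            a = eff[:-2]
            m, s = means[a], sds[a]
            add(f"{a}^2", c / s**2)
            add(a, -2 * c * m / s**2)
            add("intercept", c * m**2 / s**2)
        elif ":" in eff:
            a, b = eff.split(":")
            ma, sa, mb, sb = means[a], sds[a], means[b], sds[b]
            add(eff, c / (sa * sb))
            add(a, -c * mb / (sa * sb))
            add(b, -c * ma / (sa * sb))
            add("intercept", c * ma * mb / (sa * sb))
        else:
            m, s = means[eff], sds[eff]
            add(eff, c / s)
            add("intercept", -c * m / s)
    return out
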