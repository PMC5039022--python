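"""Multivariate semiparametric negative-binomial mixed trend model.

Survey-level population estimates for all species in a county are modelled
jointly on the log scale as

    log mu = species intercepts + s1(t) + s2(t; species) + offset

where s1 is a penalized-spline trend common to all species, s2 a
species-specific penalized-spline trend (the smooth species x time
interaction), and the offset log(mean estimate of the species in the county)
absorbs interspecific differences in population size.  Counts are NB2:
Var(Y) = mu (1 + mu / k).  In the mixed-model representation of P-splines the
spline coefficients are random effects, u1 ~ N(0, s2_u1 I) of length ds1 and
u2 ~ N(0, s2_u2 I) of length ds1 * p, so the model carries exactly three
variance components: s2_u1, s2_u2 and the NB shape k.  The smoothing
parameters are estimated automatically as variance-component ratios.

Fitting is by residual penalized quasi-likelihood (pseudo-likelihood):
alternate (i) the working variate e = eta + (y - mu)/mu with weights
w = mu / (1 + mu/k), (ii) a REML-type linear-mixed-model solve updating
(s2_u1, s2_u2) and the BLUPs, and (iii) a Pearson moment-matching update of
k, until the parameters stabilize.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import linalg, optimize, special

from .splines import SplineSpec, basis_matrix, difference_matrix, mixed_model_design

logger = logging.getLogger(__name__)

__all__ = [
    "JUNE_FRACTION",
    "decimal_year",
    "nb_logpmf",
    "TrendDataset",
    "ModelMatrices",
    "SGLMMFit",
    "assemble_design",
    "fit_pql",
    "predict_years",
    "PQLConvergenceError",
]

#: Predictions for unsurveyed years are assigned to mid-June (day ~166).
JUNE_FRACTION = 0.45

_VAR_FLOOR = 1e-10
_K_MAX = 1e8


def decimal_year(date) -> float:
    """Calendar date -> decimal year; numeric input passes through."""
    if isinstance(date, (int, float, np.integer, np.floating)):
        return float(date)
    ts = pd.Timestamp(date)
    start = pd.Timestamp(year=ts.year, month=1, day=1)
    days = 366.0 if ts.is_leap_year else 365.0
    return ts.year + (ts.dayofyear - 1) / days


def nb_logpmf(y, mu, k):
    """Log-probability of the NB2 distribution, overflow-safe via log-gamma.

    P(Y=y) = Gamma(y+k) / (y! Gamma(k)) * (mu/(mu+k))^y * (k/(mu+k))^k.
    """
    y = np.asarray(y)
    if np.any(y < 0) or np.any(y != np.floor(y)):
        raise ValueError("y must be a nonnegative integer")
    mu = np.asarray(mu, dtype=float)
    k = np.asarray(k, dtype=float)
    if np.any(mu <= 0) or np.any(k <= 0):
        raise ValueError("mu and k must be positive")
    return (
        special.gammaln(y + k)
        - special.gammaln(y + 1)
        - special.gammaln(k)
        + y * (np.log(mu) - np.log(mu + k))
        + k * (np.log(k) - np.log(mu + k))
    )


@dataclass
class TrendDataset:
    """Survey estimates for one county, with outlier exclusion flags.

    ``frame`` columns: county, species, date, estimate and optionally
    ``include`` (False marks graphically identified outliers that stay in
    the table for plotting but are excluded from fitting).
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame.copy()
        required = {"county", "species", "date", "estimate"}
        if missing := required - set(df.columns):
            raise ValueError(f"trend dataset missing columns: {sorted(missing)}")
        if df["county"].nunique() != 1:
            raise ValueError("trend model is fitted per county; got multiple counties")
        if "include" not in df.columns:
            df["include"] = True
        df["t"] = df["date"].map(decimal_year)
        self.frame = df


@dataclass
class ModelMatrices:
    """Assembled design for the SGLMM over the full observation grid.

    The grid holds one row per (survey date or June placeholder) x species;
    placeholder rows for unsurveyed years carry no response and are used only
    for prediction.  Fitting uses rows with ``observed & include``.
    """

    grid: pd.DataFrame
    X: np.ndarray
    Z_common: np.ndarray
    Z_species: np.ndarray
    offset: np.ndarray
    y: np.ndarray                      # rounded response on fit rows
    y_raw: np.ndarray
    fit_mask: np.ndarray
    species: list[str]
    offsets_by_species: dict[str, float]
    spec: SplineSpec
    fixed_names: list[str]
    dropped_species: list[str] = field(default_factory=list)

    @property
    def n_random(self) -> int:
        return self.Z_common.shape[1] + self.Z_species.shape[1]


def assemble_design(
    dataset: TrendDataset,
    spec: Optional[SplineSpec] = None,
    fixed_species_slopes: bool = True,
    predict_year_range: Optional[tuple[int, int]] = None,
) -> ModelMatrices:
    """Build fixed/random design matrices, offsets and the observation grid.

    The grid is all surveys plus a mid-June placeholder row for every year in
    the prediction range without a survey, replicated over species, so that
    n = (n_surveys + n_missing_years) * p.  The fixed design holds species
    indicators (no global intercept) and, by default, a per-species linear
    time slope -- the parametric species x time interaction, giving p + p
    fixed columns.  The slopes matter structurally: the difference-penalty
    reparameterization places the polynomial null space of the penalty
    outside the random-effect span, so without unpenalized drift terms the
    model cannot represent a monotone trend and every fit is shrunk flat.
    ``fixed_species_slopes=False`` gives the intercepts-only variant.
    Random designs are the common-trend P-spline block (ds1 columns) and the
    block-diagonal species-specific P-spline block (ds1 * p columns).
    """
    df = dataset.frame
    obs_dates = np.sort(df["t"].unique())
    if obs_dates.size < 2:
        raise ValueError("need >= 2 distinct survey dates to model a trend")

    # species offsets: log mean estimate over included surveys
    inc = df[df["include"]]
    mean_est = inc.groupby("species")["estimate"].mean()
    dropped = sorted(mean_est.index[mean_est <= 0].tolist())
    if dropped:
        logger.warning("species with all-zero estimates dropped: %s", dropped)
    species = sorted(mean_est.index[mean_est > 0].tolist())
    p = len(species)
    if p == 0:
        raise ValueError("no species with positive estimates")
    offsets_by_species = {s: float(np.log(mean_est[s])) for s in species}

    yr_lo, yr_hi = (
        predict_year_range
        if predict_year_range is not None
        else (int(np.floor(obs_dates.min())), int(np.floor(obs_dates.max())))
    )
    surveyed_years = {int(np.floor(t)) for t in obs_dates}
    missing_years = [y for y in range(yr_lo, yr_hi + 1) if y not in surveyed_years]
    all_dates = np.sort(
        np.concatenate([obs_dates, [y + JUNE_FRACTION for y in missing_years]])
    )

    if spec is None:
        spec = SplineSpec(domain=(float(all_dates.min()), float(all_dates.max())))
    county = df["county"].iloc[0]

    # grid: dates x species, species fastest so blocks group by date
    grid_rows = []
    obs_lookup = df.set_index(["t", "species"])
    for t in all_dates:
        is_obs_date = t in obs_dates
        for s in species:
            row = {
                "county": county, "species": s, "t": t,
                "year": int(np.floor(t)), "is_observed": False,
                "estimate": np.nan, "include": True,
            }
            if is_obs_date and (t, s) in obs_lookup.index:
                rec = obs_lookup.loc[(t, s)]
                if isinstance(rec, pd.DataFrame):
                    rec = rec.iloc[0]
                row.update(
                    is_observed=True,
                    estimate=float(rec["estimate"]),
                    include=bool(rec["include"]),
                )
            grid_rows.append(row)
    grid = pd.DataFrame(grid_rows)

    sp_index = grid["species"].map({s: i for i, s in enumerate(species)}).to_numpy()
    n = len(grid)
    X = np.zeros((n, p))
    X[np.arange(n), sp_index] = 1.0
    fixed_names = [f"intercept[{s}]" for s in species]
    if fixed_species_slopes:
        tc = grid["t"].to_numpy() - grid["t"].mean()
        slopes = np.zeros((n, p))
        slopes[np.arange(n), sp_index] = tc
        X = np.hstack([X, slopes])
        fixed_names += [f"slope[{s}]" for s in species]
    if p == 1 and grid["t"].nunique() < 2:
        raise ValueError("single species with a single date is not estimable")

    U = basis_matrix(spec, grid["t"].to_numpy())
    Q = difference_matrix(spec.num_basis, spec.r)
    Zc_row = mixed_model_design(U, Q)            # n x ds1
    ds1 = Zc_row.shape[1]
    Zs = np.zeros((n, ds1 * p))
    for i in range(n):
        j = sp_index[i]
        Zs[i, j * ds1 : (j + 1) * ds1] = Zc_row[i]

    offset = grid["species"].map(offsets_by_species).to_numpy(dtype=float)
    fit_mask = (grid["is_observed"] & grid["include"]).to_numpy()
    y_raw = grid["estimate"].to_numpy(dtype=float)[fit_mask]
    return ModelMatrices(
        grid=grid, X=X, Z_common=Zc_row, Z_species=Zs, offset=offset,
        y=np.round(y_raw), y_raw=y_raw, fit_mask=fit_mask, species=species,
        offsets_by_species=offsets_by_species, spec=spec,
        fixed_names=fixed_names, dropped_species=dropped,
    )


class PQLConvergenceError(RuntimeError):
    """PQL failed to converge; carries the last iterate and the trace."""

    def __init__(self, message: str, last_fit=None, trace=None):
        super().__init__(message)
        self.last_fit = last_fit
        self.trace = trace or []


@dataclass
class SGLMMFit:
    """Converged SGLMM fit: coefficients, variance components, covariance."""

    beta: np.ndarray
    u_common: np.ndarray
    u_species: np.ndarray
    var_u1: float
    var_u2: float
    k: float
    cov: np.ndarray                 # joint covariance of (beta, u - u_hat)
    matrices: ModelMatrices
    converged: bool
    n_iter: int
    trace: list[dict]
    warnings: list[str] = field(default_factory=list)

    @property
    def variance_components(self) -> dict[str, float]:
        return {"var_u1": self.var_u1, "var_u2": self.var_u2, "k": self.k}

    def linear_predictor(self, rows: Optional[np.ndarray] = None) -> np.ndarray:
        mm = self.matrices
        eta = (
            mm.X @ self.beta
            + mm.Z_common @ self.u_common
            + mm.Z_species @ self.u_species
            + mm.offset
        )
        return eta if rows is None else eta[rows]


def _reml_nll(log_s2, e, X, Zb, dinv_w, active):
    """Negative REML log-likelihood at variance components exp(log_s2)."""
    V = np.diag(dinv_w)
    it = iter(log_s2)
    for j, Z in enumerate(Zb):
        s2 = active[j] if active[j] is not None else np.exp(next(it))
        if s2 > 0:
            V += s2 * (Z @ Z.T)
    try:
        c, low = linalg.cho_factor(V, check_finite=False)
    except linalg.LinAlgError:
        return 1e30
    logdet_V = 2.0 * np.sum(np.log(np.diag(c)))
    Vi_X = linalg.cho_solve((c, low), X, check_finite=False)
    XtViX = X.T @ Vi_X
    sign, logdet_P = np.linalg.slogdet(XtViX)
    if sign <= 0:
        return 1e30
    beta = np.linalg.solve(XtViX, Vi_X.T @ e)
    r = e - X @ beta
    Vi_r = linalg.cho_solve((c, low), r, check_finite=False)
    return 0.5 * (logdet_V + logdet_P + r @ Vi_r)


def _lmm_solve(e, X, Zb, w, s2):
    """Henderson mixed-model equations: returns beta, u blocks, covariance."""
    A = np.hstack([X] + list(Zb))
    p = X.shape[1]
    ncols = [Z.shape[1] for Z in Zb]
    Ginv = np.zeros(A.shape[1] - p)
    pos = 0
    for nc, s in zip(ncols, s2):
        Ginv[pos : pos + nc] = 1.0 / max(s, _VAR_FLOOR)
        pos += nc
    M = (A * w[:, None]).T @ A
    M[p:, p:] += np.diag(Ginv)
    rhs = (A * w[:, None]).T @ e
    C = np.linalg.inv(M)
    sol = C @ rhs
    beta = sol[:p]
    ublocks, pos = [], p
    for nc in ncols:
        ublocks.append(sol[pos : pos + nc])
        pos += nc
    return beta, ublocks, C


def _pearson_k_update(y, mu, dof):
    """Solve sum (y-mu)^2 / (mu (1 + mu/k)) = dof for the NB shape k."""
    resid2 = (y - mu) ** 2

    def stat(k):
        return float(np.sum(resid2 / (mu * (1 + mu / k))) - dof)

    if stat(_K_MAX) < 0:       # under-dispersed: Poisson limit
        return _K_MAX, True
    if stat(1e-4) > 0:
        return 1e-4, True
    return optimize.brentq(stat, 1e-4, _K_MAX, xtol=1e-10, rtol=1e-12), False


def fit_pql(
    matrices: ModelMatrices,
    k_init: float = 1.0,
    fixed_k: Optional[float] = None,
    fixed_variance: tuple[Optional[float], Optional[float]] = (None, None),
    rtol: float = 1e-6,
    max_iter: int = 100,
) -> SGLMMFit:
    """Fit the SGLMM by residual penalized quasi-likelihood.

    Parameters
    ----------
    matrices : output of :func:`assemble_design`.
    fixed_k : hold the NB shape fixed instead of moment-matching it.
    fixed_variance : hold either spline variance component fixed (e.g. at 0
        to recover a plain NB GLM of estimates on species indicators).
    rtol : maximum relative parameter change declaring convergence.
    """
    mm = matrices
    mask = mm.fit_mask
    y = mm.y
    X = mm.X[mask]
    Zb = [mm.Z_common[mask], mm.Z_species[mask]]
    offset = mm.offset[mask]
    n_obs, p_fixed = X.shape
    warnings: list[str] = []

    eta = np.log(np.maximum(y, 0.0) + 0.5)
    k = float(fixed_k) if fixed_k is not None else float(k_init)
    s2 = [0.1 if f is None else f for f in fixed_variance]
    beta = np.zeros(p_fixed)
    ublocks = [np.zeros(Z.shape[1]) for Z in Zb]
    C = None
    trace: list[dict] = []
    prev_obj = None
    converged = False

    for it in range(1, max_iter + 1):
        mu = np.exp(eta)
        w = mu / (1.0 + mu / k)
        e = eta + (y - mu) / mu - offset

        free = [j for j, f in enumerate(fixed_variance) if f is None]
        if free:
            active = list(fixed_variance)
            x0 = np.log([max(s2[j], _VAR_FLOOR) for j in free])
            res = optimize.minimize(
                _reml_nll, x0, args=(e, X, Zb, 1.0 / w, active),
                method="Nelder-Mead",
                options={"xatol": 1e-9, "fatol": 1e-11, "maxiter": 400},
            )
            for pos, j in enumerate(free):
                s2[j] = float(np.exp(res.x[pos]))
                if s2[j] < _VAR_FLOOR:
                    warnings.append(f"variance component {j + 1} clamped at floor")
                    s2[j] = _VAR_FLOOR
        obj = -_reml_nll(
            np.log([max(s, _VAR_FLOOR) for s in s2]), e, X, Zb, 1.0 / w,
            [None, None],
        ) if all(f is None for f in fixed_variance) else np.nan

        beta_new, ublocks_new, C = _lmm_solve(e, X, Zb, w, s2)
        eta_new = (
            X @ beta_new
            + sum(Z @ u for Z, u in zip(Zb, ublocks_new))
            + offset
        )
        mu_new = np.exp(np.clip(eta_new, -30, 30))

        k_clamped = False
        if fixed_k is None:
            k_new, k_clamped = _pearson_k_update(y, mu_new, n_obs - p_fixed)
        else:
            k_new = k

        old = np.concatenate([beta, *ublocks, s2, [k]])
        new = np.concatenate([beta_new, *ublocks_new, s2, [k_new]])
        # relative change, with the denominator floored at a small link-scale
        # magnitude so effectively-zero coefficients cannot stall convergence
        delta = float(np.max(np.abs(new - old) / (np.abs(old) + 1e-4)))
        trace.append(
            {
                "iter": it, "var_u1": s2[0], "var_u2": s2[1], "k": k_new,
                "delta": delta, "reml": obj,
            }
        )
        if prev_obj is not None and np.isfinite(obj) and obj < prev_obj - 1e-6:
            logger.debug("pseudo-likelihood decreased at iter %d", it)
        prev_obj = obj if np.isfinite(obj) else prev_obj

        beta, ublocks, k, eta = beta_new, ublocks_new, k_new, eta_new
        if k_clamped:
            warnings.append(f"NB shape hit bound at iter {it}")
        if delta < rtol:
            converged = True
            break

    fit = SGLMMFit(
        beta=beta, u_common=ublocks[0], u_species=ublocks[1],
        var_u1=s2[0], var_u2=s2[1], k=k, cov=C, matrices=mm,
        converged=converged, n_iter=it, trace=trace, warnings=warnings,
    )
    if not converged:
        raise PQLConvergenceError(
            f"PQL did not converge in {max_iter} iterations "
            f"(last max relative change {delta:.3g})",
            last_fit=fit, trace=trace,
        )
    return fit


def predict_years(
    fit: SGLMMFit, years: Optional[Sequence[int]] = None
) -> pd.DataFrame:
    """Predicted abundance per species x year with pointwise 95% bands.

    Observed years are predicted at their survey dates (then averaged within
    the year); unsurveyed years at mid-June.  The band is
    exp(eta_hat +/- 1.96 SE(eta_hat)) with SE from the joint covariance of
    (beta_hat, u_hat - u) at convergence, so it reflects both fixed-effect
    and spline-coefficient uncertainty.  Years outside the spline domain are
    refused.
    """
    mm = fit.matrices
    grid = mm.grid
    avail = sorted(grid["year"].unique())
    if years is None:
        years = avail
    lo, hi = mm.spec.domain
    for yr in years:
        if yr not in avail and not (lo <= yr + JUNE_FRACTION <= hi):
            raise ValueError(
                f"year {yr} is outside the fitted domain [{lo:.2f}, {hi:.2f}]; "
                "refusing to extrapolate"
            )

    A = np.hstack([mm.X, mm.Z_common, mm.Z_species])
    eta = fit.linear_predictor()
    se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", A, fit.cov, A), 0.0))

    recs = []
    for yr in years:
        sel = grid.index[grid["year"] == yr].to_numpy()
        sub = grid.loc[sel]
        for s in mm.species:
            rows = sel[sub["species"].to_numpy() == s]
            eta_r, se_r = eta[rows], se[rows]
            pred = float(np.mean(np.exp(eta_r)))
            lo95 = float(np.mean(np.exp(eta_r - 1.96 * se_r)))
            hi95 = float(np.mean(np.exp(eta_r + 1.96 * se_r)))
            recs.append(
                {
                    "county": grid["county"].iloc[0], "species": s, "year": yr,
                    "pred": pred, "lo95": lo95, "hi95": hi95,
                    "is_observed_year": bool(sub["is_observed"].any()),
                }
            )
    return pd.DataFrame(recs)
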