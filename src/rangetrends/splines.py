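"""Penalized B-spline (P-spline) bases and their mixed-model reparameterization.

A smooth trend s(t) is represented as a B-spline expansion with ``m`` equally
spaced interior knots and degree ``d``, giving ``K = m + d + 1`` basis
functions, and roughness is controlled by an r-th order difference penalty on
adjacent spline coefficients.  Penalized spline smoothing and linear mixed
modelling solve equivalent minimization problems: the penalized coefficients
become random effects via the reparameterization

    Z = U_tilde @ pinv(Q_r' Q_r) @ Q_r'

where ``U_tilde`` is the n x K basis evaluation matrix and ``Q_r`` the
(K-r) x K difference matrix.  A ridge penalty on the K-r transformed
coefficients then reproduces the difference-penalized fit, and the smoothing
parameter is estimated as a variance-component ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline

__all__ = [
    "SplineSpec",
    "build_knots",
    "basis_matrix",
    "difference_matrix",
    "mixed_model_design",
    "penalized_null_basis",
    "debug_dump",
]


@dataclass(frozen=True)
class SplineSpec:
    """Configuration of a P-spline smoother on a decimal-year time axis.

    Parameters
    ----------
    m : number of equally spaced interior knots (default 20).
    d : B-spline degree (default 3, cubic).
    r : order of the difference penalty on adjacent coefficients (default 3).
    domain : (start, end) of the time axis in decimal years.
    """

    domain: tuple[float, float]
    m: int = 20
    d: int = 3
    r: int = 3

    def __post_init__(self) -> None:
        lo, hi = self.domain
        if not lo < hi:
            raise ValueError(f"degenerate spline domain [{lo}, {hi}]")
        if self.m < 0 or self.d < 1 or self.r < 1:
            raise ValueError("require m >= 0, d >= 1, r >= 1")
        if self.num_basis <= self.r:
            raise ValueError(
                f"K = m + d + 1 = {self.num_basis} must exceed penalty order r = {self.r}"
            )

    @property
    def num_basis(self) -> int:
        """Number of B-spline basis columns, K = m + d + 1."""
        return self.m + self.d + 1

    @property
    def ds1(self) -> int:
        """Columns of the penalized random-effect design, K - r."""
        return self.num_basis - self.r


def build_knots(spec: SplineSpec) -> np.ndarray:
    """Full (clamped) knot vector for the spec.

    ``m`` equally spaced interior knots strictly inside the domain; the start
    date carries ``d`` additional stacked knots beyond the endpoint itself and
    the end date ``max(1, d)``, i.e. both boundaries have multiplicity d + 1.
    This yields exactly K = m + d + 1 basis functions that form a partition of
    unity on the closed domain.
    """
    lo, hi = spec.domain
    interior = np.linspace(lo, hi, spec.m + 2)[1:-1]
    return np.concatenate(
        [np.full(spec.d + 1, lo), interior, np.full(max(1, spec.d) + 1, hi)]
    )


def basis_matrix(spec: SplineSpec, x: np.ndarray) -> np.ndarray:
    """Evaluate the n x K B-spline basis U_tilde at points ``x``.

    Points must lie inside the closed domain; evaluation outside raises,
    because extrapolating a penalized trend is not meaningful.
    """
    x = np.asarray(x, dtype=float)
    lo, hi = spec.domain
    if np.any(x < lo) or np.any(x > hi):
        raise ValueError(
            f"evaluation points outside spline domain [{lo}, {hi}]: "
            f"range [{x.min()}, {x.max()}]"
        )
    t = build_knots(spec)
    U = BSpline.design_matrix(x, t, spec.d, extrapolate=False).toarray()
    if U.shape[1] != spec.num_basis:
        raise AssertionError("basis column bookkeeping violated")
    return U


def difference_matrix(K: int, r: int) -> np.ndarray:
    """(K-r) x K matrix of r-th order finite-difference coefficients.

    Row i applies the stencil of alternating-sign binomial coefficients to
    coefficients i..i+r; every row sums to zero, and the null space is the
    set of polynomial sequences of degree < r in the coefficient index.
    """
    if not K > r >= 1:
        raise ValueError(f"require K > r >= 1, got K={K}, r={r}")
    return np.diff(np.eye(K), n=r, axis=0)


def penalized_null_basis(K: int, r: int) -> np.ndarray:
    """K x r basis of the difference-penalty null space (index polynomials)."""
    idx = np.arange(K, dtype=float)
    return np.vander(idx, r, increasing=True)


def mixed_model_design(U_tilde: np.ndarray, Q_r: np.ndarray) -> np.ndarray:
    """Random-effect design Z = U_tilde @ pinv(Q_r' Q_r) @ Q_r'.

    The Moore-Penrose pseudo-inverse resolves the generalized inverse in the
    reparameterization uniquely and stably.  Z has K - r columns; a ridge
    penalty on its coefficients is equivalent to the r-th order difference
    penalty on the original B-spline coefficients (up to the unpenalized
    polynomial null space).
    """
    U_tilde = np.asarray(U_tilde, dtype=float)
    Q_r = np.asarray(Q_r, dtype=float)
    if U_tilde.shape[1] != Q_r.shape[1]:
        raise ValueError(
            f"nonconformable shapes: U_tilde {U_tilde.shape}, Q_r {Q_r.shape}"
        )
    Z = U_tilde @ np.linalg.pinv(Q_r.T @ Q_r) @ Q_r.T
    return Z


def debug_dump(spec: SplineSpec, x: np.ndarray, outdir) -> dict[str, str]:
    """Write knots, basis and design matrices to CSV for inspection.

    Diagnostic aid; returns the written paths.
    """
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    U = basis_matrix(spec, x)
    Q = difference_matrix(spec.num_basis, spec.r)
    Z = mixed_model_design(U, Q)
    paths = {}
    for name, arr in (
        ("knots", build_knots(spec)[None, :]),
        ("basis_U", U),
        ("penalty_Q", Q),
        ("design_Z", Z),
    ):
        p = outdir / f"{name}.csv"
        np.savetxt(p, arr, delimiter=",")
        paths[name] = str(p)
    return paths
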