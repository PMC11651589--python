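"""Natural cubic spline bases and the temperature cross-basis.

The exposure-response dimension of the temperature adjustment is a natural
cubic spline: piecewise cubic, twice continuously differentiable, and
constrained to be *linear* beyond its boundary knots.  The lag-response
dimension is a second natural cubic spline (with an intercept column) over
the integer lags.  Their tensor product — the cross-basis — lets a
conditional-logistic model absorb a jointly nonlinear
temperature-response / lag-response confounding surface with a small,
fixed number of columns.

The spline construction mirrors the classical approach: a cubic B-spline
basis on the full knot sequence is projected onto the null space of the
second-derivative constraints at the two boundary knots, which enforces
linearity in the tails.  Outside the boundary knots the basis is continued
by a first-order Taylor expansion at the nearest boundary, so extrapolation
is exactly linear.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.interpolate import BSpline

__all__ = ["SplineSpec", "CrossBasisSpec", "ns_basis", "cross_basis"]


@dataclass(frozen=True)
class SplineSpec:
    """Specification of a natural cubic spline basis.

    Parameters
    ----------
    df : int
        Number of basis columns.  Without an intercept this equals
        (number of interior knots) + 1; with an intercept, + 2.
    interior_knots : tuple of float, optional
        Explicit interior knot locations.  When omitted they are placed at
        equally spaced quantiles of the data passed to :func:`ns_basis`.
    boundary_knots : (float, float), optional
        Extremes beyond which the spline is linear.  Defaults to the
        observed data range.
    intercept : bool
        Whether the basis spans constants.
    """

    df: int = 4
    interior_knots: tuple[float, ...] | None = None
    boundary_knots: tuple[float, float] | None = None
    intercept: bool = False

    def __post_init__(self) -> None:
        if self.df < 2:
            raise ValueError(f"spline df must be >= 2, got {self.df}")
        if self.interior_knots is not None and self.boundary_knots is not None:
            lo, hi = self.boundary_knots
            if not all(lo < k < hi for k in self.interior_knots):
                raise ValueError("interior knots must lie strictly inside boundary knots")

    @property
    def n_interior(self) -> int:
        return self.df - (2 if self.intercept else 1)


@dataclass(frozen=True)
class CrossBasisSpec:
    """Tensor-product basis over a variable dimension and a lag dimension.

    Defaults give the main-model temperature adjustment: a 4-df natural
    cubic spline in temperature crossed with a natural cubic spline over
    lags 0..2 with an intercept and one interior knot at lag 1 — 4 x 3 = 12
    columns.
    """

    var: SplineSpec = SplineSpec(df=4)
    lag_range: tuple[int, int] = (0, 2)
    lag_knots: tuple[float, ...] = (1.0,)
    lag_intercept: bool = True

    def __post_init__(self) -> None:
        lo, hi = self.lag_range
        if not (0 <= lo < hi):
            raise ValueError(f"invalid lag range {self.lag_range}")
        if not all(lo < k < hi for k in self.lag_knots):
            raise ValueError("lag knots must lie strictly inside the lag range")

    @property
    def n_lags(self) -> int:
        return self.lag_range[1] - self.lag_range[0] + 1

    @property
    def df_lag(self) -> int:
        return len(self.lag_knots) + (2 if self.lag_intercept else 1)

    @property
    def df(self) -> int:
        return self.var.df * self.df_lag


def _resolve_knots(x: np.ndarray, spec: SplineSpec) -> SplineSpec:
    """Fill in knot locations from the data where the spec leaves them free."""
    boundary = spec.boundary_knots
    if boundary is None:
        boundary = (float(np.min(x)), float(np.max(x)))
    if boundary[0] >= boundary[1]:
        raise ValueError(f"degenerate boundary knots {boundary}")
    interior = spec.interior_knots
    if interior is None:
        n_int = spec.n_interior
        if n_int > 0:
            probs = np.arange(1, n_int + 1) / (n_int + 1)
            inside = x[(x >= boundary[0]) & (x <= boundary[1])]
            interior = tuple(float(q) for q in np.quantile(inside, probs))
        else:
            interior = ()
        if not all(boundary[0] < k < boundary[1] for k in interior):
            raise ValueError(
                f"quantile knots {interior} collide with boundary {boundary}; "
                "data too concentrated for the requested df"
            )
    if len(interior) != spec.n_interior:
        raise ValueError(
            f"df={spec.df} (intercept={spec.intercept}) needs {spec.n_interior} "
            f"interior knots, got {len(interior)}"
        )
    return replace(spec, interior_knots=tuple(interior), boundary_knots=boundary)


def _bspline_columns(t: np.ndarray, x: np.ndarray, deriv: int = 0) -> np.ndarray:
    """Evaluate every cubic B-spline on knot sequence t (rows: x, cols: basis)."""
    n_coef = len(t) - 4
    spl = BSpline(t, np.eye(n_coef), 3, extrapolate=False)
    if deriv:
        spl = spl.derivative(deriv)
    out = spl(np.asarray(x, dtype=float))
    return np.nan_to_num(out, nan=0.0)


def ns_basis(x: Sequence[float] | np.ndarray, spec: SplineSpec) -> tuple[np.ndarray, SplineSpec]:
    """Natural cubic spline design matrix.

    Returns the (n, df) basis matrix together with the spec with knots
    resolved, so the identical basis can be re-evaluated on new data
    (e.g. a prediction grid, or the reference value of an
    exposure-response curve).
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("x must be one-dimensional")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite values in spline input")
    spec = _resolve_knots(x, spec)
    lo, hi = spec.boundary_knots  # type: ignore[misc]
    t = np.concatenate([[lo] * 4, spec.interior_knots, [hi] * 4])  # type: ignore[arg-type]

    xc = np.clip(x, lo, hi)
    design = _bspline_columns(t, xc)
    # Linear continuation beyond the boundary knots (first-order Taylor).
    below, above = x < lo, x > hi
    for mask, knot in ((below, lo), (above, hi)):
        if mask.any():
            b0 = _bspline_columns(t, np.array([knot]))
            b1 = _bspline_columns(t, np.array([knot]), deriv=1)
            design[mask] = b0 + (x[mask, None] - knot) * b1

    const = _bspline_columns(t, np.array([lo, hi]), deriv=2)
    if not spec.intercept:
        design = design[:, 1:]
        const = const[:, 1:]
    # Null space of the two boundary curvature constraints.
    q = np.linalg.qr(const.T, mode="complete")[0]
    basis = design @ q[:, 2:]
    assert basis.shape[1] == spec.df
    return basis, spec


def cross_basis(
    temp_matrix: np.ndarray, spec: CrossBasisSpec
) -> tuple[np.ndarray, CrossBasisSpec]:
    """Build the tensor-product cross-basis from lagged temperatures.

    Parameters
    ----------
    temp_matrix : (n, L+1) array
        Column l holds the temperature at lag ``lag_range[0] + l`` for each
        observation.
    spec : CrossBasisSpec

    Returns
    -------
    (n, df_var * df_lag) matrix and the spec with the variable-dimension
    knots resolved (from the pooled lagged temperatures).  Column order is
    variable-major: column ``i * df_lag + j`` pairs variable basis i with
    lag basis j.
    """
    temp_matrix = np.asarray(temp_matrix, dtype=float)
    if temp_matrix.ndim != 2 or temp_matrix.shape[1] != spec.n_lags:
        raise ValueError(
            f"temperature matrix must have {spec.n_lags} lag columns, "
            f"got shape {temp_matrix.shape}"
        )
    flat = temp_matrix.ravel()
    var_basis, var_spec = ns_basis(flat, spec.var)
    n = temp_matrix.shape[0]
    v = var_basis.reshape(n, spec.n_lags, spec.var.df)

    lags = np.arange(spec.lag_range[0], spec.lag_range[1] + 1, dtype=float)
    lag_spec = SplineSpec(
        df=spec.df_lag,
        interior_knots=spec.lag_knots,
        boundary_knots=(float(lags[0]), float(lags[-1])),
        intercept=spec.lag_intercept,
    )
    lag_basis, _ = ns_basis(lags, lag_spec)

    cb = np.einsum("nlv,lj->nvj", v, lag_basis).reshape(n, spec.df)
    return cb, replace(spec, var=var_spec)
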