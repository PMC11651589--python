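"""Conditional logistic regression over matched sets.

The conditional likelihood for a matched set with exactly one case is

    P(case | set) = exp(x_case . beta) / sum_{j in set} exp(x_j . beta),

so the log-likelihood is sum over sets of [x_case.beta - logsumexp_j x_j.beta].
Set-specific intercepts — and with them every covariate constant within a
set — cancel; no intercept column is used.  The score and observed
information have closed forms (softmax-weighted within-set means and
covariances), so the MLE is found by Newton–Raphson with step-halving,
started at beta = 0, on a concave log-likelihood.

Monotone likelihoods (complete or quasi-complete separation) are detected
and flagged instead of reporting a spuriously huge finite estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .basis import CrossBasisSpec, SplineSpec, cross_basis, ns_basis

__all__ = [
    "DesignMatrix",
    "FitResult",
    "build_design",
    "conditional_loglik",
    "fit",
    "or_per_increment",
    "exposure_response_curve",
]


@dataclass
class DesignMatrix:
    """Member-day covariate matrix with matched-set structure.

    Rows are grouped by set (``set_start`` marks the first row of each set)
    and each set has exactly one ``is_case`` row.  ``term_map`` maps model
    terms to column index lists.  ``pm_spec`` holds the resolved spline
    spec when PM2.5 is spline-encoded (needed to evaluate the fitted
    exposure-response curve later).
    """

    X: np.ndarray
    is_case: np.ndarray
    set_start: np.ndarray
    set_id: np.ndarray
    colnames: list[str]
    term_map: dict[str, list[int]]
    pm_spec: SplineSpec | None = None
    temp_spec: CrossBasisSpec | None = None
    pm_values: np.ndarray | None = None
    degenerate_cols: list[str] = field(default_factory=list)

    @property
    def n_sets(self) -> int:
        return len(self.set_start)

    def set_sizes(self) -> np.ndarray:
        return np.diff(np.append(self.set_start, len(self.X)))


@dataclass
class FitResult:
    """Maximum conditional-likelihood fit.

    ``vcov`` is the inverse observed information at the MLE; Wald CIs and
    the Monte Carlo burden draws both come from it.
    """

    beta: np.ndarray
    vcov: np.ndarray
    loglik: float
    term_map: dict[str, list[int]]
    colnames: list[str]
    converged: bool
    n_iter: int
    grad_norm: float
    separation: bool = False
    n_sets: int = 0

    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.vcov))

    def coef(self, term: str) -> np.ndarray:
        return self.beta[self.term_map[term]]


def build_design(
    sets: pd.DataFrame,
    pm: str | SplineSpec = "linear",
    temp: CrossBasisSpec | None = CrossBasisSpec(),
    holiday: bool = True,
) -> DesignMatrix:
    """Assemble the design matrix from a long-format matched-set table.

    ``pm='linear'`` enters the exposure metric as a single column (the
    main model: OR per unit, reported per 10 ug/m3); passing a
    :class:`SplineSpec` instead encodes it as a natural cubic spline for
    the flexible exposure-response mode.  ``temp`` adds the lagged
    temperature cross-basis; ``holiday`` an indicator column.
    """
    sets = sets.sort_values(["set_id", "member_date"], kind="stable")
    set_id = sets["set_id"].to_numpy()
    change = np.flatnonzero(np.r_[True, set_id[1:] != set_id[:-1]])
    is_case = sets["is_case"].to_numpy(dtype=bool)
    counts = np.add.reduceat(is_case.astype(int), change)
    if not np.all(counts == 1):
        raise ValueError("every matched set must contain exactly one case day")

    blocks: list[np.ndarray] = []
    names: list[str] = []
    term_map: dict[str, list[int]] = {}
    pm_spec = None
    pm_values = sets["pm"].to_numpy(dtype=float)

    if pm == "linear":
        blocks.append(pm_values[:, None])
        term_map["pm"] = [0]
        names.append("pm")
    elif isinstance(pm, SplineSpec):
        basis, pm_spec = ns_basis(pm_values, pm)
        term_map["pm"] = list(range(basis.shape[1]))
        names += [f"pm_ns{i + 1}" for i in range(basis.shape[1])]
        blocks.append(basis)
    else:
        raise ValueError(f"pm must be 'linear' or a SplineSpec, got {pm!r}")

    temp_spec = None
    if temp is not None:
        lag_cols = [f"temp_lag_{l}" for l in range(temp.lag_range[0], temp.lag_range[1] + 1)]
        missing = [c for c in lag_cols if c not in sets.columns]
        if missing:
            raise ValueError(f"matched sets lack temperature lag columns {missing}")
        cb, temp_spec = cross_basis(sets[lag_cols].to_numpy(dtype=float), temp)
        start = sum(b.shape[1] for b in blocks)
        term_map["temp"] = list(range(start, start + cb.shape[1]))
        names += [f"temp_cb{i + 1}" for i in range(cb.shape[1])]
        blocks.append(cb)

    if holiday:
        start = sum(b.shape[1] for b in blocks)
        blocks.append(sets["holiday"].to_numpy(dtype=float)[:, None])
        term_map["holiday"] = [start]
        names.append("holiday")

    X = np.hstack(blocks)
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite covariate values in design matrix")

    # Columns with zero variance inside every set carry no conditional
    # information; flag them so callers can drop or report them.
    mins = np.minimum.reduceat(X, change, axis=0)
    maxs = np.maximum.reduceat(X, change, axis=0)
    degenerate = np.all(mins == maxs, axis=0)
    return DesignMatrix(
        X=X,
        is_case=is_case,
        set_start=change,
        set_id=set_id[change],
        colnames=names,
        term_map=term_map,
        pm_spec=pm_spec,
        temp_spec=temp_spec,
        pm_values=pm_values,
        degenerate_cols=[n for n, d in zip(names, degenerate) if d],
    )


def conditional_loglik(
    beta: np.ndarray, dm: DesignMatrix, order: int = 0
) -> float | tuple:
    """Conditional log-likelihood; optionally the score and observed information.

    ``order=0`` returns the scalar log-likelihood; ``order=1`` adds the
    analytic gradient; ``order=2`` adds the observed information matrix
    (negative Hessian).  The within-set log-sum-exp is max-shifted for
    stability.
    """
    beta = np.asarray(beta, dtype=float)
    X, start, is_case = dm.X, dm.set_start, dm.is_case
    eta = X @ beta
    set_max = np.maximum.reduceat(eta, start)
    sizes = dm.set_sizes()
    shifted = np.exp(eta - np.repeat(set_max, sizes))
    denom = np.add.reduceat(shifted, start)
    lse = set_max + np.log(denom)
    ll = float(eta[is_case].sum() - lse.sum())
    if order == 0:
        return ll

    p = shifted / np.repeat(denom, sizes)  # within-set softmax weights
    grad = X[is_case].sum(axis=0) - X.T @ p
    if order == 1:
        return ll, grad
    # Observed information: sum over sets of softmax covariance of rows.
    M = np.empty((dm.n_sets, X.shape[1]))
    np.add.reduceat(p[:, None] * X, start, axis=0, out=M)
    info = (X * p[:, None]).T @ X - M.T @ M
    return ll, grad, info


def fit(
    dm: DesignMatrix,
    max_iter: int = 100,
    rel_tol: float = 1e-10,
    grad_tol: float = 1e-6,
    separation_norm: float = 50.0,
) -> FitResult:
    """Newton–Raphson maximisation of the conditional likelihood.

    Starts at beta = 0, halves steps that fail to improve the concave
    log-likelihood, and declares convergence when both the relative
    log-likelihood change and the gradient norm fall under tolerance.
    A coefficient norm exceeding ``separation_norm`` on the log-odds scale
    while the likelihood is still climbing is reported as separation; no
    finite estimate exists then, and the result is flagged rather than
    silently divergent.
    """
    if np.all(dm.set_sizes() < 2):
        raise ValueError("no informative matched sets (all singletons)")
    k = dm.X.shape[1]
    beta = np.zeros(k)
    ll, grad, info = conditional_loglik(beta, dm, order=2)
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        try:
            step = linalg.cho_solve(linalg.cho_factor(info), grad)
        except linalg.LinAlgError:
            step = np.linalg.pinv(info) @ grad
        # Step-halving: the likelihood is concave, so a short enough
        # Newton step always improves it.
        scale, improved = 1.0, False
        for _ in range(30):
            cand = beta + scale * step
            ll_new = conditional_loglik(cand, dm)
            if ll_new >= ll - 1e-13:
                improved = True
                break
            scale /= 2.0
        if not improved:
            break
        rel_change = abs(ll_new - ll) / (abs(ll) + 1e-300)
        beta, ll = cand, ll_new
        ll, grad, info = conditional_loglik(beta, dm, order=2)
        gnorm = float(np.max(np.abs(grad)))
        if np.linalg.norm(beta) > separation_norm:
            return FitResult(
                beta=np.full(k, np.nan), vcov=np.full((k, k), np.nan),
                loglik=ll, term_map=dm.term_map, colnames=dm.colnames,
                converged=False, n_iter=n_iter, grad_norm=gnorm,
                separation=True, n_sets=dm.n_sets,
            )
        if rel_change < rel_tol and gnorm < grad_tol:
            break
    gnorm = float(np.max(np.abs(grad)))
    converged = gnorm < grad_tol
    try:
        vcov = linalg.inv(info)
    except linalg.LinAlgError:
        vcov = np.linalg.pinv(info)
    vcov = (vcov + vcov.T) / 2.0
    return FitResult(
        beta=beta, vcov=vcov, loglik=ll, term_map=dm.term_map,
        colnames=dm.colnames, converged=converged, n_iter=n_iter,
        grad_norm=gnorm, n_sets=dm.n_sets,
    )


def or_per_increment(
    result: FitResult, term: str = "pm", increment: float = 10.0
) -> dict[str, float]:
    """Odds ratio (with Wald 95% CI) for an ``increment``-unit rise in a
    linear term — the headline "OR per 10 ug/m3" scale.
    """
    cols = result.term_map[term]
    if len(cols) != 1:
        raise ValueError(
            f"term {term!r} is spline-encoded ({len(cols)} columns); "
            "use exposure_response_curve instead"
        )
    b = float(result.beta[cols[0]])
    se = float(np.sqrt(result.vcov[cols[0], cols[0]]))
    z = stats.norm.ppf(0.975)
    return {
        "or": float(np.exp(increment * b)),
        "ci_low": float(np.exp(increment * (b - z * se))),
        "ci_high": float(np.exp(increment * (b + z * se))),
        "log_or_per_unit": b,
        "se_per_unit": se,
    }


def exposure_response_curve(
    result: FitResult,
    dm: DesignMatrix,
    reference: float,
    grid: np.ndarray | None = None,
) -> pd.DataFrame:
    """Flexible exposure-response curve OR(x) = exp[(b(x) - b(ref)) . beta].

    Pointwise 95% CIs by the delta method through the coefficient
    covariance; OR(reference) is exactly 1 with a zero-width interval.
    Grid points beyond the boundary knots are in the linear-extrapolation
    regime and are flagged in the ``extrapolated`` column.
    """
    if dm.pm_spec is None:
        raise ValueError("fit used a linear PM term; no curve to evaluate")
    lo, hi = dm.pm_spec.boundary_knots  # type: ignore[misc]
    if not (lo <= reference <= hi):
        raise ValueError(f"reference {reference} outside boundary knots ({lo}, {hi})")
    if grid is None:
        grid = np.linspace(lo, hi, 101)
    grid = np.asarray(grid, dtype=float)

    b_grid, _ = ns_basis(grid, dm.pm_spec)
    b_ref, _ = ns_basis(np.array([reference]), dm.pm_spec)
    contrast = b_grid - b_ref
    cols = result.term_map["pm"]
    beta = result.beta[cols]
    v = result.vcov[np.ix_(cols, cols)]
    log_or = contrast @ beta
    var = np.einsum("ij,jk,ik->i", contrast, v, contrast)
    se = np.sqrt(np.maximum(var, 0.0))
    z = stats.norm.ppf(0.975)
    return pd.DataFrame(
        {
            "pm": grid,
            "or": np.exp(log_or),
            "ci_low": np.exp(log_or - z * se),
            "ci_high": np.exp(log_or + z * se),
            "log_or": log_or,
            "se_log_or": se,
            "extrapolated": (grid < lo) | (grid > hi),
        }
    )
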