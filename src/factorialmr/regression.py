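"""Regression engines: multivariable OLS and Cox proportional hazards.

Both engines operate on named design matrices (:class:`pandas.DataFrame`)
and return fits carrying per-term coefficients, standard errors and enough
state for Wald inference.  The Cox engine maximises the Breslow-tie partial
likelihood by Newton-Raphson with step-halving; standard errors come from
the inverse observed information.  These are the only two model fitters the
analysis stages use.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "LinearFit",
    "CoxFit",
    "WaldResult",
    "fit_linear",
    "fit_cox",
    "wald",
    "summary_frame",
]

# 97.5% standard-normal quantile used for every 95% interval.
Z_95 = 1.959964

#: Newton-Raphson defaults for the Cox engine.
COX_MAX_ITER = 50
COX_GRAD_TOL = 1e-8
COX_STEP_TOL = 1e-10
# log-HR magnitude beyond which a "converged" fit is treated as monotone
# likelihood (perfect separation): the gradient vanishes numerically as
# exp(eta) saturates, so the flat-gradient test alone cannot catch it
COX_MAX_ABS_BETA = 15.0

# Rank / collinearity detection threshold (relative to largest singular value).
_RANK_RTOL = 1e-8


@dataclass
class LinearFit:
    """Ordinary least squares fit.

    coefficients are in outcome units per covariate unit; standard errors
    are classical (residual variance times the diagonal of (X'X)^-1).
    """

    coefficients: pd.Series
    standard_errors: pd.Series
    residual_variance: float
    n: int

    def wald(self, term: str) -> "WaldResult":
        return wald(float(self.coefficients[term]), float(self.standard_errors[term]))


@dataclass
class CoxFit:
    """Cox proportional-hazards fit (Breslow partial likelihood).

    ``coefficients`` are log hazard ratios per covariate unit.
    """

    coefficients: pd.Series
    standard_errors: pd.Series
    log_partial_likelihood: float
    n: int
    n_events: int
    converged: bool
    n_iterations: int
    covariance: np.ndarray = field(repr=False, default=None)

    def hazard_ratios(self) -> pd.Series:
        return np.exp(self.coefficients)

    def wald(self, term: str) -> "WaldResult":
        return wald(float(self.coefficients[term]), float(self.standard_errors[term]))


@dataclass
class WaldResult:
    z: float
    p: float
    ci_low: float
    ci_high: float


def _as_design(design) -> pd.DataFrame:
    if isinstance(design, pd.DataFrame):
        return design
    arr = np.asarray(design, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    cols = [f"x{j}" for j in range(arr.shape[1])]
    return pd.DataFrame(arr, columns=cols)


def _check_full_rank(X: np.ndarray, names: list[str], context: str) -> None:
    """Raise naming (approximately) collinear columns if X is rank deficient."""
    if X.shape[0] == 0:
        raise ValueError(f"{context}: empty design")
    sv = np.linalg.svd(X, compute_uv=False)
    if sv[0] == 0 or sv[-1] / sv[0] < _RANK_RTOL:
        # identify offending columns: those whose removal restores rank
        bad = []
        rank = np.linalg.matrix_rank(X, tol=sv[0] * _RANK_RTOL)
        for j, name in enumerate(names):
            Xj = np.delete(X, j, axis=1)
            if np.linalg.matrix_rank(Xj, tol=sv[0] * _RANK_RTOL) == rank:
                bad.append(name)
        raise ValueError(
            f"{context}: design matrix is rank deficient; "
            f"collinear or constant-zero columns: {bad or names}"
        )


def fit_linear(y, design) -> LinearFit:
    """Ordinary least squares of ``y`` on the named columns of ``design``.

    The caller supplies the intercept column explicitly if one is wanted.
    Raises ``ValueError`` for rank-deficient designs (naming the collinear
    columns) and when ``n <= p``.
    """
    X = _as_design(design)
    names = list(X.columns)
    Xv = X.to_numpy(dtype=float)
    yv = np.asarray(y, dtype=float).ravel()
    n, p = Xv.shape
    if yv.shape[0] != n:
        raise ValueError(f"y has length {yv.shape[0]} but design has {n} rows")
    if n <= p:
        raise ValueError(f"need n > p to fit OLS with residual variance (n={n}, p={p})")
    _check_full_rank(Xv, names, "fit_linear")

    # QR-based solve; (X'X)^-1 from R
    Q, R = np.linalg.qr(Xv)
    beta = np.linalg.solve(R, Q.T @ yv)
    resid = yv - Xv @ beta
    rss = float(resid @ resid)
    s2 = rss / (n - p)
    Rinv = np.linalg.inv(R)
    xtx_inv = Rinv @ Rinv.T
    se = np.sqrt(s2 * np.diag(xtx_inv))
    return LinearFit(
        coefficients=pd.Series(beta, index=names),
        standard_errors=pd.Series(se, index=names),
        residual_variance=s2,
        n=n,
    )


def _cox_loglik_grad_info(
    beta: np.ndarray,
    X: np.ndarray,
    event: np.ndarray,
    block_last: np.ndarray,
    want_derivs: bool = True,
):
    """Breslow log partial likelihood (and derivatives) on pre-sorted data.

    Data must be sorted by descending time; ``block_last[i]`` is the index of
    the last row sharing row i's time, so ``cumsum[...block_last[i]]`` sums
    over the full risk set (all rows with time >= time_i, ties included).
    """
    eta = X @ beta
    # guard against overflow in exp for diverging beta during step search
    eta = np.clip(eta, -500, 500)
    w = np.exp(eta)
    S0 = np.cumsum(w)
    ev = event.astype(bool)
    bl_ev = block_last[ev]
    r0 = S0[bl_ev]
    loglik = float(np.sum(eta[ev]) - np.sum(np.log(r0)))
    if not want_derivs:
        return loglik, None, None
    S1 = np.cumsum(w[:, None] * X, axis=0)
    mu = S1[bl_ev] / r0[:, None]  # (n_ev, p)
    grad = X[ev].sum(axis=0) - mu.sum(axis=0)
    # sum over events of the risk-set second moment S2/S0 equals
    # X' diag(w * A) X with A_j = sum over events whose risk set contains j
    # of 1/S0_e (subject j is in risk set e iff j <= block_last_e in the
    # descending sort), so no (n, p, p) array is ever materialized
    c = np.zeros(X.shape[0])
    np.add.at(c, bl_ev, 1.0 / r0)
    A = np.cumsum(c[::-1])[::-1]
    info = (X * (w * A)[:, None]).T @ X - mu.T @ mu
    return loglik, grad, info


def fit_cox(
    time,
    event,
    design,
    max_iter: int = COX_MAX_ITER,
    grad_tol: float = COX_GRAD_TOL,
    init: np.ndarray | None = None,
) -> CoxFit:
    """Fit a Cox proportional-hazards model by Newton-Raphson.

    Ties are handled with the Breslow approximation.  Convergence requires
    the maximum absolute score component to fall below ``grad_tol``; fits
    that exhaust ``max_iter`` (e.g. under monotone likelihood / perfect
    separation) are returned with ``converged=False`` rather than silently.

    Raises ``ValueError`` when no events are present, when any time is
    non-positive, or when the design is rank deficient on the full sample.
    """
    X = _as_design(design)
    names = list(X.columns)
    Xv = X.to_numpy(dtype=float)
    t = np.asarray(time, dtype=float).ravel()
    d = np.asarray(event).ravel().astype(int)
    n, p = Xv.shape
    if t.shape[0] != n or d.shape[0] != n:
        raise ValueError("time, event and design must have equal lengths")
    if np.any(~np.isfinite(t)) or np.any(t <= 0):
        raise ValueError("all times must be finite and > 0")
    if not np.all(np.isin(d, (0, 1))):
        raise ValueError("event indicators must be 0/1")
    n_events = int(d.sum())
    if n_events == 0:
        raise ValueError("cannot fit a Cox model with zero events")
    _check_full_rank(Xv, names, "fit_cox")

    # sort by descending time (stable for reproducibility)
    order = np.argsort(-t, kind="stable")
    Xs, ts, ds = Xv[order], t[order], d[order]
    # last index of each tie block in the descending sort
    change = np.flatnonzero(np.diff(ts) != 0)
    block_last = np.empty(n, dtype=np.intp)
    start = 0
    for end in list(change) + [n - 1]:
        block_last[start : end + 1] = end
        start = end + 1

    beta = np.zeros(p) if init is None else np.asarray(init, dtype=float).copy()
    loglik, grad, info = _cox_loglik_grad_info(beta, Xs, ds, block_last)
    converged = False
    it = 0
    ll_eps = 1e-10 * (abs(loglik) + 1.0)  # floating noise floor for step acceptance
    for it in range(1, max_iter + 1):
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            break
        # scale-free Newton decrement: expected log-likelihood gain of the
        # full step; immune to covariate-unit differences in the raw gradient
        decrement = float(grad @ step)
        if np.max(np.abs(grad)) < grad_tol or 0.5 * decrement < 1e-10:
            converged = True
            break
        # step-halving on likelihood decrease
        scale = 1.0
        for _ in range(30):
            cand = beta + scale * step
            ll_new, _, _ = _cox_loglik_grad_info(cand, Xs, ds, block_last, want_derivs=False)
            if ll_new >= loglik - ll_eps:
                break
            scale *= 0.5
        else:
            # no improving step exists: at the numerical optimum if the
            # remaining predicted gain is within floating noise
            converged = 0.5 * decrement < 1e3 * ll_eps
            break
        took_tiny_step = np.max(np.abs(scale * step)) < COX_STEP_TOL
        beta = cand
        loglik, grad, info = _cox_loglik_grad_info(beta, Xs, ds, block_last)
        if took_tiny_step:
            converged = True
            break
    else:
        converged = bool(np.max(np.abs(grad)) < grad_tol)

    if converged and np.max(np.abs(beta)) > COX_MAX_ABS_BETA:
        converged = False  # suspected monotone likelihood
    try:
        cov = np.linalg.inv(info)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        cov = np.full((p, p), np.nan)
        se = np.full(p, np.nan)
        converged = False
    return CoxFit(
        coefficients=pd.Series(beta, index=names),
        standard_errors=pd.Series(se, index=names),
        log_partial_likelihood=loglik,
        n=n,
        n_events=n_events,
        converged=converged,
        n_iterations=it,
        covariance=cov,
    )


def cox_score_test(time, event, design) -> float:
    """Score (chi-square, 1 df per column jointly) test statistic at beta=0.

    With a single binary covariate and no tied event times this equals the
    classical log-rank statistic.
    """
    X = _as_design(design)
    Xv = X.to_numpy(dtype=float)
    t = np.asarray(time, dtype=float).ravel()
    d = np.asarray(event).ravel().astype(int)
    order = np.argsort(-t, kind="stable")
    Xs, ts, ds = Xv[order], t[order], d[order]
    n = len(ts)
    change = np.flatnonzero(np.diff(ts) != 0)
    block_last = np.empty(n, dtype=np.intp)
    start = 0
    for end in list(change) + [n - 1]:
        block_last[start : end + 1] = end
        start = end + 1
    _, grad, info = _cox_loglik_grad_info(np.zeros(Xs.shape[1]), Xs, ds, block_last)
    return float(grad @ np.linalg.solve(info, grad))


def wald(coef: float, se: float) -> WaldResult:
    """Two-sided Wald z test and 95% confidence interval."""
    if not np.isfinite(se) or se <= 0:
        raise ValueError(f"standard error must be finite and > 0, got {se}")
    z = coef / se
    p = 2.0 * stats.norm.sf(abs(z))
    return WaldResult(z=z, p=float(p), ci_low=coef - Z_95 * se, ci_high=coef + Z_95 * se)


def summary_frame(fit) -> pd.DataFrame:
    """Per-term TSV-ready summary: term, estimate, se, z, p, ci_low, ci_high."""
    rows = []
    for term in fit.coefficients.index:
        est = float(fit.coefficients[term])
        se = float(fit.standard_errors[term])
        w = wald(est, se)
        rows.append(
            {
                "term": term,
                "estimate": est,
                "se": se,
                "z": w.z,
                "p": w.p,
                "ci_low": w.ci_low,
                "ci_high": w.ci_high,
            }
        )
    return pd.DataFrame(rows)
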