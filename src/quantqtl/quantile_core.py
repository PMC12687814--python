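"""Core statistical kernels for quantile-based QTL mapping.

This module provides the building blocks used by every scan in the package:

* linear quantile regression by exact check-loss minimization, via a
  Frisch--Newton primal--dual interior-point solver (the standard algorithm
  for moderate-size quantile regression problems), with an analytic
  order-statistic path for intercept-only fits and an LP path
  (:func:`scipy.optimize.linprog`, HiGHS) retained for cross-checking;
* the quantile rank-score test, which fits the covariate-only null model
  once per quantile level and then scores any number of variants against it;
* the Cauchy combination (ACAT) of dependent p-values;
* the Chatterjee rank correlation coefficient and its one-sided test,
  used to detect heterogeneity of quantile-specific effect sizes.

All solvers are deterministic: no stochastic initialization is used anywhere.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import linalg, stats

__all__ = [
    "QuantileGrid",
    "NullQuantileFit",
    "RankScoreResult",
    "check_loss",
    "fit_check_loss",
    "fit_quantile_null",
    "fit_quantile_joint",
    "rank_score_test",
    "rank_score_scan",
    "cauchy_combine",
    "chatterjee_xi",
]

#: 19-level grid used for QTL mapping (tau = 0.05, 0.10, ..., 0.95).
MAPPING_GRID = np.round(np.arange(1, 20) * 0.05, 2)
#: 99-level grid used for TWAS weight estimation (tau = 0.01, ..., 0.99).
WEIGHT_GRID = np.round(np.arange(1, 100) * 0.01, 2)

P_CLIP = 1e-15  # p-value clipping bound before the Cauchy transform


@dataclass(frozen=True)
class QuantileGrid:
    """An ordered grid of quantile levels in (0, 1)."""

    taus: np.ndarray

    def __post_init__(self):
        taus = np.asarray(self.taus, dtype=float)
        if taus.ndim != 1 or taus.size == 0:
            raise ValueError("quantile grid must be a non-empty 1-D sequence")
        if np.any(taus <= 0) or np.any(taus >= 1):
            raise ValueError("quantile levels must lie strictly in (0, 1)")
        if np.any(np.diff(taus) <= 0):
            raise ValueError("quantile levels must be strictly increasing")
        object.__setattr__(self, "taus", taus)

    def __len__(self):
        return self.taus.size

    def __iter__(self):
        return iter(self.taus)

    @classmethod
    def mapping(cls) -> "QuantileGrid":
        return cls(MAPPING_GRID.copy())

    @classmethod
    def weights(cls) -> "QuantileGrid":
        return cls(WEIGHT_GRID.copy())


@dataclass
class NullQuantileFit:
    """Covariate-only quantile regression fit at a single level tau.

    ``rank_scores`` are the Gutenbrunner-Jureckova regression rank scores
    phi_i = a_i - (1 - tau) from the dual of the quantile LP: they equal
    tau - 1(resid < 0) away from the fitted hyperplane, take interior
    values on the ~q+1 interpolated observations, and satisfy
    sum_i x_i phi_i = 0 exactly — which keeps the rank-score test
    calibrated when the covariate count is not small.
    """

    tau: float
    alpha0: float
    alpha: np.ndarray
    fitted: np.ndarray
    residuals: np.ndarray
    check_loss: float
    rank_scores: np.ndarray | None = None
    n_iter: int = 0


@dataclass
class RankScoreResult:
    """Per-variant rank-score statistics over a quantile grid."""

    taus: np.ndarray
    score: np.ndarray  # (n_tau,) or (n_tau, m)
    sigma: np.ndarray
    pvalues: np.ndarray
    combined_p: float | np.ndarray
    gstar_norm2: float | np.ndarray
    testable: bool | np.ndarray = True


def check_loss(residuals: np.ndarray, tau: float) -> float:
    """Quantile check loss ``sum_i rho_tau(r_i)`` with rho_tau(u)=u(tau-1(u<0))."""
    r = np.asarray(residuals, dtype=float)
    return float(np.sum(r * (tau - (r < 0))))


# ---------------------------------------------------------------------------
# Check-loss solvers
# ---------------------------------------------------------------------------


def _fit_intercept_only(y: np.ndarray, tau: float) -> float:
    """Exact 1-D minimizer of the check loss: the lower-order-statistic
    empirical quantile ``y_(ceil(n*tau))`` (1-based)."""
    ys = np.sort(np.asarray(y, dtype=float))
    n = ys.size
    k = int(math.ceil(n * tau))
    k = min(max(k, 1), n)
    return float(ys[k - 1])


_NUMBA_KERNEL = None
_NUMBA_TRIED = False


def _numba_kernel():
    """Compiled Frisch-Newton kernel, or None when numba is unavailable."""
    global _NUMBA_KERNEL, _NUMBA_TRIED
    if not _NUMBA_TRIED:
        _NUMBA_TRIED = True
        try:
            from ._fn_numba import fn_qr_nb

            _NUMBA_KERNEL = fn_qr_nb
        except Exception:  # pragma: no cover - numba strictly optional
            _NUMBA_KERNEL = None
    return _NUMBA_KERNEL


def _fn_solve(X, y, tau, tol=1e-8, max_iter=100):
    """Dispatch to the compiled kernel when available, else pure numpy."""
    kern = _numba_kernel()
    if kern is not None:
        X = np.ascontiguousarray(X, dtype=np.float64)
        y = np.ascontiguousarray(y, dtype=np.float64)
        b, f, it, gap, a = kern(X, y, float(tau), float(tol), int(max_iter))
        if f < 0.0 and it >= max_iter:
            raise RuntimeError(
                f"quantile regression did not converge in {max_iter} "
                f"iterations (tau={tau}, gap={gap:.3e})"
            )
        return b, f, it, gap, a
    return _fit_fn(X, y, tau, tol=tol, max_iter=max_iter)


def _fit_fn(X: np.ndarray, y: np.ndarray, tau: float, tol: float, max_iter: int):
    """Frisch--Newton primal-dual interior point for min sum rho_tau(y - Xb).

    Operates on the bounded-variable dual  max y'a  s.t. X'a = (1-tau) X'1,
    0 <= a <= 1, carrying the primal (b, u, v) alongside; Mehrotra
    predictor-corrector steps; terminates on the primal-dual gap.
    """
    n, p = X.shape
    b = np.linalg.lstsq(X, y, rcond=None)[0]
    r = y - X @ b
    u = np.maximum(r, 0.0) + 1.0
    v = np.maximum(-r, 0.0) + 1.0
    a = np.full(n, 1.0 - tau)
    s = np.full(n, tau)
    c1 = (1.0 - tau) * X.sum(axis=0)
    ysum = float(y.sum())
    gap = np.inf
    for it in range(max_iter):
        r1 = c1 - X.T @ a
        r2 = 1.0 - a - s
        r3 = y - X @ b - u + v
        mu = (a @ v + s @ u) / (2 * n)
        f = check_loss(y - X @ b, tau)
        dual = float(y @ a) - (1.0 - tau) * ysum
        gap = f - dual
        if gap < tol * (1.0 + abs(f)):
            return b, f, it, gap, a
        d = 1.0 / (u / s + v / a)
        Xd = X * d[:, None]
        M = X.T @ Xd
        try:
            cho = linalg.cho_factor(M, check_finite=False)
        except linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                "rank-deficient design in quantile regression"
            ) from exc

        def step(rav, rsu):
            r3t = r3 - (rsu - u * r2) / s + rav / a
            db = linalg.cho_solve(cho, Xd.T @ r3t - r1, check_finite=False)
            da = d * (r3t - X @ db)
            ds = r2 - da
            dv = (rav - v * da) / a
            du = (rsu - u * ds) / s
            return db, da, ds, du, dv

        def lengths(da, ds, du, dv, frac=0.9995):
            ap = ad = 1.0
            for z, dz in ((a, da), (s, ds)):
                neg = dz < 0
                if neg.any():
                    ap = min(ap, frac * float(np.min(-z[neg] / dz[neg])))
            for z, dz in ((u, du), (v, dv)):
                neg = dz < 0
                if neg.any():
                    ad = min(ad, frac * float(np.min(-z[neg] / dz[neg])))
            return ap, ad

        # predictor (affine) step
        db, da, ds, du, dv = step(-a * v, -s * u)
        ap, ad = lengths(da, ds, du, dv)
        mu_aff = ((a + ap * da) @ (v + ad * dv) + (s + ap * ds) @ (u + ad * du)) / (2 * n)
        sigma = min(1.0, (mu_aff / mu) ** 3) if mu > 0 else 0.0
        # corrector step (reuses the factorization)
        db, da, ds, du, dv = step(
            sigma * mu - a * v - ap * ad * da * dv,
            sigma * mu - s * u - ap * ad * ds * du,
        )
        ap, ad = lengths(da, ds, du, dv)
        b = b + ap * db
        a = a + ap * da
        s = s + ap * ds
        u = u + ad * du
        v = v + ad * dv
    raise RuntimeError(
        f"quantile regression did not converge in {max_iter} iterations "
        f"(tau={tau}, gap={gap:.3e})"
    )


def _fit_highs(X: np.ndarray, y: np.ndarray, tau: float):
    """Exact LP solution via HiGHS; used as a slow reference path."""
    from scipy import sparse
    from scipy.optimize import linprog

    n, p = X.shape
    A = sparse.hstack(
        [sparse.csc_matrix(X), sparse.eye(n), -sparse.eye(n)], format="csc"
    )
    c = np.concatenate([np.zeros(p), tau * np.ones(n), (1 - tau) * np.ones(n)])
    bounds = [(None, None)] * p + [(0, None)] * (2 * n)
    res = linprog(c, A_eq=A, b_eq=y, bounds=bounds, method="highs")
    if not res.success:
        raise RuntimeError(f"HiGHS failed on quantile LP at tau={tau}: {res.message}")
    b = res.x[:p]
    return b, check_loss(y - X @ b, tau), 0, 0.0


def fit_check_loss(
    X: np.ndarray,
    y: np.ndarray,
    tau: float,
    solver: str = "fn",
    tol: float = 1e-8,
    max_iter: int = 100,
):
    """Minimize the quantile check loss for response ``y`` and design ``X``.

    Returns ``(coef, loss, n_iter)``. ``solver`` is ``"fn"`` (Frisch-Newton,
    default) or ``"highs"`` (exact LP). Deterministic for fixed inputs.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if not 0.0 < tau < 1.0:
        raise ValueError(f"tau must be in (0,1), got {tau}")
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ValueError("design/response shape mismatch")
    n, p = X.shape
    if n <= p:
        raise ValueError(f"need n > number of parameters ({n} <= {p})")
    if p == 1 and np.all(X[:, 0] == X[0, 0]) and X[0, 0] != 0:
        # constant single column: exact order-statistic solution
        coef = np.array([_fit_intercept_only(y, tau) / X[0, 0]])
        return coef, check_loss(y - X @ coef, tau), 0
    if np.linalg.matrix_rank(X) < p:
        raise np.linalg.LinAlgError("rank-deficient design in quantile regression")
    if solver == "fn":
        b, loss, it, _, _ = _fn_solve(X, y, tau, tol=tol, max_iter=max_iter)
    elif solver == "highs":
        b, loss, it, _ = _fit_highs(X, y, tau)
    else:
        raise ValueError(f"unknown solver {solver!r}")
    return b, loss, it


def fit_quantile_null(
    Y: np.ndarray,
    C: np.ndarray | None,
    tau: float,
    solver: str = "fn",
) -> NullQuantileFit:
    """Fit the covariate-only quantile regression model at level ``tau``.

    ``C`` is an (n, q) covariate matrix *without* an intercept column (one is
    added here), or None for an intercept-only fit. The fit minimizes
    ``sum_i rho_tau(Y_i - alpha0 - C_i' alpha)``.
    """
    Y = np.asarray(Y, dtype=float)
    n = Y.size
    phi = None
    if C is None or (hasattr(C, "shape") and np.size(C) == 0):
        a0 = _fit_intercept_only(Y, tau)
        coef = np.array([a0])
        X = np.ones((n, 1))
        r = Y - a0
        phi = np.where(r > 0, tau, np.where(r < 0, tau - 1.0, 0.0))
        ties = r == 0
        if ties.any():  # distribute the balancing score over tied points
            fill = -phi.sum() / ties.sum()
            phi[ties] = np.clip(fill, tau - 1.0, tau)
    else:
        C = np.atleast_2d(np.asarray(C, dtype=float))
        if C.shape[0] != n:
            C = C.T
        q = C.shape[1]
        if n <= q + 1:
            raise ValueError(f"need n > q+1 ({n} <= {q + 1})")
        X = np.column_stack([np.ones(n), C])
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise np.linalg.LinAlgError("rank-deficient covariate design")
        if solver == "fn":
            coef, _, _, _, dual = _fn_solve(X, Y, tau, tol=1e-8, max_iter=100)
            phi = dual - (1.0 - tau)
        else:
            coef, _, _ = fit_check_loss(X, Y, tau, solver=solver)
            phi = _regression_rank_scores(X, Y - X @ coef, tau)
    fitted = X @ coef
    resid = Y - fitted
    return NullQuantileFit(
        tau=float(tau),
        alpha0=float(coef[0]),
        alpha=coef[1:].copy(),
        fitted=fitted,
        residuals=resid,
        check_loss=check_loss(resid, tau),
        rank_scores=phi,
    )


def fit_quantile_joint(
    Y: np.ndarray,
    X_block: np.ndarray,
    C: np.ndarray | None,
    grid: QuantileGrid | Sequence[float],
    solver: str = "fn",
) -> np.ndarray:
    """Joint quantile regression of ``Y`` on predictors ``X_block`` plus
    covariates, over a grid of levels.

    Returns the predictor coefficient matrix of shape (n_predictors, n_tau);
    intercept and covariate coefficients are fitted but not returned.
    """
    taus = np.asarray(getattr(grid, "taus", grid), dtype=float)
    Y = np.asarray(Y, dtype=float)
    Xb = np.atleast_2d(np.asarray(X_block, dtype=float))
    if Xb.shape[0] != Y.size:
        Xb = Xb.T
    n, p = Xb.shape
    if C is None or np.size(C) == 0:
        design = np.column_stack([np.ones(n), Xb])
        q = 0
    else:
        C = np.atleast_2d(np.asarray(C, dtype=float))
        if C.shape[0] != n:
            C = C.T
        q = C.shape[1]
        design = np.column_stack([np.ones(n), C, Xb])
    if n <= p + q + 1:
        raise ValueError("need p + q + 1 < n")
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise np.linalg.LinAlgError("rank-deficient joint design")
    out = np.empty((p, taus.size))
    for k, tau in enumerate(taus):
        coef, _, _ = fit_check_loss(design, Y, float(tau), solver=solver)
        out[:, k] = coef[1 + q :]
    return out


# ---------------------------------------------------------------------------
# Rank-score test
# ---------------------------------------------------------------------------


def projection_basis(C: np.ndarray | None, n: int) -> np.ndarray:
    """Orthonormal basis Q of span{1, C}; the rank-score projection removes
    this span from each dosage column (the intercept is always included so
    the score is mean-centered)."""
    if C is None or np.size(C) == 0:
        X0 = np.ones((n, 1))
    else:
        C = np.atleast_2d(np.asarray(C, dtype=float))
        if C.shape[0] != n:
            C = C.T
        X0 = np.column_stack([np.ones(n), C])
    Q, R = np.linalg.qr(X0)
    # guard against rank deficiency of [1, C]
    keep = np.abs(np.diag(R)) > 1e-10 * max(np.abs(np.diag(R)).max(), 1.0)
    return Q[:, keep]


def project_out(G: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """Residualize columns of G against the orthonormal basis Q."""
    G = np.asarray(G, dtype=float)
    return G - Q @ (Q.T @ G)


def _phi_tau(residuals: np.ndarray, tau: float) -> np.ndarray:
    return tau - (residuals < 0)


def _regression_rank_scores(
    X: np.ndarray, residuals: np.ndarray, tau: float, ztol: float = 1e-7
) -> np.ndarray:
    """Regression rank scores from residual signs with tie balancing.

    Observations with |r| <= ztol * scale sit on the fitted hyperplane;
    their scores are chosen (least-squares, clipped to [tau-1, tau]) so
    that X' phi = 0, matching the LP-dual scores up to clipping.
    """
    r = np.asarray(residuals, dtype=float)
    scale = max(float(np.abs(r).max()), 1.0)
    on = np.abs(r) <= ztol * scale
    phi = np.where(r > 0, tau, tau - 1.0)
    if on.any():
        rhs = -X[~on].T @ phi[~on]
        phi[on] = np.clip(_tie_fill(X[on], rhs), tau - 1.0, tau)
    return phi


def _tie_fill(X_on: np.ndarray, rhs: np.ndarray) -> np.ndarray:
    """Least-norm phi_on with X_on' phi_on = rhs."""
    sol, *_ = np.linalg.lstsq(X_on.T, rhs, rcond=None)
    return sol


def rank_score_test(
    G_col: np.ndarray,
    null_fit: NullQuantileFit,
    C: np.ndarray | None,
) -> tuple[float, float, float]:
    """Quantile rank-score test of a single dosage column against a null fit.

    Returns ``(S, sigma, p)`` where ``S = n^{-1/2} sum_i G*_i phi_tau(resid_i)``,
    ``sigma^2 = tau(1-tau) ||G*||^2 / n`` and ``p`` is the two-sided normal
    p-value of S/sigma. A dosage lying in the covariate span is untestable:
    ``(nan, 0, nan)`` is returned.
    """
    G_col = np.asarray(G_col, dtype=float)
    n = G_col.size
    Q = projection_basis(C, n)
    g_star = project_out(G_col[:, None], Q)[:, 0]
    norm2 = float(g_star @ g_star)
    if norm2 <= 1e-10 * max(float(G_col @ G_col), 1.0):
        return (float("nan"), 0.0, float("nan"))
    tau = null_fit.tau
    phi = (null_fit.rank_scores if null_fit.rank_scores is not None
           else _phi_tau(null_fit.residuals, tau))
    S = float(g_star @ phi) / math.sqrt(n)
    sigma = math.sqrt(tau * (1 - tau) * norm2 / n)
    p = 2.0 * stats.norm.sf(abs(S) / sigma)
    return (S, sigma, float(p))


def rank_score_scan(
    G: np.ndarray,
    null_fits: Sequence[NullQuantileFit],
    C: np.ndarray | None,
) -> RankScoreResult:
    """Vectorized rank-score scan: m dosage columns against per-tau null fits.

    The null model is fitted once per tau (outside this function) and shared
    across all variants; the per-variant work is two matrix products.
    """
    G = np.atleast_2d(np.asarray(G, dtype=float))
    n = null_fits[0].residuals.size
    if G.shape[0] != n:
        G = G.T
    m = G.shape[1]
    taus = np.array([f.tau for f in null_fits])
    Q = projection_basis(C, n)
    G_star = project_out(G, Q)
    norm2 = np.einsum("ij,ij->j", G_star, G_star)
    testable = norm2 > 1e-10 * np.maximum(np.einsum("ij,ij->j", G, G), 1.0)
    Phi = np.stack([
        f.rank_scores if f.rank_scores is not None
        else _phi_tau(f.residuals, f.tau)
        for f in null_fits
    ])  # (T, n)
    S = (Phi @ G_star) / math.sqrt(n)  # (T, m)
    sigma = np.sqrt(np.outer(taus * (1 - taus), norm2) / n)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sigma > 0, S / np.where(sigma > 0, sigma, 1.0), np.nan)
    p = 2.0 * stats.norm.sf(np.abs(z))
    p[:, ~testable] = np.nan
    combined = np.full(m, np.nan)
    for j in np.nonzero(testable)[0]:
        combined[j] = cauchy_combine(p[:, j])
    return RankScoreResult(
        taus=taus,
        score=S,
        sigma=sigma,
        pvalues=p,
        combined_p=combined,
        gstar_norm2=norm2,
        testable=testable,
    )


# ---------------------------------------------------------------------------
# Cauchy combination (ACAT)
# ---------------------------------------------------------------------------


def cauchy_combine(pvalues, weights=None) -> float:
    """Cauchy combination of dependent p-values.

    ``T = sum_i w_i tan((0.5 - p_i) pi)`` with weights summing to one;
    the combined p-value is ``0.5 - arctan(T)/pi``. Inputs are clipped to
    ``[1e-15, 1 - 1e-15]`` before the transform.
    """
    p = np.asarray(pvalues, dtype=float).ravel()
    if p.size == 0:
        raise ValueError("cauchy_combine requires at least one p-value")
    if np.any(np.isnan(p)):
        raise ValueError("cauchy_combine received NaN p-values")
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    if weights is None:
        w = np.full(p.size, 1.0 / p.size)
    else:
        w = np.asarray(weights, dtype=float).ravel()
        if w.size != p.size or np.any(w < 0) or w.sum() <= 0:
            raise ValueError("invalid weights")
        w = w / w.sum()
    p = np.clip(p, P_CLIP, 1.0 - P_CLIP)
    T = float(w @ np.tan((0.5 - p) * np.pi))
    return float(0.5 - math.atan(T) / math.pi)


# ---------------------------------------------------------------------------
# Chatterjee correlation
# ---------------------------------------------------------------------------


def chatterjee_xi(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Chatterjee's rank correlation xi_n and its one-sided (right-tail) test.

    ``y`` is ordered by ``x`` (stable sort; ties in x broken by original
    index, never at random), then with r_i = #{j: y_j <= y_(i)} and
    l_i = #{j: y_j >= y_(i)}:

        xi_n = 1 - n * sum_i |r_{i+1} - r_i| / (2 * sum_i l_i (n - l_i))

    which reduces to 1 - 3 sum|dr| / (n^2 - 1) without ties in y. The test
    uses the asymptotic null law sqrt(n) * xi ~ N(0, 2/5) (right tail only:
    the alternative of interest is positive dependence).
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    n = x.size
    if n < 3 or y.size != n:
        raise ValueError("chatterjee_xi needs at least 3 paired observations")
    order = np.argsort(x, kind="stable")
    yo = y[order]
    r = np.array([np.sum(y <= yi) for yi in yo], dtype=float)
    l = np.array([np.sum(y >= yi) for yi in yo], dtype=float)
    denom = 2.0 * float(np.sum(l * (n - l)))
    if denom == 0:  # all y equal
        return (0.0, 1.0)
    xi = 1.0 - n * float(np.sum(np.abs(np.diff(r)))) / denom
    z = math.sqrt(n) * xi / math.sqrt(0.4)
    p = float(stats.norm.sf(z))
    return (float(xi), p)
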