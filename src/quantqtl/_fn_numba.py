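"""Numba-compiled Frisch-Newton quantile regression kernel.

Same algorithm as the numpy implementation in :mod:`.quantile_core`
(Mehrotra predictor-corrector interior point on the bounded-variable
dual); compiled for the tight per-replicate loops of the simulation
study. ``fastmath`` is off so results are deterministic and agree with
the numpy path to solver tolerance. A failed convergence is signalled by
an objective of -1.0 and handled by the caller.
"""

import numpy as np
from numba import njit

@njit(cache=True, fastmath=False)
def fn_qr_nb(X, y, tau, tol, max_iter):
    n, p = X.shape
    b = np.linalg.lstsq(X, y.copy())[0][:p]
    r = y - X @ b
    u = np.maximum(r, 0.0) + 1.0
    v = np.maximum(-r, 0.0) + 1.0
    a = np.full(n, 1.0 - tau)
    s = np.full(n, tau)
    c1 = (1.0 - tau) * X.sum(axis=0)
    ysum = y.sum()
    gap = np.inf
    for it in range(max_iter):
        r1 = c1 - X.T @ a
        r2 = 1.0 - a - s
        r3 = y - X @ b - u + v
        mu = (a @ v + s @ u) / (2 * n)
        rr = y - X @ b
        f = 0.0
        for i in range(n):
            f += rr[i] * (tau - (1.0 if rr[i] < 0 else 0.0))
        dual = y @ a - (1.0 - tau) * ysum
        gap = f - dual
        if gap < tol * (1.0 + abs(f)):
            return b, f, it, gap, a
        d = 1.0 / (u / s + v / a)
        Xd = X * d.reshape(-1, 1)
        M = X.T @ Xd
        # predictor
        rav = -a * v
        rsu = -s * u
        r3t = r3 - (rsu - u * r2) / s + rav / a
        db = np.linalg.solve(M, Xd.T @ r3t - r1)
        da = d * (r3t - X @ db)
        ds = r2 - da
        dv = (rav - v * da) / a
        du = (rsu - u * ds) / s
        ap = 1.0; ad = 1.0
        for i in range(n):
            if da[i] < 0: ap = min(ap, -0.9995 * a[i] / da[i])
            if ds[i] < 0: ap = min(ap, -0.9995 * s[i] / ds[i])
            if du[i] < 0: ad = min(ad, -0.9995 * u[i] / du[i])
            if dv[i] < 0: ad = min(ad, -0.9995 * v[i] / dv[i])
        mu_aff = ((a + ap * da) @ (v + ad * dv) + (s + ap * ds) @ (u + ad * du)) / (2 * n)
        sigma = min(1.0, (mu_aff / mu) ** 3) if mu > 0 else 0.0
        # corrector
        rav = sigma * mu - a * v - ap * ad * da * dv
        rsu = sigma * mu - s * u - ap * ad * ds * du
        r3t = r3 - (rsu - u * r2) / s + rav / a
        db = np.linalg.solve(M, Xd.T @ r3t - r1)
        da = d * (r3t - X @ db)
        ds = r2 - da
        dv = (rav - v * da) / a
        du = (rsu - u * ds) / s
        ap = 1.0; ad = 1.0
        for i in range(n):
            if da[i] < 0: ap = min(ap, -0.9995 * a[i] / da[i])
            if ds[i] < 0: ap = min(ap, -0.9995 * s[i] / ds[i])
            if du[i] < 0: ad = min(ad, -0.9995 * u[i] / du[i])
            if dv[i] < 0: ad = min(ad, -0.9995 * v[i] / dv[i])
        b = b + ap * db
        a = a + ap * da
        s = s + ap * ds
        u = u + ad * du
        v = v + ad * dv
    return b, -1.0, max_iter, gap, a

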