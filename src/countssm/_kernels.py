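"""Numba kernels for the Kalman filter recursions (scalar-data path).

These are the hot loops behind :mod:`countssm.filters`.  Each kernel runs
the full forward recursion for one time series and returns flat arrays;
the public wrappers assemble them into :class:`~countssm.filters.FilterOutput`.

Status codes: 0 = ok, 1 = diverged (state norm beyond the guard, or a
non-finite observation prediction), 2 = numerical failure (non-positive or
non-finite innovation variance, or an indefinite covariance).
"""

from __future__ import annotations

import numpy as np
from numba import njit

OK = 0
DIVERGED = 1
NUMERICAL_FAILURE = 2

LOG2PI = np.log(2.0 * np.pi)


@njit(cache=True)
def _obs_pair(code: int, z: float, k: float) -> tuple[float, float]:
    """(f(z), f'(z)) for observation kind `code`; see model.OBS_CODE."""
    if code == 0:  # identity
        return z, 1.0
    if code == 1:  # exponential
        fz = np.exp(z)
        return fz, fz
    if code == 2:  # adh
        root = np.sqrt(z * z / 4.0 + k)
        return z / 2.0 + root, 0.5 + z / (4.0 * root)
    # softplus, stable in both tails
    a = z / k
    if a > 30.0:
        return z + k * np.exp(-a), 1.0 / (1.0 + np.exp(-a))
    if a < -30.0:
        e = np.exp(a)
        return k * e, e / (1.0 + e)
    e = np.exp(a)
    return k * np.log1p(e), e / (1.0 + e)


@njit(cache=True)
def linear_kf_kernel(A, Bu, c_row, Q, r, x0, P0, y, u, guard):
    """Standard linear Kalman filter with scalar observation row c_row."""
    T = y.shape[0]
    m = A.shape[0]
    x_pred = np.zeros((T, m))
    P_pred = np.zeros((T, m, m))
    x_filt = np.zeros((T, m))
    P_filt = np.zeros((T, m, m))
    nu = np.zeros(T)
    V = np.zeros(T)
    ll = np.zeros(T)
    status = OK
    fail_t = -1

    x = x0.copy()
    P = P0.copy()
    for t in range(T):
        xp = A @ x + Bu @ u[t]
        Pp = A @ P @ A.T + Q
        Pp = 0.5 * (Pp + Pp.T)
        ok = True
        s = 0.0
        for q in range(m):
            s += xp[q] * xp[q]
            if not np.isfinite(xp[q]):
                ok = False
        if (not ok) or np.sqrt(s) > guard:
            status = DIVERGED
            fail_t = t
            break
        v = float(c_row @ (Pp @ c_row) + r)
        if not np.isfinite(v):
            status = DIVERGED
            fail_t = t
            break
        if v <= 0.0:
            status = NUMERICAL_FAILURE
            fail_t = t
            break
        e = y[t] - float(c_row @ xp)
        K = (Pp @ c_row) / v
        x = xp + K * e
        P = Pp - np.outer(K, c_row @ Pp)
        P = 0.5 * (P + P.T)
        x_pred[t] = xp
        P_pred[t] = Pp
        x_filt[t] = x
        P_filt[t] = P
        nu[t] = e
        V[t] = v
        ll[t] = -0.5 * (np.log(v) + e * e / v + LOG2PI)
    return x_pred, P_pred, x_filt, P_filt, nu, V, ll, status, fail_t


@njit(cache=True)
def iekf_kernel(
    A, Bu, c_row, Q, r, x0, P0, y, u, obs_code, k, iter_tol, iter_max, guard
):
    """Iterated EKF with dense covariance propagation.

    The inner Gauss-Newton loop relinearizes the observation function around
    the current filtered-state iterate; every relative-change norm is
    recorded in ``traces`` for convergence instrumentation.
    """
    T = y.shape[0]
    m = A.shape[0]
    x_pred = np.zeros((T, m))
    P_pred = np.zeros((T, m, m))
    x_filt = np.zeros((T, m))
    P_filt = np.zeros((T, m, m))
    nu = np.zeros(T)
    V = np.zeros(T)
    ll = np.zeros(T)
    iters = np.zeros(T, np.int64)
    traces = np.zeros((T, iter_max))
    status = OK
    fail_t = -1

    x = x0.copy()
    P = P0.copy()
    for t in range(T):
        xp = A @ x + Bu @ u[t]
        Pp = A @ P @ A.T + Q
        Pp = 0.5 * (Pp + Pp.T)
        bad = False
        s = 0.0
        for q in range(m):
            s += xp[q] * xp[q]
            if not np.isfinite(xp[q]):
                bad = True
        if bad or np.sqrt(s) > guard:
            status = DIVERGED
            fail_t = t
            break

        xi = xp.copy()
        e = 0.0
        e_lin = 0.0
        v = 1.0
        K = np.zeros(m)
        H = np.zeros(m)
        for it in range(iter_max):
            z = float(c_row @ xi)
            fz, dfz = _obs_pair(obs_code, z, k)
            if not np.isfinite(fz):
                status = DIVERGED
                fail_t = t
                break
            H = dfz * c_row
            e = y[t] - fz
            v = float(H @ (Pp @ H) + r)
            if not np.isfinite(v):
                # overflow from a diverging observation prediction
                status = DIVERGED
                fail_t = t
                break
            if v <= 0.0:
                status = NUMERICAL_FAILURE
                fail_t = t
                break
            K = (Pp @ H) / v
            # relinearized prediction error: reduces to y - C x_pred in the
            # linear case and is the innovation entering the likelihood
            e_lin = e - float(H @ (xp - xi))
            xn = xp + K * e_lin
            dn = 0.0
            xin = 0.0
            for q in range(m):
                d = xn[q] - xi[q]
                dn += d * d
                xin += xi[q] * xi[q]
            rel = np.sqrt(dn) / max(np.sqrt(xin), 1e-30)
            traces[t, it] = rel
            iters[t] = it + 1
            xi = xn
            if rel < iter_tol:
                break
            nm = 0.0
            for q in range(m):
                nm += xi[q] * xi[q]
            if np.sqrt(nm) > guard:
                status = DIVERGED
                fail_t = t
                break
        if status != OK:
            break

        x = xi
        P = Pp - np.outer(K, H @ Pp)
        P = 0.5 * (P + P.T)
        # a covariance with a clearly negative diagonal has lost
        # (semi-)definiteness: flag rather than silently continue
        for q in range(m):
            if P[q, q] < -1e-8:
                status = NUMERICAL_FAILURE
                fail_t = t
        if status != OK:
            break
        x_pred[t] = xp
        P_pred[t] = Pp
        x_filt[t] = x
        P_filt[t] = P
        nu[t] = e_lin
        V[t] = v
        ll[t] = -0.5 * (np.log(v) + e_lin * e_lin / v + LOG2PI)
    return (
        x_pred,
        P_pred,
        x_filt,
        P_filt,
        nu,
        V,
        ll,
        iters,
        traces,
        status,
        fail_t,
    )


@njit(cache=True)
def svd_iekf_kernel(
    A,
    Bu,
    c_row,
    SQW,
    sR,
    x0,
    W0,
    s0,
    y,
    u,
    obs_code,
    k,
    iter_tol,
    iter_max,
    guard,
):
    """SVD square-root IEKF: covariances live as (W, sigma) factors.

    Predicted and filtered covariances are obtained by singular value
    decompositions of stacked pre-arrays, never by subtracting matrices,
    so they are positive semi-definite by construction.  ``SQW`` holds the
    non-zero rows of ``diag(sigma_Q) W_Q^T`` (rank(Q) rows — rank 1 for a
    single ARMA block), which is all of the dynamical-noise part of the
    time-update pre-array; ``sR`` is the square root of the scalar
    observation noise variance.
    """
    T = y.shape[0]
    m = A.shape[0]
    x_pred = np.zeros((T, m))
    P_pred = np.zeros((T, m, m))
    x_filt = np.zeros((T, m))
    P_filt = np.zeros((T, m, m))
    nu = np.zeros(T)
    V = np.zeros(T)
    ll = np.zeros(T)
    iters = np.zeros(T, np.int64)
    traces = np.zeros((T, iter_max))
    status = OK
    fail_t = -1

    x = x0.copy()
    WP = W0.copy()
    sP = s0.copy()
    rq = SQW.shape[0]
    pre = np.empty((m + rq, m))
    pre2 = np.empty((m + 1, m))
    for t in range(T):
        xp = A @ x + Bu @ u[t]
        bad = False
        s = 0.0
        for q in range(m):
            s += xp[q] * xp[q]
            if not np.isfinite(xp[q]):
                bad = True
        if bad or np.sqrt(s) > guard:
            status = DIVERGED
            fail_t = t
            break

        # time update: SVD of [diag(sP) WP' A' ; diag(sQ) WQ'], with the
        # structurally zero dynamical-noise rows dropped
        WA = WP.T @ A.T
        for i in range(m):
            for j in range(m):
                pre[i, j] = sP[i] * WA[i, j]
        for i in range(rq):
            for j in range(m):
                pre[m + i, j] = SQW[i, j]
        _, sv, Vt = np.linalg.svd(pre, full_matrices=False)
        WPp = Vt.T.copy()
        sPp = sv
        Pp = (WPp * (sPp**2)) @ WPp.T

        xi = xp.copy()
        e = 0.0
        e_lin = 0.0
        v = 1.0
        K = np.zeros(m)
        H = np.zeros(m)
        for it in range(iter_max):
            z = float(c_row @ xi)
            fz, dfz = _obs_pair(obs_code, z, k)
            if not np.isfinite(fz):
                status = DIVERGED
                fail_t = t
                break
            H = dfz * c_row
            e = y[t] - fz
            # measurement factorization: the ((1+m) x 1) pre-array
            # [sR ; diag(sPp) WPp' H'] has squared column norm V
            col = sPp * (WPp.T @ H)
            v = sR * sR
            for q in range(m):
                v += col[q] * col[q]
            if not np.isfinite(v):
                status = DIVERGED
                fail_t = t
                break
            if v <= 0.0:
                status = NUMERICAL_FAILURE
                fail_t = t
                break
            K = (Pp @ H) / v
            # relinearized prediction error: reduces to y - C x_pred in the
            # linear case and is the innovation entering the likelihood
            e_lin = e - float(H @ (xp - xi))
            xn = xp + K * e_lin
            dn = 0.0
            xin = 0.0
            for q in range(m):
                d = xn[q] - xi[q]
                dn += d * d
                xin += xi[q] * xi[q]
            rel = np.sqrt(dn) / max(np.sqrt(xin), 1e-30)
            traces[t, it] = rel
            iters[t] = it + 1
            xi = xn
            if rel < iter_tol:
                break
            nm = 0.0
            for q in range(m):
                nm += xi[q] * xi[q]
            if np.sqrt(nm) > guard:
                status = DIVERGED
                fail_t = t
                break
        if status != OK:
            break

        # measurement update of the factor:
        # SVD of [diag(sPp) WPp' (I - K H)' ; sR K']
        Wk = np.empty((m, m))
        for i in range(m):
            for j in range(m):
                acc = 0.0
                for q in range(m):
                    ikh = (1.0 if j == q else 0.0) - K[j] * H[q]
                    acc += WPp[q, i] * ikh
                Wk[i, j] = acc
        for i in range(m):
            for j in range(m):
                pre2[i, j] = sPp[i] * Wk[i, j]
        for j in range(m):
            pre2[m, j] = sR * K[j]
        _, sv2, Vt2 = np.linalg.svd(pre2, full_matrices=False)
        WP = Vt2.T.copy()
        sP = sv2
        x = xi

        x_pred[t] = xp
        P_pred[t] = Pp
        x_filt[t] = x
        P_filt[t] = (WP * (sP**2)) @ WP.T
        nu[t] = e_lin
        V[t] = v
        ll[t] = -0.5 * (np.log(v) + e_lin * e_lin / v + LOG2PI)
    return (
        x_pred,
        P_pred,
        x_filt,
        P_filt,
        nu,
        V,
        ll,
        iters,
        traces,
        status,
        fail_t,
    )
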