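"""Inner loops for stochastic gradient training.

The per-sample update sweep is the hot path (one pass touches every
parameter of the network for every training window, for up to 1000
epochs), so it is written as explicit loops and JIT-compiled with numba.
A pure-Python fallback with identical semantics is kept for environments
where compilation is unavailable; both paths are exercised by the tests.

All gradients are exact analytic derivatives of the per-sample error
E = 1/2 sum_k (u_k^d - u_k)^2 through the product-t-norm network, and are
cross-checked elsewhere against central finite differences.
"""

from __future__ import annotations

import math

import numpy as np

MIN_WIDTH = 1e-6


def _sgd_epoch_impl(X, T, order, c, s, a, b, w, pc, ps, pa, pb, pw,
                    gamma, lam, width_floor):
    """One epoch of per-sample updates with momentum, in place.

    Arrays: X (N, m) inputs, T (N, n) targets, order (N,) visit order;
    c, s (m, r) antecedent centres/widths; a (m, r), b (r) consequents;
    w (r, n) mixing weights; p* hold the previous parameter values for the
    momentum term  p(t+1) = p(t) - gamma * dE/dp + lam * (p(t) - p(t-1)).
    Widths are clamped at ``width_floor`` so no membership degenerates.

    Returns the summed squared error accumulated over the epoch (each
    sample's error measured just before its update), for monitoring and
    the adaptive learning rate.
    """
    N, m = X.shape
    r = c.shape[1]
    n = w.shape[1]
    mu = np.empty(r)
    y = np.empty(r)
    u = np.empty(n)
    e = np.empty(n)
    q = np.empty(r)
    tcoef = np.empty(r)
    sse = 0.0
    for oi in range(N):
        idx = order[oi]
        x = X[idx]
        # forward pass; exponents shifted by their minimum so the largest
        # firing strength is 1 (u and all gradients depend on mu only
        # through ratios, so the shift is exact)
        amin = np.inf
        for j in range(r):
            acc = 0.0
            yy = b[j]
            for i in range(m):
                z = (x[i] - c[i, j]) / s[i, j]
                acc += z * z
                yy += x[i] * a[i, j]
            mu[j] = acc
            y[j] = yy
            if acc < amin:
                amin = acc
        S = 0.0
        for j in range(r):
            mu[j] = math.exp(-(mu[j] - amin))
            S += mu[j]
        eu = 0.0
        for k in range(n):
            acc = 0.0
            for j in range(r):
                acc += w[j, k] * mu[j] * y[j]
            u[k] = acc / S
            e[k] = u[k] - T[idx, k]
            sse += e[k] * e[k]
            eu += e[k] * u[k]
        # shared per-rule factors (all from pre-update parameters)
        for j in range(r):
            qq = 0.0
            for k in range(n):
                qq += e[k] * w[j, k]
            q[j] = qq
            tcoef[j] = (y[j] * qq - eu) / S  # dE/dmu_j
        # mixing weights: dE/dw_jk = e_k mu_j y_j / S
        for j in range(r):
            y1s = mu[j] * y[j] / S
            for k in range(n):
                g = e[k] * y1s
                new = w[j, k] - gamma * g + lam * (w[j, k] - pw[j, k])
                pw[j, k] = w[j, k]
                w[j, k] = new
        for j in range(r):
            muS = mu[j] / S
            gb = q[j] * muS
            new = b[j] - gamma * gb + lam * (b[j] - pb[j])
            pb[j] = b[j]
            b[j] = new
            tm = tcoef[j] * mu[j]
            for i in range(m):
                ga = q[j] * muS * x[i]
                new = a[i, j] - gamma * ga + lam * (a[i, j] - pa[i, j])
                pa[i, j] = a[i, j]
                a[i, j] = new
                d = x[i] - c[i, j]
                sig = s[i, j]
                gc = tm * 2.0 * d / (sig * sig)
                gs = tm * 2.0 * d * d / (sig * sig * sig)
                newc = c[i, j] - gamma * gc + lam * (c[i, j] - pc[i, j])
                pc[i, j] = c[i, j]
                c[i, j] = newc
                news = s[i, j] - gamma * gs + lam * (s[i, j] - ps[i, j])
                ps[i, j] = s[i, j]
                if news < width_floor:
                    news = width_floor
                s[i, j] = news
    return sse


def _forward_sse_impl(X, T, c, s, a, b, w):
    """Summed squared output error of the current parameters on (X, T)."""
    N, m = X.shape
    r = c.shape[1]
    n = w.shape[1]
    mu = np.empty(r)
    y = np.empty(r)
    sse = 0.0
    for idx in range(N):
        x = X[idx]
        amin = np.inf
        for j in range(r):
            acc = 0.0
            yy = b[j]
            for i in range(m):
                z = (x[i] - c[i, j]) / s[i, j]
                acc += z * z
                yy += x[i] * a[i, j]
            mu[j] = acc
            y[j] = yy
            if acc < amin:
                amin = acc
        S = 0.0
        for j in range(r):
            mu[j] = math.exp(-(mu[j] - amin))
            S += mu[j]
        for k in range(n):
            acc = 0.0
            for j in range(r):
                acc += w[j, k] * mu[j] * y[j]
            err = acc / S - T[idx, k]
            sse += err * err
    return sse


try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit

    sgd_epoch = njit(cache=True)(_sgd_epoch_impl)
    forward_sse = njit(cache=True)(_forward_sse_impl)
    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    sgd_epoch = _sgd_epoch_impl
    forward_sse = _forward_sse_impl
    HAVE_NUMBA = False
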