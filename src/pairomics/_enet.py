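"""Elastic-net penalized logistic regression path solver.

FISTA (accelerated proximal gradient) on the glmnet-style objective

    (1/n) sum log(1 + exp(-y_i eta_i)) + lam * (alpha |w|_1 + (1-alpha)/2 |w|^2)

with an unpenalized intercept, warm-started along a descending lambda
path.  Compiled with numba; the tiny problem sizes of leave-one-out
stability selection make per-call overhead the dominant cost, which JIT
compilation removes.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a hard dependency in practice
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def deco(f):
            return f

        return deco if not (args and callable(args[0])) else args[0]


@njit(cache=True)
def _path_kernel(X, y, lambdas, alpha, L, tol, max_iter):  # pragma: no cover - jit
    n, p = X.shape
    n_lam = lambdas.shape[0]
    out = np.zeros((n_lam, p + 1))
    w = np.zeros(p)
    b = 0.0
    for li in range(n_lam):
        lam = lambdas[li]
        l1 = lam * alpha
        l2 = lam * (1.0 - alpha)
        step = 1.0 / (L + l2)
        wv = w.copy()
        bv = b
        w_prev = w.copy()
        b_prev = b
        t = 1.0
        for _ in range(max_iter):
            eta = X @ wv + bv
            pz = 1.0 / (1.0 + np.exp(-eta))
            g = (pz - y) / n
            gw = X.T @ g + l2 * wv
            gb = np.sum(g)
            wn = wv - step * gw
            # soft threshold
            for j in range(p):
                if wn[j] > step * l1:
                    wn[j] -= step * l1
                elif wn[j] < -step * l1:
                    wn[j] += step * l1
                else:
                    wn[j] = 0.0
            bn = bv - step * gb
            t_new = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t * t))
            mom = (t - 1.0) / t_new
            wv = wn + mom * (wn - w_prev)
            bv = bn + mom * (bn - b_prev)
            delta = np.abs(bn - b_prev)
            for j in range(p):
                d = np.abs(wn[j] - w_prev[j])
                if d > delta:
                    delta = d
            w_prev = wn.copy()
            b_prev = bn
            t = t_new
            if delta < tol:
                break
        w = w_prev.copy()
        b = b_prev
        out[li, :p] = w
        out[li, p] = b
    return out


def enet_logistic_path(
    X: np.ndarray,
    y: np.ndarray,
    lambdas: np.ndarray,
    alpha: float,
    tol: float = 1e-6,
    max_iter: int = 1500,
) -> np.ndarray:
    """Coefficient matrix (n_lambda, p+1); last column is the intercept."""
    X = np.ascontiguousarray(X, dtype=np.float64)
    y = np.ascontiguousarray(y, dtype=np.float64)
    lambdas = np.ascontiguousarray(lambdas, dtype=np.float64)
    n = X.shape[0]
    aug = np.hstack([X, np.ones((n, 1))])
    smax = np.linalg.svd(aug, compute_uv=False)[0]
    L = smax * smax / (4.0 * n) + 1e-12
    return _path_kernel(X, y, lambdas, float(alpha), float(L), float(tol), int(max_iter))
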