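"""Compiled leave-one-out tuning-curve loop.

Same computation as :func:`serialdep.decoding.tuning_curve_loo` (bin means
of training trials, Ledoit–Wolf shrinkage covariance of training-fold
residuals, Mahalanobis distances, sign-flip and mean-centering), written
so numba can compile the per-fold loop. The within-group scatter is formed
by downdating the precomputed total scatter instead of materializing the
residual matrix per fold; the two routes agree to machine precision and are
cross-checked in the test suite.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*a, **k):
        def deco(f):
            return f

        return deco if not (len(a) == 1 and callable(a[0])) else a[0]


@njit(cache=True)
def _loo_all_jit(X: np.ndarray, bins: np.ndarray, n_bins: int, identity: bool) -> np.ndarray:
    n, k = X.shape
    out = np.full((n, n_bins), np.nan)
    G = X.T @ X  # total scatter, downdated per fold
    nsq = np.empty(n)
    for j in range(n):
        s = 0.0
        for c in range(k):
            s += X[j, c] * X[j, c]
        nsq[j] = s

    for i in range(n):
        row = bins[i]
        counts = np.zeros(n_bins, dtype=np.int64)
        Ssum = np.zeros((n_bins, k))
        for j in range(n):
            if j == i:
                continue
            b = row[j]
            counts[b] += 1
            for c in range(k):
                Ssum[b, c] += X[j, c]
        empty = False
        for b in range(n_bins):
            if counts[b] == 0:
                empty = True
        if empty:
            continue

        M = np.empty((n_bins, k))
        for b in range(n_bins):
            for c in range(k):
                M[b, c] = Ssum[b, c] / counts[b]
        diff = M - X[i]

        d = np.empty(n_bins)
        if identity:
            for b in range(n_bins):
                s = 0.0
                for c in range(k):
                    s += diff[b, c] * diff[b, c]
                d[b] = np.sqrt(s)
        else:
            ntr = n - 1
            # within-group scatter: G - x_i x_i^T - sum_b c_b M_b M_b^T
            S = G.copy()
            for a in range(k):
                for c in range(k):
                    S[a, c] -= X[i, a] * X[i, c]
            for b in range(n_bins):
                cb = counts[b]
                for a in range(k):
                    for c in range(k):
                        S[a, c] -= cb * M[b, a] * M[b, c]
            S /= ntr
            # Ledoit-Wolf intensity from the training residuals
            tr = 0.0
            for a in range(k):
                tr += S[a, a]
            mu = tr / k
            ssq = 0.0
            for a in range(k):
                for c in range(k):
                    ssq += S[a, c] * S[a, c]
            delta2 = ssq - k * mu * mu
            msq = np.empty(n_bins)
            for b in range(n_bins):
                s = 0.0
                for c in range(k):
                    s += M[b, c] * M[b, c]
                msq[b] = s
            norms4 = 0.0
            for j in range(n):
                if j == i:
                    continue
                b = row[j]
                p = 0.0
                for c in range(k):
                    p += X[j, c] * M[b, c]
                rsq = nsq[j] - 2.0 * p + msq[b]
                norms4 += rsq * rsq
            beta_bar = (norms4 / ntr - ssq) / ntr
            beta2 = min(beta_bar, delta2)
            alpha = 0.0 if delta2 <= 0.0 else beta2 / delta2
            cov = (1.0 - alpha) * S
            for a in range(k):
                cov[a, a] += alpha * mu
            sol = np.linalg.solve(cov, diff.T)  # (k, n_bins)
            for b in range(n_bins):
                s = 0.0
                for c in range(k):
                    s += diff[b, c] * sol[c, b]
                d[b] = np.sqrt(max(s, 0.0))

        mean_d = 0.0
        for b in range(n_bins):
            mean_d += d[b]
        mean_d /= n_bins
        for b in range(n_bins):
            out[i, b] = -(d[b] - mean_d)
    return out
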