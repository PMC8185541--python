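"""Brute-force / closed-form oracles used by the tests.

Each oracle is written independently of the implementation it checks:
direct translations of definitions (percentile interpolation, BH step-up,
nearest-neighbour search, the missing-value filter sentence) and exact
normal order-statistic expectations by numerical quadrature.
"""

from __future__ import annotations

import numpy as np
from scipy import integrate, special, stats


def percentile_type7(xs, q):
    """Linear interpolation of order statistics (type-7), from scratch."""
    xs = sorted(float(x) for x in xs)
    n = len(xs)
    h = (n - 1) * (q / 100.0)
    lo = int(np.floor(h))
    g = h - lo
    if lo + 1 >= n:
        return xs[-1]
    return xs[lo] * (1 - g) + xs[lo + 1] * g


def idr_oracle(xs):
    return percentile_type7(xs, 90) - percentile_type7(xs, 10)


def expected_normal_order_stat(n, k):
    """E[X_(k)] of n iid standard normals (k 1-based), by quadrature."""
    logc = (np.log(n) + special.gammaln(n) - special.gammaln(k)
            - special.gammaln(n - k + 1))
    def f(x):
        return x * np.exp(logc + (k - 1) * stats.norm.logcdf(x)
                          + (n - k) * stats.norm.logsf(x)
                          + stats.norm.logpdf(x))
    v, _ = integrate.quad(f, -12, 12, limit=200)
    return v


def expected_normal_idr(n):
    """Exact E[q90 - q10] of the type-7 sample IDR of n iid N(0,1)."""
    def eq(q):
        h = (n - 1) * q + 1
        lo = int(np.floor(h))
        g = h - lo
        v = (1 - g) * expected_normal_order_stat(n, lo)
        if g > 0:
            v += g * expected_normal_order_stat(n, lo + 1)
        return v
    return eq(0.9) - eq(0.1)


def bh_stepup(p):
    """Benjamini-Hochberg step-up adjusted p-values, literal definition."""
    p = np.asarray(p, dtype=float)
    n = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(n)
    running_min = 1.0
    for rank_from_top in range(n, 0, -1):
        i = order[rank_from_top - 1]
        running_min = min(running_min, p[i] * n / rank_from_top)
        adj[i] = running_min
    return np.minimum(adj, 1.0)


def knn_impute_oracle(X, k):
    """Exhaustive nearest-neighbour imputation over protein rows."""
    X = np.asarray(X, dtype=float)
    n, m = X.shape
    out = X.copy()
    for i in range(n):
        for j in range(m):
            if not np.isnan(X[i, j]):
                continue
            cands = []
            for r in range(n):
                if r == i or np.isnan(X[r, j]):
                    continue
                shared = ~np.isnan(X[i]) & ~np.isnan(X[r])
                if not shared.any():
                    continue
                d = np.sqrt(np.sum((X[i, shared] - X[r, shared]) ** 2)
                            * m / shared.sum())
                cands.append((d, r))
            cands.sort(key=lambda t: t[0])
            donors = [r for _, r in cands[:k]]
            if donors:
                out[i, j] = np.mean([X[r, j] for r in donors])
            else:
                out[i, j] = np.nanmean(X[i])
    return out


def filter_rule_oracle(n_miss_g1, n_miss_g2, n1=12, n2=10):
    """Status of a protein with the given per-group missing counts, read
    straight off the filtering rule: drop when overall missingness exceeds
    30 %, unless one group is > 90 % missing and the other < 10 % missing
    (then keep and zero-impute the high-missing group)."""
    f1, f2 = n_miss_g1 / n1, n_miss_g2 / n2
    overall = (n_miss_g1 + n_miss_g2) / (n1 + n2)
    exception = (f1 > 0.9 and f2 < 0.1) or (f2 > 0.9 and f1 < 0.1)
    if exception:
        return "kept_zero_imputed"
    if overall > 0.3:
        return "dropped"
    return "kept"


def pooled_t_oracle(x1, x2):
    """Ordinary two-sample pooled-variance t statistic."""
    n1, n2 = len(x1), len(x2)
    s2 = (((n1 - 1) * np.var(x1, ddof=1) + (n2 - 1) * np.var(x2, ddof=1))
          / (n1 + n2 - 2))
    return (np.mean(x2) - np.mean(x1)) / np.sqrt(s2 * (1 / n1 + 1 / n2))


def pca_retained_oracle(X, threshold):
    """Retained component count from a direct eigendecomposition of the
    sample covariance of protein-centered data."""
    Xc = X - X.mean(axis=1, keepdims=True)   # proteins x samples
    C = Xc.T @ Xc                            # sample-space Gram matrix
    evals = np.linalg.eigvalsh(C)[::-1]
    frac = evals / evals.sum()
    return int(np.searchsorted(np.cumsum(frac), threshold) + 1)
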