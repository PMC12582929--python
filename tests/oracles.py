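"""Independent brute-force reference implementations used only by tests.

These deliberately re-derive each quantity from first principles (explicit
sums, eigendecompositions, closed forms) so they share no code path with the
package.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats


def student_t_pvalue(a, b) -> float:
    """Textbook pooled-variance two-sided t-test."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    n1, n2 = len(a), len(b)
    m1 = sum(a) / n1
    m2 = sum(b) / n2
    s1 = sum((x - m1) ** 2 for x in a) / (n1 - 1)
    s2 = sum((x - m2) ** 2 for x in b) / (n2 - 1)
    sp2 = ((n1 - 1) * s1 + (n2 - 1) * s2) / (n1 + n2 - 2)
    t = (m2 - m1) / math.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    return 2.0 * stats.t.sf(abs(t), df=n1 + n2 - 2)


def storey_q(p, lam=0.5):
    """Hand enumeration of the Storey q-value formula (fixed lambda)."""
    p = list(map(float, p))
    m = len(p)
    pi0 = min(1.0, sum(1 for x in p if x > lam) / (m * (1.0 - lam)))
    pi0 = max(pi0, 1e-300)
    order = sorted(range(m), key=lambda i: p[i])
    q = [0.0] * m
    prev = math.inf
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        val = min(prev, pi0 * m * p[i] / rank, 1.0)
        q[i] = val
        prev = val
    return q


def bh_adjust(p):
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    prev = np.inf
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        prev = min(prev, m * p[i] / rank, 1.0)
        adj[i] = prev
    return adj


def pca_eigen(X):
    """Eigendecomposition of the (n-1)-normalised covariance matrix.

    Returns (eigenvalues desc, explained pct desc, loadings columns).
    """
    X = np.asarray(X, float)
    Xc = X - X.mean(axis=0)
    cov = Xc.T @ Xc / (X.shape[0] - 1)
    w, V = np.linalg.eigh(cov)
    order = np.argsort(w)[::-1]
    w = np.clip(w[order], 0.0, None)
    pct = 100.0 * w / w.sum()
    return w, pct, V[:, order]


def pearson_r(x, y) -> float:
    """Sum-of-products Pearson correlation."""
    x, y = list(map(float, x)), list(map(float, y))
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    return sxy / math.sqrt(sxx * syy)


def ridge_closed_form(X, y, alpha):
    """beta = (X'X + alpha I)^-1 X'y with intercept via centering."""
    X, y = np.asarray(X, float), np.asarray(y, float)
    xm, ym = X.mean(axis=0), y.mean()
    Xc, yc = X - xm, y - ym
    beta = np.linalg.solve(Xc.T @ Xc + alpha * np.eye(X.shape[1]), Xc.T @ yc)
    b0 = ym - xm @ beta
    return beta, b0


def mean_baseline_loocv_mse(y):
    """Closed-form LOOCV MSE of the train-mean predictor."""
    y = np.asarray(y, float)
    n = len(y)
    errs = [(y[i] - np.delete(y, i).mean()) ** 2 for i in range(n)]
    return float(np.mean(errs))
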