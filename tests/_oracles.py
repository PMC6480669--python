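"""Independent brute-force oracles, kept separate from production code.

Every routine here is a literal step-by-step transcription of the
textbook algorithm it checks, written with explicit loops and the
plainest linear algebra available, so that agreement with the package
is meaningful.
"""

from __future__ import annotations

import itertools

import numpy as np


def nipals_pls1_reference(X, y, A):
    """Textbook PLS1 NIPALS, one explicit deflation step at a time.

    Returns (x_mean, y_mean, W, P, q, T, beta). Weight vectors are
    unit-norm; only X is deflated for the regression vector (y
    deflation included as in the classical write-up; it does not change
    the solution for a single response).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    x_mean = X.mean(axis=0)
    y_mean = y.mean()
    E = X - x_mean
    f = y - y_mean
    W = np.zeros((p, A))
    P = np.zeros((p, A))
    T = np.zeros((n, A))
    q = np.zeros(A)
    for a in range(A):
        w = np.zeros(p)
        for j in range(p):  # w_j = sum_i E_ij f_i
            w[j] = sum(E[i, j] * f[i] for i in range(n))
        w = w / np.sqrt(np.sum(w**2))
        t = np.array([sum(E[i, j] * w[j] for j in range(p)) for i in range(n)])
        tt = float(np.sum(t * t))
        pa = np.array([sum(t[i] * E[i, j] for i in range(n)) / tt for j in range(p)])
        qa = sum(t[i] * f[i] for i in range(n)) / tt
        for i in range(n):
            for j in range(p):
                E[i, j] -= t[i] * pa[j]
            f[i] -= qa * t[i]
        W[:, a], P[:, a], T[:, a], q[a] = w, pa, t, qa
    beta = W @ np.linalg.inv(P.T @ W) @ q
    return x_mean, y_mean, W, P, q, T, beta


def ols_normal_equations(X, y, intercept=True):
    """OLS via explicitly inverted normal equations; returns (coef, b0)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if intercept:
        D = np.hstack([X, np.ones((X.shape[0], 1))])
    else:
        D = X
    sol = np.linalg.inv(D.T @ D) @ D.T @ y
    if intercept:
        return sol[:-1], sol[-1]
    return sol, np.zeros_like(sol[:1] @ np.zeros((X.shape[1], 0)))


def lstsq_pinv(A, B):
    """Least-squares solution by explicit Moore-Penrose pseudo-inverse."""
    return np.linalg.pinv(np.asarray(A, dtype=float)) @ np.asarray(B, dtype=float)


def wilcoxon_exact_two_sided(d):
    """Exact two-sided signed-rank p by enumerating all sign patterns.

    ``d`` must be free of zeros. Ranks of |d| use midranks. The
    two-sided p is P(W+ <= w_lo) + P(W+ >= w_hi) with w_lo/w_hi the
    observed min/max of (W+, W-) under the null of sign symmetry.
    """
    d = np.asarray(d, dtype=float)
    n = d.size
    from scipy.stats import rankdata

    ranks = rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    w_lo, w_hi = min(w_plus, w_minus), max(w_plus, w_minus)
    count = 0
    for signs in itertools.product([0, 1], repeat=n):
        w = float(sum(r for r, s in zip(ranks, signs) if s))
        if w <= w_lo + 1e-12 or w >= w_hi - 1e-12:
            count += 1
    return count / 2.0**n


def canonical_correlations_reference(Xa, Xb):
    """Canonical correlations via the generalized-eigenvalue formulation.

    Blocks are centered and PCA-reduced to full rank first so the
    covariance inverses exist; returns non-increasing correlations.
    """
    Xa = np.asarray(Xa, dtype=float)
    Xb = np.asarray(Xb, dtype=float)
    Xa = Xa - Xa.mean(axis=0)
    Xb = Xb - Xb.mean(axis=0)

    def reduce(X):
        U, s, Vt = np.linalg.svd(X, full_matrices=False)
        r = int(np.sum(s > 1e-10 * s[0]))
        return X @ Vt[:r].T

    Za, Zb = reduce(Xa), reduce(Xb)
    Saa, Sbb = Za.T @ Za, Zb.T @ Zb
    Sab = Za.T @ Zb
    M = np.linalg.inv(Saa) @ Sab @ np.linalg.inv(Sbb) @ Sab.T
    eig = np.linalg.eigvals(M).real
    eig = np.clip(eig, 0.0, 1.0)
    return np.sqrt(np.sort(eig)[::-1])
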