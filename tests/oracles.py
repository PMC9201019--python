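"""Independent reference computations used by the tests.

These deliberately avoid the package's own code paths: brute-force
minimisation for the geometric median, naive triple loops for the fuzzy
objective and validity indices.
"""

import numpy as np
from scipy.optimize import minimize


def objective_sum_dist(y, X, eta=None):
    eta = np.ones(len(X)) if eta is None else eta
    return float(sum(e * np.linalg.norm(y - x) for e, x in zip(eta, X)))


def geometric_median_oracle(X, eta=None):
    """Multi-start derivative-free minimiser of the weighted distance sum.

    Starts Nelder-Mead from every (slightly perturbed) data point plus the
    centroid and the coordinate-wise median, then compares against the data
    points themselves (the optimum can sit on a vertex).
    """
    X = np.asarray(X, float)
    starts = [x + 1e-4 for x in X] + [X.mean(axis=0), np.median(X, axis=0)]
    best, best_val = None, np.inf
    for s in starts:
        res = minimize(
            objective_sum_dist, s, args=(X, eta), method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 20000},
        )
        if res.fun < best_val:
            best, best_val = res.x, res.fun
    for x in X:  # vertex candidates
        val = objective_sum_dist(x, X, eta)
        if val < best_val:
            best, best_val = x.copy(), val
    return best


def naive_Jm(Z, U, V, m):
    total = 0.0
    for k in range(len(Z)):
        for i in range(len(V)):
            total += U[i, k] ** m * np.linalg.norm(Z[k] - V[i]) ** 2
    return total


def naive_tss(Z, U, V):
    c = len(V)
    compact = naive_Jm(Z, U, V, 2)
    seps = [
        np.linalg.norm(V[i] - V[j]) ** 2
        for i in range(c) for j in range(c) if i != j
    ]
    denom = min(seps) + 1.0 / c
    return compact / denom + (sum(seps) / (c * (c - 1))) / denom


def naive_xie_beni(Z, U, V):
    c = len(V)
    compact = naive_Jm(Z, U, V, 2)
    min_sep = min(
        np.linalg.norm(V[i] - V[j]) ** 2
        for i in range(c) for j in range(c) if i != j
    )
    return compact / (len(Z) * min_sep)


def in_convex_hull(y, X, tol=1e-6):
    """Feasibility of y = X^T w, w >= 0, sum w = 1, via penalised NNLS."""
    from scipy.optimize import nnls

    A = np.vstack([X.T, 1e6 * np.ones(len(X))])
    b = np.concatenate([y, [1e6]])
    w, _ = nnls(A, b)
    return np.linalg.norm(X.T @ w - y) < tol and abs(w.sum() - 1) < tol
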