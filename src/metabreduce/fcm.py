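"""Fuzzy c-means clustering by Picard (alternating) iteration.

Minimises the fuzzy within-cluster sum of squares

    J_m(U, V) = sum_k sum_i u_ik^m * ||z_k - v_i||^2    (squared Euclidean)

subject to the fuzzy-partition constraints: memberships in [0, 1], no
empty cluster, and each data point's memberships summing to 1.  The
stationary updates are

    u_ik = ( sum_j (d_ik^2 / d_jk^2)^{1/(m-1)} )^{-1}
    v_i  = sum_k u_ik^m z_k / sum_k u_ik^m

iterated as V -> U -> V until the Frobenius norm of the center change
drops below epsilon.  Centers are initialised as c distinct rows of Z
sampled without replacement; multiple seeded restarts keep the best
(lowest final J_m) solution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator, ClusterMixin

from .errors import DegenerateClusterError, DomainError

__all__ = [
    "FuzzyClusterModel",
    "objective_Jm",
    "update_memberships",
    "update_centers",
    "fit_fcm",
    "FuzzyCMeans",
]

ZERO_DIST_TOL = 1e-12


@dataclass
class FuzzyClusterModel:
    """Fitted fuzzy partition: U (c x n), centers V (c x d), J_m trace."""

    U: np.ndarray
    V: np.ndarray
    m: float
    objective_trace: list[float] = field(default_factory=list)
    iterations: int = 0
    converged: bool = False
    seed_used: int | None = None

    @property
    def objective(self) -> float:
        return self.objective_trace[-1]

    @property
    def n_clusters(self) -> int:
        return self.V.shape[0]


def _check_shapes(Z: np.ndarray, U: np.ndarray, V: np.ndarray) -> None:
    if U.shape != (V.shape[0], Z.shape[0]) or V.shape[1] != Z.shape[1]:
        raise DomainError(
            f"inconsistent shapes: Z {Z.shape}, U {U.shape}, V {V.shape}"
        )


def objective_Jm(Z: np.ndarray, U: np.ndarray, V: np.ndarray, m: float = 2.0) -> float:
    """J_m = sum_k sum_i u_ik^m ||z_k - v_i||^2."""
    Z, U, V = np.asarray(Z, float), np.asarray(U, float), np.asarray(V, float)
    _check_shapes(Z, U, V)
    D2 = cdist(V, Z, "sqeuclidean")
    return float(np.sum(U**m * D2))


def update_memberships(Z: np.ndarray, V: np.ndarray, m: float = 2.0) -> np.ndarray:
    """Membership update; columns sum to 1.

    Points at zero distance from one or more centers split their membership
    equally among those centers (the stationary update divides by zero there).
    """
    Z, V = np.asarray(Z, float), np.asarray(V, float)
    if m <= 1:
        raise DomainError("fuzzifier m must be > 1")
    D2 = cdist(V, Z, "sqeuclidean")  # c x n
    U = np.zeros_like(D2)
    zero_cols = (D2 < ZERO_DIST_TOL).any(axis=0)
    if zero_cols.any():
        hits = D2[:, zero_cols] < ZERO_DIST_TOL
        U[:, zero_cols] = hits / hits.sum(axis=0)
    reg = ~zero_cols
    if reg.any():
        P = D2[:, reg] ** (-1.0 / (m - 1.0))
        U[:, reg] = P / P.sum(axis=0)
    return U


def update_centers(Z: np.ndarray, U: np.ndarray, m: float = 2.0) -> np.ndarray:
    """Center update v_i = sum_k u_ik^m z_k / sum_k u_ik^m."""
    Z, U = np.asarray(Z, float), np.asarray(U, float)
    W = U**m
    denom = W.sum(axis=1)
    if np.any(denom <= 0):
        raise DegenerateClusterError(
            f"cluster(s) {np.nonzero(denom <= 0)[0].tolist()} have no membership mass"
        )
    return (W @ Z) / denom[:, None]


def _single_run(
    Z: np.ndarray,
    c: int,
    m: float,
    epsilon: float,
    max_iter: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, list[float], int, bool]:
    uniq = np.unique(Z, axis=0)
    if len(uniq) < c:
        raise DomainError(f"need >= {c} distinct rows to place {c} centers")
    V = uniq[rng.choice(len(uniq), size=c, replace=False)].copy()
    trace: list[float] = []
    converged = False
    iterations = 0
    for _ in range(max_iter):
        U = update_memberships(Z, V, m)
        V_new = update_centers(Z, U, m)
        trace.append(objective_Jm(Z, U, V_new, m))
        shift = float(np.linalg.norm(V_new - V))
        V = V_new
        iterations += 1
        if shift < epsilon:
            converged = True
            break
    U = update_memberships(Z, V, m)  # leave U consistent with the final V
    trace.append(objective_Jm(Z, U, V, m))
    return U, V, trace, iterations, converged


def fit_fcm(
    Z: np.ndarray,
    c: int,
    m: float = 2.0,
    epsilon: float = 1e-5,
    max_iter: int = 100,
    seed: int | None = None,
    restarts: int = 10,
) -> FuzzyClusterModel:
    """Fit FCM with seeded restarts; returns the lowest-J_m solution."""
    Z = np.atleast_2d(np.asarray(Z, float))
    n = Z.shape[0]
    if not 1 < c < n:
        raise DomainError(f"cluster count must satisfy 1 < c < n (c={c}, n={n})")
    if restarts < 1:
        raise DomainError("restarts must be >= 1")
    rng = np.random.default_rng(seed)
    best: FuzzyClusterModel | None = None
    failures = 0
    attempts = 0
    while attempts < restarts:
        try:
            U, V, trace, iters, conv = _single_run(Z, c, m, epsilon, max_iter, rng)
        except DegenerateClusterError:
            failures += 1
            if failures > 5 * restarts:
                raise
            continue
        attempts += 1
        if best is None or trace[-1] < best.objective_trace[-1]:
            best = FuzzyClusterModel(U, V, m, trace, iters, conv, seed_used=seed)
    assert best is not None
    return best


class FuzzyCMeans(BaseEstimator, ClusterMixin):
    """Fuzzy c-means clustering with a scikit-learn estimator interface.

    Parameters
    ----------
    n_clusters : int, default 2
        Number of clusters c, with 1 < c < n_samples.
    m : float, default 2.0
        Fuzzifier (> 1); larger values give softer partitions.
    tol : float, default 1e-5
        Frobenius-norm threshold on the center change.
    max_iter : int, default 100
    n_init : int, default 10
        Seeded restarts; the lowest-J_m run is kept.
    random_state : int or None

    Attributes
    ----------
    cluster_centers_ : ndarray (c, d)
    membership_ : ndarray (c, n)
        Fuzzy partition U; columns sum to 1.
    labels_ : ndarray (n,)
        Crisp argmax labels (ties to the smallest cluster index).
    objective_ : float
        Final J_m.
    objective_trace_ : list of float
    n_iter_ : int
    converged_ : bool
    """

    def __init__(
        self,
        n_clusters: int = 2,
        m: float = 2.0,
        tol: float = 1e-5,
        max_iter: int = 100,
        n_init: int = 10,
        random_state: int | None = None,
    ) -> None:
        self.n_clusters = n_clusters
        self.m = m
        self.tol = tol
        self.max_iter = max_iter
        self.n_init = n_init
        self.random_state = random_state

    def fit(self, X: np.ndarray, y: None = None) -> "FuzzyCMeans":
        model = fit_fcm(
            X,
            c=self.n_clusters,
            m=self.m,
            epsilon=self.tol,
            max_iter=self.max_iter,
            seed=self.random_state,
            restarts=self.n_init,
        )
        self.model_ = model
        self.cluster_centers_ = model.V
        self.membership_ = model.U
        self.labels_ = np.argmax(model.U, axis=0)
        self.objective_ = model.objective
        self.objective_trace_ = model.objective_trace
        self.n_iter_ = model.iterations
        self.converged_ = model.converged
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Memberships of new points against the fitted centers (n x c)."""
        U = update_memberships(np.atleast_2d(np.asarray(X, float)),
                               self.cluster_centers_, self.m)
        return U.T

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.argmax(self.predict_proba(X), axis=1)
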