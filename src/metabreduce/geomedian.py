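"""Weighted geometric median via the (modified) Weiszfeld algorithm.

The representative of a region is the point ``y*`` minimising the weighted
sum of Euclidean distances to the region's replicate vectors::

    C(y) = sum_i eta_i * ||y - x_i||

The classical Weiszfeld fixed-point iteration

    T(y) = sum_i eta_i x_i / ||y - x_i||  /  sum_i eta_i / ||y - x_i||

is undefined whenever ``y`` coincides with a data point.  The Vardi-Zhang
modification replaces the update by a convex combination

    y  <-  (1 - psi) * T~(y) + psi * y,     psi = min(1, eta(y) / r(y)),

where ``T~`` sums over non-coincident points only, ``eta(y)`` is the weight
of a coincident data point (0 if none), and ``r(y) = ||R~(y)||`` with
``R~(y) = sum_{x_i != y} eta_i (x_i - y)/||x_i - y||`` the negative gradient
of C away from data points (convention 0/0 = 0).  The modified step is
total: at a data point whose weight dominates the pull of the others
(``eta_k >= r(x_k)``) it recognises the vertex as optimal and stays put,
and away from the data it reduces exactly to the classical update.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from .errors import CoincidenceError, DomainError
from .io import RegionBlock

__all__ = [
    "WeightedPointSet",
    "GeoMedianResult",
    "objective_C",
    "weiszfeld_T",
    "r_tilde",
    "modified_step",
    "geometric_median",
    "reduce_region_mwa",
    "GeometricMedian",
]

#: two points closer than this (Euclidean) are treated as coincident
COINCIDENCE_TOL = 1e-12


@dataclass
class WeightedPointSet:
    """``n`` data vectors in R^d (rows of ``X``) with positive weights."""

    X: np.ndarray
    eta: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        if self.eta is None:
            self.eta = np.ones(self.X.shape[0])
        self.eta = np.asarray(self.eta, dtype=float)
        if self.X.shape[0] < 1 or self.X.shape[1] < 1:
            raise DomainError("point set must have n >= 1 points in d >= 1 dims")
        if self.eta.shape != (self.X.shape[0],):
            raise DomainError("one weight per point required")
        if np.any(self.eta <= 0):
            raise DomainError("weights must be strictly positive")
        if not np.all(np.isfinite(self.X)):
            raise DomainError("non-finite coordinates in point set")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def d(self) -> int:
        return self.X.shape[1]


@dataclass
class GeoMedianResult:
    y: np.ndarray
    objective: float
    iterations: int
    converged: bool
    objective_trace: list[float] = field(default_factory=list)


def _distances(y: np.ndarray, points: WeightedPointSet) -> np.ndarray:
    y = np.asarray(y, dtype=float)
    if y.shape != (points.d,):
        raise DomainError(f"y has shape {y.shape}, expected ({points.d},)")
    return np.linalg.norm(points.X - y, axis=1)


def objective_C(y: np.ndarray, points: WeightedPointSet) -> float:
    """Weighted sum of (unsquared) Euclidean distances from ``y`` to X."""
    return float(points.eta @ _distances(y, points))


def weiszfeld_T(
    y: np.ndarray, points: WeightedPointSet, tol: float = COINCIDENCE_TOL
) -> np.ndarray:
    """Classical Weiszfeld operator; errors if ``y`` coincides with a point."""
    dist = _distances(y, points)
    if np.any(dist < tol):
        k = int(np.argmin(dist))
        raise CoincidenceError(
            f"y coincides with data point {k}; use the modified step"
        )
    w = points.eta / dist
    return (w @ points.X) / w.sum()


def r_tilde(
    y: np.ndarray, points: WeightedPointSet, tol: float = COINCIDENCE_TOL
) -> np.ndarray:
    """R~(y): sum of unit pulls toward non-coincident points (neg. gradient)."""
    dist = _distances(y, points)
    active = dist >= tol
    if not np.any(active):
        return np.zeros(points.d)
    diffs = points.X[active] - np.asarray(y, dtype=float)
    return (points.eta[active] / dist[active]) @ diffs


def modified_step(
    y: np.ndarray, points: WeightedPointSet, tol: float = COINCIDENCE_TOL
) -> np.ndarray:
    """One Vardi-Zhang update; well-defined for any ``y``, including y in X."""
    y = np.asarray(y, dtype=float)
    dist = _distances(y, points)
    coincident = dist < tol
    eta_y = float(points.eta[coincident].sum())
    active = ~coincident
    if not np.any(active):
        # every data point sits at y: y is the optimum
        return y.copy()
    w = points.eta[active] / dist[active]
    T = (w @ points.X[active]) / w.sum()
    diffs = points.X[active] - y
    R = (points.eta[active] / dist[active]) @ diffs
    r = float(np.linalg.norm(R))
    if eta_y == 0.0:
        psi = 0.0  # covers the 0/0 = 0 convention
    elif r == 0.0:
        psi = 1.0
    else:
        psi = min(1.0, eta_y / r)
    return (1.0 - psi) * T + psi * y


def geometric_median(
    points: WeightedPointSet,
    epsilon: float = 1e-5,
    max_iter: int = 100,
    y0: np.ndarray | str | None = "zero",
    tol: float = COINCIDENCE_TOL,
) -> GeoMedianResult:
    """Iterate the modified Weiszfeld step until the move is below ``epsilon``.

    The default start is the zero vector.  A start coinciding with a data
    point is allowed: the modified step is total, escaping a non-optimal
    vertex (psi < 1) and recognising a dominant vertex as a fixed point
    (psi = 1, giving a zero move and immediate convergence).  Perturbing
    such a start off the data instead would risk a false stop: the very
    first plain-Weiszfeld moves near a vertex can be smaller than epsilon
    even when the vertex is not the optimum.
    """
    if epsilon <= 0 or max_iter < 1:
        raise DomainError("epsilon must be > 0 and max_iter >= 1")
    if points.n == 1:
        y = points.X[0].copy()
        return GeoMedianResult(y, 0.0, 0, True, [0.0])
    if y0 is None or (isinstance(y0, str) and y0 == "zero"):
        y = np.zeros(points.d)
    else:
        y = np.asarray(y0, dtype=float).copy()
        if y.shape != (points.d,):
            raise DomainError(f"y0 has shape {y.shape}, expected ({points.d},)")
    trace = [objective_C(y, points)]
    converged = False
    iterations = 0
    for _ in range(max_iter):
        y_new = modified_step(y, points, tol=tol)
        iterations += 1
        trace.append(objective_C(y_new, points))
        step = float(np.linalg.norm(y_new - y))
        y = y_new
        if step < epsilon:
            converged = True
            break
    return GeoMedianResult(y, trace[-1], iterations, converged, trace)


def reduce_region_mwa(
    block: RegionBlock,
    epsilon: float = 1e-5,
    max_iter: int = 100,
    y0: np.ndarray | str | None = "zero",
) -> np.ndarray:
    """Geometric median of a region's replicate columns (unit weights)."""
    if block.scale != "log":
        raise DomainError("reduce_region_mwa expects a log-scale block")
    points = WeightedPointSet(block.values.T)
    return geometric_median(points, epsilon=epsilon, max_iter=max_iter, y0=y0).y


class GeometricMedian(BaseEstimator):
    """Weighted geometric median as a scikit-learn style estimator.

    Parameters
    ----------
    epsilon : float, default 1e-5
        Stop when the Euclidean move between iterates falls below this.
    max_iter : int, default 100
        Iteration cap.
    y0 : array-like, "zero" or None, default "zero"
        Starting point (perturbed off the data if coincident).
    weights : array-like or None
        Per-point weights ``eta_i`` (default: all ones).

    Attributes
    ----------
    median_ : ndarray of shape (d,)
        The fitted representative ``y*``.
    objective_ : float
        ``C(median_)``.
    n_iter_ : int
    converged_ : bool
    objective_trace_ : list of float
        ``C`` at the start and after every iteration; non-increasing.
    """

    def __init__(
        self,
        epsilon: float = 1e-5,
        max_iter: int = 100,
        y0: np.ndarray | str | None = "zero",
        weights: np.ndarray | None = None,
    ) -> None:
        self.epsilon = epsilon
        self.max_iter = max_iter
        self.y0 = y0
        self.weights = weights

    def fit(self, X: np.ndarray, y: None = None) -> "GeometricMedian":
        points = WeightedPointSet(np.asarray(X, dtype=float), self.weights)
        res = geometric_median(
            points, epsilon=self.epsilon, max_iter=self.max_iter, y0=self.y0
        )
        self.median_ = res.y
        self.objective_ = res.objective
        self.n_iter_ = res.iterations
        self.converged_ = res.converged
        self.objective_trace_ = res.objective_trace
        return self
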