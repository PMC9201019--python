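"""Cluster validity indices and the optimal-cluster-count sweep.

Three indices are provided:

* **TSS** (Tang-Sun-Sun; smaller is better): fuzzy compactness over minimum
  center separation, plus a punishing mean-pairwise-separation term that
  keeps the index from decaying monotonically to zero as c approaches n —
  the defect that biases the Xie-Beni index toward c = n - 1::

      TSS = [ sum_i sum_k u_ik^2 ||z_k - v_i||^2
              + (1/(c(c-1))) sum_{i != j} ||v_i - v_j||^2 ]
            / [ min_{i != j} ||v_i - v_j||^2 + 1/c ]

  The membership exponent is 2 by definition, regardless of the fuzzifier
  used when fitting.

* **silhouette** (larger is better): crisp per-point contrast
  (b - a)/max(a, b) between the mean within-cluster distance and the
  smallest mean distance to another cluster; singleton clusters score 0.

* **Xie-Beni** (optional comparator; smaller is better): compactness over
  n times the minimum center separation — included to demonstrate its
  monotone decay for large c.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist, pdist, squareform

from .errors import DomainError
from .fcm import fit_fcm

__all__ = [
    "ValidityCurve",
    "SilhouetteBreakdown",
    "tss_index",
    "tss_limit_form",
    "crisp_assign",
    "silhouette_index",
    "xie_beni_index",
    "sweep_validity",
]

INDEX_RULES = {"tss": "argmin", "silhouette": "argmax", "xie_beni": "argmin"}


@dataclass
class ValidityCurve:
    """Index value per swept cluster count, with the index's optimality rule."""

    index_name: str
    values: dict[int, float]
    rule: str

    @property
    def optimal_c(self) -> int:
        """Extremal c per the rule; NaNs excluded; ties go to the smaller c."""
        finite = {c: v for c, v in sorted(self.values.items()) if np.isfinite(v)}
        if not finite:
            raise DomainError(f"no finite {self.index_name} values in the sweep")
        pick = min if self.rule == "argmin" else max
        best_val = pick(finite.values())
        return next(c for c, v in finite.items() if v == best_val)


@dataclass
class SilhouetteBreakdown:
    a: np.ndarray
    b: np.ndarray
    s: np.ndarray
    labels: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))


def _center_separations(V: np.ndarray) -> tuple[float, float]:
    """(min squared separation, sum over ordered pairs of squared separation)."""
    seps = pdist(V) ** 2
    return float(seps.min()), float(2.0 * seps.sum())


def tss_index(Z: np.ndarray, U: np.ndarray, V: np.ndarray) -> float:
    """Tang-Sun-Sun validity index (argmin rule)."""
    Z, U, V = np.asarray(Z, float), np.asarray(U, float), np.asarray(V, float)
    c = V.shape[0]
    if c < 2:
        raise DomainError("TSS requires c >= 2")
    D2 = cdist(V, Z, "sqeuclidean")
    compact = float(np.sum(U**2 * D2))
    min_sep, pair_sum = _center_separations(V)
    denom = min_sep + 1.0 / c
    return compact / denom + (pair_sum / (c * (c - 1))) / denom


def tss_limit_form(Z: np.ndarray) -> float:
    """Closed-form c -> n limit of TSS (crisp U = I, V = Z).

    Equals ``sum_{i != j} ||z_i - z_j||^2 / (n(n-1) min_{i != j} ||z_i - z_j||^2
    + (n-1))``; requires all points distinct.
    """
    Z = np.atleast_2d(np.asarray(Z, float))
    n = Z.shape[0]
    if n < 2:
        raise DomainError("need at least 2 points")
    d2 = pdist(Z) ** 2
    min_sep = float(d2.min())
    if min_sep < 1e-24:
        raise DomainError("duplicate points: the c = n limit is undefined")
    total = float(2.0 * d2.sum())
    return total / (n * (n - 1) * min_sep + (n - 1))


def crisp_assign(U: np.ndarray) -> np.ndarray:
    """Crisp labels by maximal membership; ties to the smallest cluster index."""
    return np.argmax(np.asarray(U, float), axis=0)


def silhouette_index(
    Z: np.ndarray, labels: np.ndarray
) -> tuple[float, SilhouetteBreakdown]:
    """Mean crisp silhouette plus the per-point breakdown.

    a_k is the mean distance to the other members of the point's own cluster
    (self excluded); b_k the smallest mean distance to another cluster;
    s_k = (b_k - a_k)/max(a_k, b_k).  Points in singleton clusters get s = 0.
    """
    Z = np.atleast_2d(np.asarray(Z, float))
    labels = np.asarray(labels)
    present = np.unique(labels)
    if len(present) < 2:
        raise DomainError("silhouette needs at least 2 non-empty clusters")
    D = squareform(pdist(Z))
    n = Z.shape[0]
    a = np.zeros(n)
    b = np.zeros(n)
    s = np.zeros(n)
    for k in range(n):
        own = np.flatnonzero((labels == labels[k]) & (np.arange(n) != k))
        others = [
            D[k, labels == lab].mean() for lab in present if lab != labels[k]
        ]
        b[k] = min(others)
        if len(own) == 0:  # singleton cluster: s = 0 by convention
            a[k] = 0.0
            s[k] = 0.0
            continue
        a[k] = D[k, own].mean()
        s[k] = (b[k] - a[k]) / max(a[k], b[k])
    return float(s.mean()), SilhouetteBreakdown(a, b, s, labels.copy())


def xie_beni_index(Z: np.ndarray, U: np.ndarray, V: np.ndarray) -> float:
    """Xie-Beni index (argmin rule); errors on coincident centers."""
    Z, U, V = np.asarray(Z, float), np.asarray(U, float), np.asarray(V, float)
    if V.shape[0] < 2:
        raise DomainError("Xie-Beni requires c >= 2")
    min_sep, _ = _center_separations(V)
    if min_sep < 1e-24:
        raise DomainError("coincident cluster centers: Xie-Beni undefined")
    D2 = cdist(V, Z, "sqeuclidean")
    compact = float(np.sum(U**2 * D2))
    return compact / (Z.shape[0] * min_sep)


def _child_seed(seed: int | None, c: int) -> int:
    ss = np.random.SeedSequence(0 if seed is None else seed, spawn_key=(c,))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def sweep_validity(
    Z: np.ndarray,
    c_min: int = 2,
    c_max: int | None = None,
    indices: tuple[str, ...] = ("tss", "silhouette"),
    m: float = 2.0,
    epsilon: float = 1e-5,
    max_iter: int = 100,
    restarts: int = 10,
    seed: int | None = None,
    return_models: bool = False,
):
    """Fit FCM for each c in [c_min, c_max] and evaluate the requested indices.

    Each c gets an independently derived child seed.  If the crisp partition
    at some c leaves fewer than two non-empty clusters, the silhouette is
    recorded as NaN and excluded from the argmax.  Returns a list of
    :class:`ValidityCurve` (and the fitted models when ``return_models``).
    """
    Z = np.atleast_2d(np.asarray(Z, float))
    n = Z.shape[0]
    if c_max is None:
        c_max = n - 1
    if not 2 <= c_min <= c_max <= n - 1:
        raise DomainError(f"need 2 <= c_min <= c_max <= n-1 (n={n})")
    for name in indices:
        if name not in INDEX_RULES:
            raise DomainError(f"unknown validity index {name!r}")
    values: dict[str, dict[int, float]] = {name: {} for name in indices}
    models = {}
    for c in range(c_min, c_max + 1):
        model = fit_fcm(
            Z, c, m=m, epsilon=epsilon, max_iter=max_iter,
            seed=_child_seed(seed, c), restarts=restarts,
        )
        models[c] = model
        for name in indices:
            if name == "tss":
                values[name][c] = tss_index(Z, model.U, model.V)
            elif name == "xie_beni":
                values[name][c] = xie_beni_index(Z, model.U, model.V)
            else:
                labels = crisp_assign(model.U)
                if len(np.unique(labels)) < 2:
                    values[name][c] = float("nan")
                else:
                    values[name][c] = silhouette_index(Z, labels)[0]
    curves = [
        ValidityCurve(name, values[name], INDEX_RULES[name]) for name in indices
    ]
    if return_models:
        return curves, models
    return curves
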