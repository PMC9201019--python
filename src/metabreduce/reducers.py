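"""Reduce a region's d x n_rep replicate block to a single length-d vector.

The geometric-median reducer (``mwa``) aggregates the n_rep replicate
vectors in metabolite space R^d.  The spectral comparators (``pca``,
``cmds``, ``le``, ``lle``) instead view the d metabolites as points in
replicate space R^{n_rep} and embed them into one dimension, which also
yields a length-d representative.  ``median`` and ``mean`` reduce each
metabolite row independently.

Eigenvector sign is fixed by requiring non-negative correlation with the
metabolite-wise mean across replicates, so all reducers are deterministic.
"""

from __future__ import annotations

import warnings

import numpy as np
import scipy.linalg
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import squareform, pdist
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import DisconnectedGraphError, DomainError
from .geomedian import reduce_region_mwa
from .io import MetaboliteTable, ReducedDataset, RegionBlock, split_regions

__all__ = [
    "reduce_region_pca",
    "reduce_region_cmds",
    "reduce_region_le",
    "reduce_region_lle",
    "reduce_region_median",
    "reduce_region_mean",
    "reduce_dataset",
    "ReplicateReducer",
]


def _sign_fix(vec: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Flip ``vec`` so its inner product with the centered reference is >= 0."""
    ref = reference - reference.mean()
    dot = float(vec @ ref)
    if dot < 0:
        return -vec
    if dot == 0:
        nz = np.nonzero(vec)[0]
        if len(nz) and vec[nz[0]] < 0:
            return -vec
    return vec


def _degenerate_block(block: RegionBlock) -> np.ndarray | None:
    """Common column if all replicate columns are identical, else None."""
    if np.allclose(block.values, block.values[:, [0]], atol=0, rtol=0):
        return block.values[:, 0].copy()
    return None


def reduce_region_pca(block: RegionBlock) -> np.ndarray:
    """First principal-component scores of the metabolite points.

    Metabolites are points in replicate space; each replicate coordinate is
    centered over the metabolites, and the scores along the first right
    singular vector are returned (length d), sign-fixed.
    """
    common = _degenerate_block(block)
    if common is not None:
        warnings.warn("zero-variance block: returning the common column")
        return common
    if block.n_replicates < 2:
        raise DomainError("PCA reduction needs at least 2 replicates")
    P = block.values  # d points x n_rep features
    Pc = P - P.mean(axis=0)
    _, s, Vt = np.linalg.svd(Pc, full_matrices=False)
    scores = Pc @ Vt[0]
    return _sign_fix(scores, P.mean(axis=1))


def reduce_region_cmds(block: RegionBlock) -> np.ndarray:
    """Classical MDS 1-D coordinates of the metabolite points.

    Double-centers the squared Euclidean distance matrix, B = -0.5 J D^2 J,
    and returns sqrt(lambda_1) times the top eigenvector.  For Euclidean
    distances this equals the centered first-PC scores up to sign.
    """
    common = _degenerate_block(block)
    if common is not None:
        warnings.warn("zero-variance block: returning the common column")
        return common
    P = block.values
    d = P.shape[0]
    D2 = squareform(pdist(P)) ** 2
    J = np.eye(d) - np.ones((d, d)) / d
    B = -0.5 * J @ D2 @ J
    evals, evecs = np.linalg.eigh((B + B.T) / 2)
    lam, vec = evals[-1], evecs[:, -1]
    if lam <= 0:
        raise DomainError("no positive eigenvalue in CMDS; degenerate geometry")
    coord = np.sqrt(lam) * vec
    return _sign_fix(coord, P.mean(axis=1))


def _knn_graph(P: np.ndarray, n_neighbors: int) -> np.ndarray:
    """Union-symmetrized kNN adjacency (0/1) over the rows of P."""
    d = P.shape[0]
    if not 1 <= n_neighbors < d:
        raise DomainError(
            f"n_neighbors must be in [1, {d - 1}] for {d} points"
        )
    D = squareform(pdist(P))
    A = np.zeros((d, d))
    order = np.argsort(D, axis=1)
    for i in range(d):
        nbrs = [j for j in order[i] if j != i][:n_neighbors]
        A[i, nbrs] = 1.0
    return np.maximum(A, A.T)


def reduce_region_le(
    block: RegionBlock,
    n_neighbors: int = 5,
    weighting: str = "binary",
    heat_sigma: float = 1.0,
) -> np.ndarray:
    """Laplacian-eigenmaps 1-D coordinates of the metabolite points.

    Builds a union-symmetrized kNN graph with binary or heat-kernel weights
    exp(-d^2 / (2 sigma^2)), solves the generalized eigenproblem
    L f = lambda D f, and returns the eigenvector of the smallest non-zero
    eigenvalue, sign-fixed.
    """
    P = block.values
    A = _knn_graph(P, n_neighbors)
    n_comp, _ = connected_components(A, directed=False)
    if n_comp > 1:
        raise DisconnectedGraphError(
            f"kNN graph has {n_comp} components; increase n_neighbors"
        )
    if weighting == "heat":
        D2 = squareform(pdist(P)) ** 2
        W = A * np.exp(-D2 / (2.0 * heat_sigma**2))
    elif weighting == "binary":
        W = A
    else:
        raise DomainError(f"unknown LE weighting {weighting!r}")
    deg = W.sum(axis=1)
    Dm = np.diag(deg)
    L = Dm - W
    evals, evecs = scipy.linalg.eigh(L, Dm)
    # connected graph: exactly one ~zero eigenvalue; take the next one
    vec = evecs[:, 1]
    return _sign_fix(vec, P.mean(axis=1))


def _lle_weights(P: np.ndarray, n_neighbors: int, reg: float = 1e-3) -> np.ndarray:
    d = P.shape[0]
    D = squareform(pdist(P))
    order = np.argsort(D, axis=1)
    W = np.zeros((d, d))
    for i in range(d):
        nbrs = [j for j in order[i] if j != i][:n_neighbors]
        Zi = P[nbrs] - P[i]
        G = Zi @ Zi.T
        trace = np.trace(G)
        G = G + reg * (trace if trace > 0 else 1.0) * np.eye(len(nbrs))
        w = np.linalg.solve(G, np.ones(len(nbrs)))
        W[i, nbrs] = w / w.sum()
    return W


def reduce_region_lle(block: RegionBlock, n_neighbors: int = 5) -> np.ndarray:
    """Locally-linear-embedding 1-D coordinates of the metabolite points.

    Per-point reconstruction weights solve the local Gram system
    (regularized by 1e-3 * trace) with rows summing to 1; the embedding is
    the eigenvector of the second-smallest eigenvalue of
    M = (I - W)^T (I - W), sign-fixed.
    """
    if n_neighbors < 2:
        raise DomainError("LLE needs n_neighbors >= 2")
    P = block.values
    A = _knn_graph(P, n_neighbors)
    n_comp, _ = connected_components(A, directed=False)
    if n_comp > 1:
        raise DisconnectedGraphError(
            f"kNN graph has {n_comp} components; increase n_neighbors"
        )
    W = _lle_weights(P, n_neighbors)
    d = P.shape[0]
    IW = np.eye(d) - W
    M = IW.T @ IW
    evals, evecs = np.linalg.eigh((M + M.T) / 2)
    vec = evecs[:, 1]
    return _sign_fix(vec, P.mean(axis=1))


def reduce_region_median(block: RegionBlock) -> np.ndarray:
    """Per-metabolite (row-wise) median across replicates."""
    return np.median(block.values, axis=1)


def reduce_region_mean(block: RegionBlock) -> np.ndarray:
    """Per-metabolite (row-wise) arithmetic mean across replicates."""
    return block.values.mean(axis=1)


_REDUCERS = {
    "mwa": reduce_region_mwa,
    "pca": reduce_region_pca,
    "cmds": reduce_region_cmds,
    "le": reduce_region_le,
    "lle": reduce_region_lle,
    "median": reduce_region_median,
    "mean": reduce_region_mean,
}


def reduce_region(block: RegionBlock, method: str, **settings) -> np.ndarray:
    """Dispatch to one of the region reducers by tag."""
    try:
        fn = _REDUCERS[method]
    except KeyError:
        raise DomainError(
            f"unknown reduction method {method!r}; choose from {sorted(_REDUCERS)}"
        ) from None
    return fn(block, **settings)


def reduce_dataset(
    table: MetaboliteTable, method: str, **settings
) -> ReducedDataset:
    """Apply one reducer to every region block of a (log-scale) table.

    Returns one representative row per region, ordered by region label.
    """
    if table.scale != "log":
        raise DomainError("reduce_dataset expects a preprocessed (log-scale) table")
    blocks = split_regions(table)
    rows, regions, origins = [], [], []
    for block in blocks:
        rows.append(reduce_region(block, method, **settings))
        regions.append(block.region)
        origins.append(block.origin)
    return ReducedDataset(
        Z=np.vstack(rows),
        region_labels=regions,
        origin_labels=origins,
        method=method,
        metabolite_ids=list(table.metabolite_ids),
    )


class ReplicateReducer(BaseEstimator, TransformerMixin):
    """Reduce every region of a metabolite table to one representative row.

    Parameters mirror the per-method settings: ``epsilon``/``max_iter``/``y0``
    apply to the geometric-median reducer, ``n_neighbors``/``le_weighting``/
    ``heat_sigma`` to the spectral embeddings.  Stateless: ``fit`` validates
    only, ``transform`` returns a :class:`ReducedDataset`.
    """

    def __init__(
        self,
        method: str = "mwa",
        epsilon: float = 1e-5,
        max_iter: int = 100,
        y0="zero",
        n_neighbors: int = 5,
        le_weighting: str = "binary",
        heat_sigma: float = 1.0,
    ) -> None:
        self.method = method
        self.epsilon = epsilon
        self.max_iter = max_iter
        self.y0 = y0
        self.n_neighbors = n_neighbors
        self.le_weighting = le_weighting
        self.heat_sigma = heat_sigma

    def _settings(self) -> dict:
        if self.method == "mwa":
            return dict(epsilon=self.epsilon, max_iter=self.max_iter, y0=self.y0)
        if self.method == "le":
            return dict(
                n_neighbors=self.n_neighbors,
                weighting=self.le_weighting,
                heat_sigma=self.heat_sigma,
            )
        if self.method == "lle":
            return dict(n_neighbors=self.n_neighbors)
        return {}

    def fit(self, X: MetaboliteTable, y: None = None) -> "ReplicateReducer":
        if self.method not in _REDUCERS:
            raise DomainError(f"unknown reduction method {self.method!r}")
        return self

    def transform(self, X: MetaboliteTable) -> ReducedDataset:
        self.fit(X)
        return reduce_dataset(X, self.method, **self._settings())
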