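"""Per-species preprocessing and manifold construction.

Builds, for each species independently, a feature-weighted PCA representation
and a directed k-nearest-neighbor graph of the cells. Gene weights follow a
self-assembling-manifold style iteration: genes whose kNN-averaged expression
is highly dispersed on the current cell graph (i.e. spatially structured on
the manifold) are up-weighted, the weighted PCA and the kNN graph are rebuilt,
and the loop repeats until the weights stop changing. The manifold's PCA
loadings over *all* genes (top 300 components) are what downstream alignment
uses to project a partner species into this species' expression space.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from sklearn.decomposition import PCA

__all__ = [
    "ExpressionAtlas",
    "AtlasManifold",
    "StandardizedExpression",
    "preprocess_atlas",
    "build_manifold",
    "standardize_and_mask",
]

N_FINAL_PCS = 300  # rows of the all-gene loading matrix


@dataclass
class ExpressionAtlas:
    """A single-species expression matrix with identifiers.

    ``counts`` is cells x genes, nonnegative. After :func:`preprocess_atlas`
    the matrix holds library-normalized ``log2(x+1)`` values instead of raw
    counts.
    """

    counts: sp.csr_matrix | np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    cell_types: list[str] | None = None

    def __post_init__(self) -> None:
        n, m = self.counts.shape
        if len(self.gene_ids) != m:
            raise ValueError(f"{len(self.gene_ids)} gene ids for {m} columns")
        if len(self.cell_ids) != n:
            raise ValueError(f"{len(self.cell_ids)} cell ids for {n} rows")
        if len(set(self.gene_ids)) != m or len(set(self.cell_ids)) != n:
            raise ValueError("duplicate gene or cell identifiers")
        if self.cell_types is not None and len(self.cell_types) != n:
            raise ValueError("cell_types length mismatch")

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def dense(self) -> np.ndarray:
        X = self.counts
        return X.toarray() if sp.issparse(X) else np.asarray(X, dtype=float)


@dataclass
class AtlasManifold:
    """Output of the per-species manifold construction.

    Attributes
    ----------
    lognorm
        Cells x genes log-normalized expression (dense).
    knn_graph
        Directed binary kNN adjacency, k outgoing edges per cell (self
        excluded; ``min(k, n-1)`` if the dataset is small).
    gene_weights
        Per-gene structure weights in [0, 1].
    loadings
        ``300 x m`` PCA loading matrix over all genes (gene weights folded
        in, so projecting standardized expression with ``Z @ loadings.T``
        reproduces the weighted PC scores). Zero-padded if the data support
        fewer than 300 components.
    pc_scores
        Cell scores in the working PC space of the final weight iteration.
    """

    lognorm: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    knn_graph: sp.csr_matrix
    gene_weights: np.ndarray
    loadings: np.ndarray
    pc_scores: np.ndarray
    cell_types: list[str] | None = None
    k: int = 20


@dataclass
class StandardizedExpression:
    """Per-gene standardized expression with non-homology genes zeroed."""

    values: np.ndarray
    gene_ids: list[str]
    zeroed: np.ndarray  # boolean mask of zeroed gene columns


def preprocess_atlas(
    atlas: ExpressionAtlas,
    max_expressing_fraction: float = 0.96,
    expressed_threshold: float = 1.0,
) -> ExpressionAtlas:
    """Library-size normalize, log-transform, and drop ubiquitous genes.

    Cells are rescaled so every library totals the median raw library size;
    expression becomes ``log2(x+1)``. Genes "expressed" (log value strictly
    above ``expressed_threshold``) in strictly more than
    ``max_expressing_fraction`` of cells are removed. Cells with zero total
    counts are dropped with a warning.
    """
    X = atlas.dense()
    if np.any(X < 0) or not np.all(np.isfinite(X)):
        raise ValueError("counts must be finite and nonnegative")
    totals = X.sum(axis=1)
    keep_cells = totals > 0
    if not np.all(keep_cells):
        warnings.warn(
            f"dropping {int((~keep_cells).sum())} cells with zero counts",
            stacklevel=2,
        )
        X = X[keep_cells]
        totals = totals[keep_cells]
    if X.shape[0] == 0:
        raise ValueError("no cells with nonzero counts")
    median_size = float(np.median(totals))
    X = X * (median_size / totals)[:, None]
    X = np.log2(X + 1.0)
    expressing = (X > expressed_threshold).mean(axis=0)
    keep_genes = expressing <= max_expressing_fraction
    X = X[:, keep_genes]
    cell_ids = [c for c, k in zip(atlas.cell_ids, keep_cells) if k]
    cell_types = (
        [t for t, k in zip(atlas.cell_types, keep_cells) if k]
        if atlas.cell_types is not None
        else None
    )
    gene_ids = [g for g, k in zip(atlas.gene_ids, keep_genes) if k]
    return ExpressionAtlas(X, gene_ids, cell_ids, cell_types)


def _standardize(X: np.ndarray) -> np.ndarray:
    """Column z-scores; zero-variance columns become all-zero."""
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    out = X - mu
    nz = sd > 0
    out[:, nz] /= sd[nz]
    out[:, ~nz] = 0.0
    return out


def _knn_correlation(scores: np.ndarray, k: int) -> sp.csr_matrix:
    """Exact directed kNN under correlation distance, self excluded.

    Zero-variance score rows get zero similarity to everything, so their
    neighbors are arbitrary (stable smallest-index ties) rather than an error.
    """
    n = scores.shape[0]
    C = scores - scores.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(C, axis=1)
    nz = norms > 0
    C[nz] /= norms[nz, None]
    C[~nz] = 0.0
    sim = C @ C.T
    np.fill_diagonal(sim, -np.inf)
    k_eff = min(k, n - 1)
    order = np.argsort(-sim, axis=1, kind="stable")[:, :k_eff]
    rows = np.repeat(np.arange(n), k_eff)
    return sp.csr_matrix(
        (np.ones(n * k_eff), (rows, order.ravel())), shape=(n, n)
    )


def _row_normalize(M: sp.spmatrix) -> sp.csr_matrix:
    """L1 row normalization; empty rows stay empty."""
    M = M.tocsr().astype(float)
    s = np.asarray(np.abs(M).sum(axis=1)).ravel()
    inv = np.zeros_like(s)
    nz = s > 0
    inv[nz] = 1.0 / s[nz]
    return sp.diags(inv) @ M


def build_manifold(
    atlas: ExpressionAtlas,
    k: int = 20,
    npcs: int = 150,
    n_top_genes: int = 3000,
    seed: int = 0,
    tol: float = 1e-2,
    max_iter: int = 10,
    uniform_weights: bool = False,
) -> AtlasManifold:
    """Iterative feature-weighted manifold construction for one atlas.

    Repeats {standardize genes; apply gene weights; PCA on the top
    ``n_top_genes`` by weight; directed kNN (correlation distance) in PC
    space; recompute weights as the max-normalized dispersion of kNN-averaged
    expression} until the RMS change of the weight vector drops below ``tol``
    or ``max_iter`` iterations. A final PCA over *all* genes yields the
    300-row loading matrix.

    With ``uniform_weights=True`` the weight iteration is skipped and the
    result is a single plain PCA + kNN pass (useful as a baseline).
    """
    n, m = atlas.counts.shape
    if n <= k:
        raise ValueError(
            f"dataset has {n} cells but k={k}; choose k < n_cells"
        )
    X = atlas.dense()
    Xs = _standardize(X)
    npcs_eff = min(npcs, n - 1, m)
    w = np.ones(m)
    knn = None
    scores = None
    for _ in range(max_iter):
        top = np.argsort(-w, kind="stable")[: min(n_top_genes, m)]
        pca = PCA(n_components=npcs_eff, random_state=seed)
        scores = pca.fit_transform(Xs[:, top] * w[top])
        knn = _knn_correlation(scores, k)
        if uniform_weights:
            break
        smoothed = _row_normalize(knn) @ X
        disp = smoothed.var(axis=0)
        mx = disp.max()
        new_w = disp / mx if mx > 0 else np.ones(m)
        rms = float(np.sqrt(np.mean((new_w - w) ** 2)))
        w = new_w
        if rms < tol:
            top = np.argsort(-w, kind="stable")[: min(n_top_genes, m)]
            pca = PCA(n_components=npcs_eff, random_state=seed)
            scores = pca.fit_transform(Xs[:, top] * w[top])
            knn = _knn_correlation(scores, k)
            break
    # all-gene loadings for cross-species projection
    n_load = min(N_FINAL_PCS, n - 1, m)
    pca_all = PCA(n_components=n_load, random_state=seed)
    pca_all.fit(Xs * w)
    loadings = np.zeros((N_FINAL_PCS, m))
    loadings[:n_load] = pca_all.components_ * w[None, :]
    return AtlasManifold(
        lognorm=X,
        gene_ids=list(atlas.gene_ids),
        cell_ids=list(atlas.cell_ids),
        knn_graph=knn,
        gene_weights=w,
        loadings=loadings,
        pc_scores=scores,
        cell_types=list(atlas.cell_types) if atlas.cell_types is not None else None,
        k=k,
    )


def standardize_and_mask(
    manifold: AtlasManifold, homology, side: int
) -> StandardizedExpression:
    """Standardize expression and zero genes without a homology edge.

    ``side`` selects which species of the homology graph this manifold is
    (1 or 2). Genes absent from the graph's *current* weight support are
    zeroed; remaining genes get zero mean and unit variance; zero-variance
    genes become all-zero rather than NaN.
    """
    if side not in (1, 2):
        raise ValueError("side must be 1 or 2")
    if homology.weights_12 is None or homology.weights_21 is None:
        raise ValueError("homology graph has no weights; run filter_and_normalize")
    if side == 1:
        W = homology.weights_12
        ids = homology.gene_ids_1
        deg = np.asarray((W > 0).sum(axis=1)).ravel()
        deg = deg + np.asarray((homology.weights_21 > 0).sum(axis=0)).ravel()
    else:
        W = homology.weights_21
        ids = homology.gene_ids_2
        deg = np.asarray((W > 0).sum(axis=1)).ravel()
        deg = deg + np.asarray((homology.weights_12 > 0).sum(axis=0)).ravel()
    with_edge = {g for g, d in zip(ids, deg) if d > 0}
    mask = np.array([g not in with_edge for g in manifold.gene_ids])
    Z = _standardize(manifold.lognorm)
    Z[:, mask] = 0.0
    return StandardizedExpression(Z, list(manifold.gene_ids), mask)
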