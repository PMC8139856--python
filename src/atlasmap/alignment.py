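"""One round of cross-species manifold alignment.

The two species' standardized expression matrices are translated into each
other's gene spaces through the homology graph, projected into a joint
600-dimensional PC space, and linked by cross-species k-nearest neighbors.
Raw kNN edges are then coarsened against each cell's local within-species
neighborhood: instead of requiring two individual cells to pick each other
(fragile under kNN stochasticity), an edge measures the fraction of a cell's
outgoing cross-species edge mass that lands inside the *neighborhood* of a
partner cell. The element-wise geometric mean of the two directions keeps
only reciprocally supported neighborhood links, from which the final top-k
cross-species edges per cell are selected and stitched with the two
within-species graphs into one combined cell graph.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .atlas_manifold import _row_normalize

__all__ = [
    "CrossNeighbors",
    "NeighborhoodStructure",
    "CombinedGraph",
    "translate_features",
    "joint_projection",
    "cross_species_knn",
    "hops_for_size",
    "expand_neighborhoods",
    "coarsen_edges",
    "mutual_neighborhoods",
    "select_knn_neighborhoods",
    "stitch_manifolds",
    "overall_alignment_score",
]


@dataclass
class CrossNeighbors:
    """Directed cross-species cell biadjacency matrices.

    ``C_1`` is ``n1 x n2`` (species 1 -> 2), ``C_2`` is ``n2 x n1``.
    """

    C_1: sp.csr_matrix
    C_2: sp.csr_matrix
    k: int


@dataclass
class NeighborhoodStructure:
    """Within-species neighborhoods from hop expansion of the kNN graph.

    ``expanded`` counts directed paths of length <= ``hops``; ``pruned``
    keeps, per cell, only its ``cluster_sizes[a]`` geodesically closest
    cells (ascending hop count, ties broken by descending path count then
    ascending index), where the per-cell neighborhood size is the size of
    the cell's community at the configured clustering resolution.
    """

    hops: int
    expanded: sp.csr_matrix
    pruned: sp.csr_matrix
    cluster_sizes: np.ndarray
    clusters: np.ndarray


@dataclass
class CombinedGraph:
    """Stitched cross-species cell graph in block form [[N1~, C1], [C2, N2~]]."""

    matrix: sp.csr_matrix
    n1: int
    n2: int
    within_floor: float = 0.3

    def blocks(self) -> tuple[sp.csr_matrix, sp.csr_matrix, sp.csr_matrix, sp.csr_matrix]:
        n1, n2 = self.n1, self.n2
        M = self.matrix.tocsr()
        return (
            M[:n1, :n1],
            M[:n1, n1:],
            M[n1:, :n1],
            M[n1:, n1:],
        )

    def write_mtx(self, path) -> None:
        from scipy.io import mmwrite

        mmwrite(path, self.matrix)


def translate_features(values: np.ndarray, H: sp.spmatrix) -> np.ndarray:
    """Impute partner-species gene expression through the homology graph.

    ``H`` (``m_i x m_j``) is normalized over its homolog (row) axis per
    partner gene — each column sums to one — so each partner gene's column
    in the output is the weight-averaged expression of its homologs. Genes
    with no homolog yield zero columns.
    """
    if values.shape[1] != H.shape[0]:
        raise ValueError(
            f"expression has {values.shape[1]} genes but homology rows are {H.shape[0]}"
        )
    Hn = _row_normalize(H.T).T
    return np.asarray(values @ Hn)


def joint_projection(
    Zt_i: np.ndarray, Zt_ij: np.ndarray, L_i: np.ndarray, L_j: np.ndarray
) -> np.ndarray:
    """Concatenate within- and cross-species PC projections (n_i x 600)."""
    if L_i.shape[0] != L_j.shape[0]:
        raise ValueError("loading matrices disagree on component count")
    P_i = Zt_i @ L_i.T
    P_ij = Zt_ij @ L_j.T
    return np.hstack([P_i, P_ij])


def _rowwise_topk_dense(S: np.ndarray, k: int) -> sp.csr_matrix:
    """Keep the k largest positive entries per row (ties -> smaller column)."""
    n, m = S.shape
    k_eff = min(k, m)
    order = np.argsort(-S, axis=1, kind="stable")[:, :k_eff]
    rows = np.repeat(np.arange(n), k_eff)
    cols = order.ravel()
    vals = S[rows, cols]
    keep = vals > 0
    return sp.csr_matrix((vals[keep], (rows[keep], cols[keep])), shape=(n, m))


def cross_species_knn(P1: np.ndarray, P2: np.ndarray, k: int = 20) -> CrossNeighbors:
    """Exact cross-species kNN by cosine similarity in the joint space.

    Negative similarities are clipped to zero. If the partner dataset has
    fewer than k cells, all of them are kept with a warning.
    """
    if P1.shape[1] != P2.shape[1]:
        raise ValueError("projections live in different spaces")
    n1, n2 = P1.shape[0], P2.shape[0]
    if min(n1, n2) < k:
        warnings.warn(
            f"partner dataset smaller than k={k}; keeping all neighbors",
            stacklevel=2,
        )

    def _unit(X):
        norms = np.linalg.norm(X, axis=1)
        out = X.astype(float).copy()
        nz = norms > 0
        out[nz] /= norms[nz, None]
        out[~nz] = 0.0
        return out

    S = _unit(P1) @ _unit(P2).T
    np.clip(S, 0.0, None, out=S)
    return CrossNeighbors(
        C_1=_rowwise_topk_dense(S, k),
        C_2=_rowwise_topk_dense(S.T, k),
        k=k,
    )


def hops_for_size(n_cells: int) -> int:
    """Neighborhood expansion depth: 2 below 20,000 cells, 3 otherwise."""
    return 2 if n_cells < 20_000 else 3


def expand_neighborhoods(
    N: sp.spmatrix,
    resolution: float = 3.0,
    seed: int = 0,
    hops: int | None = None,
) -> NeighborhoodStructure:
    """Expand each cell's kNN edges into a local multi-hop neighborhood.

    The binarized kNN graph is raised to powers 1..t (t from
    :func:`hops_for_size` unless given), summing directed path counts within
    t hops. Leiden communities at the given resolution bound each cell's
    neighborhood size: row a keeps only its ``|community(a)|`` geodesically
    closest cells.
    """
    N = N.tocsr()
    n = N.shape[0]
    t = hops if hops is not None else hops_for_size(n)
    B = (N > 0).astype(float).tocsr()
    # path counts within <= t hops and per-entry minimum hop count
    acc = B.copy()
    hop = B.tocoo()
    hopmat = sp.csr_matrix(
        (np.ones(hop.nnz), (hop.row, hop.col)), shape=B.shape
    )
    power = B
    for h in range(2, t + 1):
        power = power @ B
        acc = acc + power
        newly = ((power > 0).astype(float) - (hopmat > 0).astype(float)) > 0
        hopmat = hopmat + sp.csr_matrix(newly) * h
    acc = acc.tocsr()

    clusters = _leiden_clusters(B, resolution=resolution, seed=seed)
    sizes = np.bincount(clusters, minlength=clusters.max() + 1)
    l_a = sizes[clusters]

    pruned = _prune_to_closest(acc, hopmat.tocsr(), l_a)
    return NeighborhoodStructure(
        hops=t,
        expanded=acc,
        pruned=pruned,
        cluster_sizes=l_a,
        clusters=clusters,
    )


def _leiden_clusters(B: sp.csr_matrix, resolution: float, seed: int) -> np.ndarray:
    import igraph
    import leidenalg

    coo = B.tocoo()
    g = igraph.Graph(
        n=B.shape[0],
        edges=list(zip(coo.row.tolist(), coo.col.tolist())),
        directed=True,
    )
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution,
        seed=int(seed),
    )
    return np.asarray(part.membership)


def _prune_to_closest(
    acc: sp.csr_matrix, hopmat: sp.csr_matrix, l_a: np.ndarray
) -> sp.csr_matrix:
    """Per row keep the l_a geodesically closest cells.

    Order: ascending hop count, ties by descending path count, then
    ascending cell index (deterministic).
    """
    n = acc.shape[0]
    indptr = [0]
    indices: list[int] = []
    data: list[float] = []
    for a in range(n):
        start, end = acc.indptr[a], acc.indptr[a + 1]
        cols = acc.indices[start:end]
        counts = acc.data[start:end]
        hs, he = hopmat.indptr[a], hopmat.indptr[a + 1]
        # hopmat has identical sparsity pattern ordering as acc rows may differ;
        # build a lookup for safety
        hop_lookup = dict(zip(hopmat.indices[hs:he], hopmat.data[hs:he]))
        hops = np.array([hop_lookup[c] for c in cols])
        order = np.lexsort((cols, -counts, hops))[: l_a[a]]
        order = np.sort(order)
        indices.extend(cols[order].tolist())
        data.extend(counts[order].tolist())
        indptr.append(len(indices))
    return sp.csr_matrix((data, indices, indptr), shape=acc.shape)


def coarsen_edges(
    C: sp.spmatrix, nbhd_target: NeighborhoodStructure, prune: float = 0.1
) -> sp.csr_matrix:
    """Replace cell-to-cell cross edges by cell-to-neighborhood fractions.

    Rows of ``C`` are L1-normalized so the coarsened weight
    ``C~(a, b) = sum_{c in X_b} C_norm(a, c)`` is the fraction of a's
    outgoing cross-species edge mass landing in the neighborhood ``X_b`` of
    partner cell b. Entries strictly below ``prune`` are removed.
    """
    Cn = _row_normalize(C)
    M = (nbhd_target.pruned > 0).astype(float)
    out = (Cn @ M.T).tocsr()
    out.data[out.data < prune] = 0.0
    out.eliminate_zeros()
    return out


def mutual_neighborhoods(Ct_1: sp.spmatrix, Ct_2: sp.spmatrix) -> sp.csr_matrix:
    """Element-wise geometric mean of the two coarsened directions.

    Only bidirectional neighborhood links survive: a zero in either
    direction zeroes the product.
    """
    prod = Ct_1.multiply(Ct_2.T).tocsr()
    prod.data = np.sqrt(prod.data)
    prod.eliminate_zeros()
    return prod


def select_knn_neighborhoods(Ct: sp.spmatrix, k: int = 20) -> CrossNeighbors:
    """Row-wise top-k of the mutual neighborhood matrix, in both directions."""

    def _topk_sparse(M: sp.csr_matrix) -> sp.csr_matrix:
        M = M.tocsr()
        indptr = [0]
        indices: list[int] = []
        data: list[float] = []
        for a in range(M.shape[0]):
            start, end = M.indptr[a], M.indptr[a + 1]
            cols = M.indices[start:end]
            vals = M.data[start:end]
            order = np.lexsort((cols, -vals))[:k]
            order = np.sort(order)
            indices.extend(cols[order].tolist())
            data.extend(vals[order].tolist())
            indptr.append(len(indices))
        return sp.csr_matrix((data, indices, indptr), shape=M.shape)

    Ct = Ct.tocsr()
    return CrossNeighbors(C_1=_topk_sparse(Ct), C_2=_topk_sparse(Ct.T.tocsr()), k=k)


def stitch_manifolds(
    N_1: sp.spmatrix,
    N_2: sp.spmatrix,
    C_1: sp.spmatrix,
    C_2: sp.spmatrix,
    k: int,
    within_floor: float = 0.3,
) -> CombinedGraph:
    """Assemble the combined cross-species cell graph.

    Within-species edges are reweighted by the one-mode projection
    ``Norm(C_1) @ Norm(C_2)`` (number of shared cross-species neighborhood
    links), masked to the original kNN edges, floored at ``within_floor`` so
    cells with no cross-species support keep their local topology, and then
    attenuated per cell by ``1 - (1/k) * sum_j C_ij`` so strongly aligned
    cells rely mostly on their cross-species edges.
    """
    N_1, N_2 = N_1.tocsr(), N_2.tocsr()
    C_1, C_2 = C_1.tocsr(), C_2.tocsr()

    def _within(N, C_fwd, C_bwd):
        omp = (_row_normalize(C_fwd) @ _row_normalize(C_bwd)).tocsr()
        mask = (N > 0).astype(float).tocsr()
        on_edges = mask.multiply(omp).tocsr()
        floored = mask * within_floor
        out = on_edges.maximum(floored)
        scale = 1.0 - np.asarray(C_fwd.sum(axis=1)).ravel() / k
        np.clip(scale, 0.0, None, out=scale)
        return sp.diags(scale) @ out

    Nt1 = _within(N_1, C_1, C_2)
    Nt2 = _within(N_2, C_2, C_1)
    M = sp.bmat([[Nt1, C_1], [C_2, Nt2]], format="csr")
    return CombinedGraph(matrix=M, n1=N_1.shape[0], n2=N_2.shape[0], within_floor=within_floor)


def overall_alignment_score(
    C_1: sp.spmatrix, C_2: sp.spmatrix, k: int | None = None
) -> float:
    """Average cross-species mutual-neighborhood edge mass per cell.

    ``S = (sum C_1 + sum C_2) / (n1 + n2)``; with ``k`` given the score is
    additionally divided by k, landing in [0, 1] — the scale on which the
    mapping thresholds are defined.
    """
    n1 = C_1.shape[0]
    n2 = C_2.shape[0]
    S = float(C_1.sum() + C_2.sum()) / (n1 + n2)
    if k is not None:
        S /= k
    return S
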