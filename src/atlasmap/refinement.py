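"""The outer mapping loop: alignment, cross-species expression imputation,
gene-gene correlation, homology reweighting, and convergence monitoring.

Each iteration aligns the two manifolds with the current homology graph,
imputes every gene's expression into the partner species through the
cross-species cell graph, smooths within-species expression over the kNN
graph, correlates homologous gene pairs over the concatenated cell panel,
and rewrites the homology edge weights from those correlations. Three
iterations are run by default; the convergence trace records the
root-mean-square change of the cluster-level alignment scores between
adjacent iterations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from . import alignment as al
from . import atlas_manifold as am
from . import homology_graph as hg

__all__ = [
    "ImputedExpression",
    "ConvergenceTrace",
    "MappingResult",
    "impute_and_smooth",
    "gene_pair_correlations",
    "map_atlases",
]


@dataclass
class ImputedExpression:
    """Cross-imputed and kNN-smoothed expression, both directions.

    For a species-1 gene the concatenated cell vector is
    ``[within_1 ; cross_21]`` (species-1 cells then species-2 cells); for a
    species-2 gene it is ``[cross_12 ; within_2]`` — the same cell panel in
    the same order, so homologous genes can be correlated directly.
    """

    cross_12: np.ndarray  # n1 x m2, species-2 genes imputed into species-1 cells
    cross_21: np.ndarray  # n2 x m1
    within_1: np.ndarray  # n1 x m1, kNN-smoothed
    within_2: np.ndarray  # n2 x m2
    gene_ids_1: list[str] = field(default_factory=list)
    gene_ids_2: list[str] = field(default_factory=list)

    def concatenated_1(self) -> np.ndarray:
        """(n1+n2) x m1 panel for species-1 genes."""
        return np.vstack([self.within_1, self.cross_21])

    def concatenated_2(self) -> np.ndarray:
        """(n1+n2) x m2 panel for species-2 genes."""
        return np.vstack([self.cross_12, self.within_2])


@dataclass
class ConvergenceTrace:
    """Per-iteration cluster alignment score tables and adjacent-iteration RMSE."""

    scores: list[pd.DataFrame] = field(default_factory=list)
    rmse: list[float] = field(default_factory=list)

    @property
    def iterations(self) -> int:
        return len(self.scores)


@dataclass
class MappingResult:
    """Everything the mapping run produces."""

    combined: al.CombinedGraph
    homology: hg.HomologyGraph
    trace: ConvergenceTrace
    cross: al.CrossNeighbors
    correlations: pd.DataFrame
    manifold_1: am.AtlasManifold
    manifold_2: am.AtlasManifold
    labels_1: np.ndarray
    labels_2: np.ndarray
    score: float      # overall alignment score on the [0, 1] (per-k) scale
    score_raw: float  # unnormalized: average edge mass per cell


def impute_and_smooth(
    C_1: sp.spmatrix,
    C_2: sp.spmatrix,
    N_1: sp.spmatrix,
    N_2: sp.spmatrix,
    Z_1: np.ndarray,
    Z_2: np.ndarray,
    gene_ids_1: list[str] | None = None,
    gene_ids_2: list[str] | None = None,
) -> ImputedExpression:
    """Weighted-average imputation across species and kNN smoothing within.

    Rows of the cross-species (``C``) and within-species (``N``) graphs are
    L1-normalized first, so imputed/smoothed values are weighted means on the
    expression scale. Cells with no cross-species edges get zero imputed
    expression.
    """
    Cn1 = am._row_normalize(C_1)
    Cn2 = am._row_normalize(C_2)
    Nn1 = am._row_normalize(N_1)
    Nn2 = am._row_normalize(N_2)
    return ImputedExpression(
        cross_12=np.asarray(Cn1 @ Z_2),
        cross_21=np.asarray(Cn2 @ Z_1),
        within_1=np.asarray(Nn1 @ Z_1),
        within_2=np.asarray(Nn2 @ Z_2),
        gene_ids_1=list(gene_ids_1 or []),
        gene_ids_2=list(gene_ids_2 or []),
    )


def gene_pair_correlations(
    imputed: ImputedExpression,
    pairs: pd.DataFrame,
    block_size: int = 2000,
) -> pd.DataFrame:
    """Pearson correlation of homologous gene pairs over the joint cell panel.

    ``pairs`` has columns ``gene_1``/``gene_2`` (the initial unpruned
    homology support). Pairs whose genes are missing from the imputed panel,
    or where either vector is constant, get r = 0. Computation is chunked in
    blocks of ``block_size`` pairs; results are bit-identical for any block
    size because each pair's arithmetic is independent of the blocking.
    """
    V1 = imputed.concatenated_1()
    V2 = imputed.concatenated_2()
    n = V1.shape[0]
    idx1 = {g: i for i, g in enumerate(imputed.gene_ids_1)}
    idx2 = {g: i for i, g in enumerate(imputed.gene_ids_2)}

    mu1, sd1 = V1.mean(axis=0), V1.std(axis=0)
    mu2, sd2 = V2.mean(axis=0), V2.std(axis=0)

    g1 = pairs["gene_1"].to_numpy()
    g2 = pairs["gene_2"].to_numpy()
    i1 = np.array([idx1.get(g, -1) for g in g1])
    i2 = np.array([idx2.get(g, -1) for g in g2])
    r = np.zeros(len(pairs))
    ok = (i1 >= 0) & (i2 >= 0)
    valid = np.nonzero(ok)[0]
    for start in range(0, len(valid), block_size):
        sel = valid[start : start + block_size]
        a, b = i1[sel], i2[sel]
        num = np.einsum("ij,ij->j", V1[:, a], V2[:, b]) / n - mu1[a] * mu2[b]
        denom = sd1[a] * sd2[b]
        nz = denom > 0
        r[sel[nz]] = num[nz] / denom[nz]
    np.clip(r, -1.0, 1.0, out=r)
    return pd.DataFrame({"gene_1": g1, "gene_2": g2, "r": r})


def _trace_rmse(prev: pd.DataFrame, cur: pd.DataFrame) -> float:
    """RMSE between two cluster alignment score tables over their pair union."""
    a = prev.set_index(["type_a", "type_b"])["score"]
    b = cur.set_index(["type_a", "type_b"])["score"]
    union = a.index.union(b.index)
    da = a.reindex(union, fill_value=0.0)
    db = b.reindex(union, fill_value=0.0)
    if len(union) == 0:
        return 0.0
    return float(np.sqrt(np.mean((da - db) ** 2)))


def map_atlases(
    atlas_1: am.ExpressionAtlas,
    atlas_2: am.ExpressionAtlas,
    hits_12: list[hg.BlastHit] | None = None,
    hits_21: list[hg.BlastHit] | None = None,
    homology: hg.HomologyGraph | None = None,
    num_iters: int = 3,
    k: int = 20,
    npcs: int = 150,
    n_top_genes: int = 3000,
    resolution: float = 3.0,
    coarsen_prune: float = 0.1,
    within_floor: float = 0.3,
    block_size: int = 2000,
    seed: int = 0,
    preprocessed: bool = False,
) -> MappingResult:
    """Run the full two-species mapping pipeline.

    Preprocessing and per-species manifold construction run once; alignment
    and homology refinement alternate for ``num_iters`` iterations (3 by
    default). Cluster-level alignment scores are recorded each iteration and
    the RMSE between adjacent score tables forms the convergence trace.

    Either ``homology`` (a prebuilt graph, e.g. one-to-one orthologs) or
    both BLAST hit lists must be provided.
    """
    from . import celltype_analysis as ca

    if homology is None:
        if hits_12 is None or hits_21 is None:
            raise ValueError("provide either a homology graph or both hit lists")
        homology = hg.build_reciprocal_graph(hits_12, hits_21)
    if homology.weights_12 is None:
        homology = hg.filter_and_normalize(homology)
    support = homology.support_pairs()

    if not preprocessed:
        atlas_1 = am.preprocess_atlas(atlas_1)
        atlas_2 = am.preprocess_atlas(atlas_2)
    man1 = am.build_manifold(atlas_1, k=k, npcs=npcs, n_top_genes=n_top_genes, seed=seed)
    man2 = am.build_manifold(
        atlas_2, k=k, npcs=npcs, n_top_genes=n_top_genes, seed=seed + 1
    )

    nb1 = al.expand_neighborhoods(man1.knn_graph, resolution=resolution, seed=seed)
    nb2 = al.expand_neighborhoods(man2.knn_graph, resolution=resolution, seed=seed + 1)

    if man1.cell_types is not None:
        labels_1 = np.asarray(man1.cell_types)
    else:
        labels_1 = np.array([f"c1_{c}" for c in nb1.clusters])
    if man2.cell_types is not None:
        labels_2 = np.asarray(man2.cell_types)
    else:
        labels_2 = np.array([f"c2_{c}" for c in nb2.clusters])

    trace = ConvergenceTrace()
    cross = None
    correlations = pd.DataFrame({"gene_1": [], "gene_2": [], "r": []})
    graph = homology
    for _ in range(num_iters):
        Zt1 = am.standardize_and_mask(man1, graph, side=1)
        Zt2 = am.standardize_and_mask(man2, graph, side=2)
        W12, W21 = graph.reindex(man1.gene_ids, man2.gene_ids)
        Zt12 = al.translate_features(Zt1.values, W12)
        Zt21 = al.translate_features(Zt2.values, W21)
        # joint space ordered [species-1 PCs | species-2 PCs] for both sides
        P1 = al.joint_projection(Zt1.values, Zt12, man1.loadings, man2.loadings)
        P2 = np.hstack([Zt21 @ man1.loadings.T, Zt2.values @ man2.loadings.T])
        raw = al.cross_species_knn(P1, P2, k=k)
        Ct1 = al.coarsen_edges(raw.C_1, nb2, prune=coarsen_prune)
        Ct2 = al.coarsen_edges(raw.C_2, nb1, prune=coarsen_prune)
        Ct = al.mutual_neighborhoods(Ct1, Ct2)
        cross = al.select_knn_neighborhoods(Ct, k=k)

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            scores = ca.celltype_alignment_scores(
                cross.C_1, cross.C_2, labels_1, labels_2, k=k, z=0.0
            )
        if trace.scores:
            trace.rmse.append(_trace_rmse(trace.scores[-1], scores))
        trace.scores.append(scores)

        imputed = impute_and_smooth(
            cross.C_1,
            cross.C_2,
            man1.knn_graph,
            man2.knn_graph,
            man1.lognorm,
            man2.lognorm,
            man1.gene_ids,
            man2.gene_ids,
        )
        correlations = gene_pair_correlations(imputed, support, block_size=block_size)
        graph = hg.update_weights_from_correlation(graph, correlations)

    combined = al.stitch_manifolds(
        man1.knn_graph, man2.knn_graph, cross.C_1, cross.C_2, k=k,
        within_floor=within_floor,
    )
    return MappingResult(
        combined=combined,
        homology=graph,
        trace=trace,
        cross=cross,
        correlations=correlations,
        manifold_1=man1,
        manifold_2=man2,
        labels_1=labels_1,
        labels_2=labels_2,
        score=al.overall_alignment_score(cross.C_1, cross.C_2, k=k),
        score_raw=al.overall_alignment_score(cross.C_1, cross.C_2),
    )
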