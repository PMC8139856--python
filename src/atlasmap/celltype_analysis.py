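"""Downstream statistics on a stitched cross-species map.

Covers cell-type alignment scores, the gene pairs that drive a cell-type
mapping, triad transitivity of the cell-type graph with a bootstrap null,
hypergeometric functional-term enrichment, and one-to-one ortholog selection
by maximum-weight bipartite matching.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.optimize import linear_sum_assignment
from scipy.stats import hypergeom, norm

__all__ = [
    "CellTypeGraph",
    "celltype_alignment_scores",
    "differential_expression",
    "enriched_gene_pairs",
    "transitivity",
    "bootstrap_transitivity_null",
    "hypergeometric_enrichment",
    "max_weight_one_to_one",
]


def _indicator(labels: np.ndarray) -> tuple[sp.csr_matrix, list[str]]:
    cats = sorted(set(labels.tolist()))
    index = {c: j for j, c in enumerate(cats)}
    cols = np.array([index[v] for v in labels])
    M = sp.csr_matrix(
        (np.ones(len(labels)), (np.arange(len(labels)), cols)),
        shape=(len(labels), len(cats)),
    )
    return M, cats


def celltype_alignment_scores(
    C_1: sp.spmatrix,
    C_2: sp.spmatrix,
    labels_1,
    labels_2,
    k: int,
    z: float = 0.1,
) -> pd.DataFrame:
    """Alignment score between every pair of cell types.

    ``s_ab`` is the total cross-species edge mass between type-a cells and
    type-b cells (both directions) divided by ``(|c_a| + |c_b|) * k``, a
    [0, 1] measure of mapping strength. Pairs scoring strictly below ``z``
    are dropped (default 0.1).

    Raises
    ------
    ValueError
        If any cell is unlabeled (None/NaN), listing the offending indices.
    """
    labels_1 = np.asarray(labels_1, dtype=object)
    labels_2 = np.asarray(labels_2, dtype=object)
    for name, lab in (("species 1", labels_1), ("species 2", labels_2)):
        bad = [i for i, v in enumerate(lab) if v is None or (isinstance(v, float) and np.isnan(v))]
        if bad:
            raise ValueError(f"unlabeled cells in {name}: indices {bad[:20]}")
    M1, cats1 = _indicator(labels_1)
    M2, cats2 = _indicator(labels_2)
    E = (M1.T @ C_1 @ M2) + (M2.T @ C_2 @ M1).T
    E = np.asarray(E.todense() if sp.issparse(E) else E)
    n_a = np.asarray(M1.sum(axis=0)).ravel()
    n_b = np.asarray(M2.sum(axis=0)).ravel()
    denom = (n_a[:, None] + n_b[None, :]) * k
    S = E / denom
    rows = []
    for i, a in enumerate(cats1):
        for j, b in enumerate(cats2):
            if S[i, j] > 0 and S[i, j] >= z:
                rows.append(
                    (a, b, float(S[i, j]), int(n_a[i]), int(n_b[j]))
                )
    out = pd.DataFrame(
        rows, columns=["type_a", "type_b", "score", "n_cells_a", "n_cells_b"]
    )
    return out.sort_values("score", ascending=False, ignore_index=True)


def differential_expression(X: np.ndarray, labels) -> pd.DataFrame:
    """One-vs-rest Wilcoxon rank-sum (upregulation) p-values per gene and type.

    Uses the tie-corrected normal approximation of the rank-sum statistic —
    the behavior of the standard single-cell implementations — with the
    one-sided alternative that the group's expression is higher.

    Returns a long frame with columns ``label``, ``gene_index``, ``p``.
    """
    labels = np.asarray(labels)
    n, m = X.shape
    from scipy.stats import rankdata

    ranks = np.empty_like(X, dtype=float)
    tie_term = np.empty(m)
    for g in range(m):
        ranks[:, g] = rankdata(X[:, g])
        _, counts = np.unique(X[:, g], return_counts=True)
        tie_term[g] = np.sum(counts**3 - counts)
    rows = []
    for lab in sorted(set(labels.tolist())):
        grp = labels == lab
        n1 = int(grp.sum())
        n2 = n - n1
        if n1 == 0 or n2 == 0:
            continue
        R1 = ranks[grp].sum(axis=0)
        U = R1 - n1 * (n1 + 1) / 2.0
        mu = n1 * n2 / 2.0
        sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
        sigma = np.sqrt(np.maximum(sigma2, 0.0))
        with np.errstate(divide="ignore", invalid="ignore"):
            zscore = np.where(sigma > 0, (U - mu) / sigma, 0.0)
        p = norm.sf(zscore)
        for g in range(m):
            rows.append((lab, g, float(p[g])))
    return pd.DataFrame(rows, columns=["label", "gene_index", "p"])


def _mapped_cells(
    C_1: sp.spmatrix, C_2: sp.spmatrix, labels_1, labels_2, type_a: str, type_b: str
) -> tuple[np.ndarray, np.ndarray]:
    """Cells of each species incident to cross edges between types a and b."""
    labels_1 = np.asarray(labels_1)
    labels_2 = np.asarray(labels_2)
    in_a = labels_1 == type_a
    in_b = labels_2 == type_b
    C1 = C_1.tocsr()
    C2 = C_2.tocsr()
    sub1 = C1[in_a][:, in_b]
    sub2 = C2[in_b][:, in_a]
    a_idx = np.nonzero(in_a)[0]
    b_idx = np.nonzero(in_b)[0]
    a_hit = np.zeros(len(a_idx), dtype=bool)
    b_hit = np.zeros(len(b_idx), dtype=bool)
    a_hit |= np.asarray(sub1.sum(axis=1)).ravel() > 0
    b_hit |= np.asarray(sub1.sum(axis=0)).ravel() > 0
    b_hit |= np.asarray(sub2.sum(axis=1)).ravel() > 0
    a_hit |= np.asarray(sub2.sum(axis=0)).ravel() > 0
    return a_idx[a_hit], b_idx[b_hit]


def _standardize_vec(y: np.ndarray) -> np.ndarray:
    sd = y.std()
    if sd == 0:
        return np.zeros_like(y)
    return (y - y.mean()) / sd


def enriched_gene_pairs(
    pair: tuple[str, str],
    C_1: sp.spmatrix,
    C_2: sp.spmatrix,
    labels_1,
    labels_2,
    Zt_1: np.ndarray,
    Zt_2: np.ndarray,
    gene_ids_1: list[str],
    gene_ids_2: list[str],
    linked_pairs: pd.DataFrame,
    de_p_1: dict[str, float] | pd.Series,
    de_p_2: dict[str, float] | pd.Series,
    sam_weights_1: dict[str, float] | pd.Series,
    sam_weights_2: dict[str, float] | pd.Series,
    lognorm_1: np.ndarray | None = None,
    lognorm_2: np.ndarray | None = None,
    top_n: int = 1000,
    de_p_max: float = 1e-2,
    min_sam_weight: float = 0.2,
    min_expressed_fraction: float = 0.05,
) -> pd.DataFrame:
    """Rank and filter the homologous gene pairs supporting one type mapping.

    For the mapped cell-type pair, each species' genes get a signature
    ``Y_i`` = mean standardized expression over the cells participating in
    the cross-species edges between the two types. Each linked gene pair is
    scored ``h_g = T(S(Y_1))_g1 * T(S(Y_2))_g2`` where S standardizes a
    vector and T truncates negatives at zero (ignoring lowly expressed
    genes). The top ``top_n`` pairs by h_g are then filtered: both genes
    must be differentially expressed in their cell type (p <= ``de_p_max``),
    carry at least ``min_sam_weight`` manifold weight, and be expressed in
    at least ``min_expressed_fraction`` of their cluster's cells.

    Returns the candidate table ranked by ``h_g`` with a ``passed`` flag.
    """
    type_a, type_b = pair
    cells_a, cells_b = _mapped_cells(C_1, C_2, labels_1, labels_2, type_a, type_b)
    cols = [
        "gene_1", "gene_2", "h_g", "de_p_1", "de_p_2",
        "frac_expr_1", "frac_expr_2", "sam_weight_1", "sam_weight_2", "passed",
    ]
    if len(cells_a) == 0 or len(cells_b) == 0:
        warnings.warn(f"cell type pair {pair} is unmapped; empty table", stacklevel=2)
        return pd.DataFrame(columns=cols)
    Y1 = Zt_1[cells_a].mean(axis=0)
    Y2 = Zt_2[cells_b].mean(axis=0)
    idx1 = {g: i for i, g in enumerate(gene_ids_1)}
    idx2 = {g: i for i, g in enumerate(gene_ids_2)}
    g1 = linked_pairs["gene_1"].to_numpy()
    g2 = linked_pairs["gene_2"].to_numpy()
    keep = np.array([a in idx1 and b in idx2 for a, b in zip(g1, g2)])
    g1, g2 = g1[keep], g2[keep]
    i1 = np.array([idx1[g] for g in g1], dtype=int)
    i2 = np.array([idx2[g] for g in g2], dtype=int)
    T1 = np.clip(_standardize_vec(Y1), 0.0, None)
    T2 = np.clip(_standardize_vec(Y2), 0.0, None)
    h = T1[i1] * T2[i2]
    order = np.argsort(-h, kind="stable")[:top_n]

    def _get(d, key, default=np.nan):
        try:
            return float(d[key])
        except (KeyError, IndexError, TypeError):
            return default

    in_a = np.asarray(labels_1) == type_a
    in_b = np.asarray(labels_2) == type_b
    rows = []
    for o in order:
        if h[o] <= 0:
            break
        a, b = g1[o], g2[o]
        pa = _get(de_p_1, (type_a, a))
        pb = _get(de_p_2, (type_b, b))
        wa = _get(sam_weights_1, a, 0.0)
        wb = _get(sam_weights_2, b, 0.0)
        fa = (
            float((lognorm_1[in_a, idx1[a]] > 0).mean())
            if lognorm_1 is not None
            else 1.0
        )
        fb = (
            float((lognorm_2[in_b, idx2[b]] > 0).mean())
            if lognorm_2 is not None
            else 1.0
        )
        passed = (
            (not np.isnan(pa) and pa <= de_p_max)
            and (not np.isnan(pb) and pb <= de_p_max)
            and wa >= min_sam_weight
            and wb >= min_sam_weight
            and fa >= min_expressed_fraction
            and fb >= min_expressed_fraction
        )
        rows.append((a, b, float(h[o]), pa, pb, fa, fb, wa, wb, bool(passed)))
    return pd.DataFrame(rows, columns=cols)


@dataclass
class CellTypeGraph:
    """Undirected weighted graph of mapped cell types across species pairs."""

    nodes: list[str]
    edges: pd.DataFrame  # columns: node_a, node_b, score
    edge_transitivity: pd.DataFrame | None = None
    node_transitivity: pd.Series | None = None

    @classmethod
    def from_mapping_tables(cls, tables: list[pd.DataFrame]) -> "CellTypeGraph":
        rows = []
        for t in tables:
            for _, r in t.iterrows():
                rows.append((str(r["type_a"]), str(r["type_b"]), float(r["score"])))
        edges = pd.DataFrame(rows, columns=["node_a", "node_b", "score"])
        nodes = sorted(set(edges["node_a"]) | set(edges["node_b"]))
        return cls(nodes=nodes, edges=edges)


def _adjacency_sets(edges: pd.DataFrame) -> dict[str, set[str]]:
    adj: dict[str, set[str]] = {}
    for _, r in edges.iterrows():
        u, v = r["node_a"], r["node_b"]
        if u == v:
            continue
        adj.setdefault(u, set()).add(v)
        adj.setdefault(v, set()).add(u)
    return adj


def transitivity(
    graph: CellTypeGraph,
    edge_threshold: float = 0.05,
    denominator: str = "edge",
) -> CellTypeGraph:
    """Edge and node triad transitivity of the thresholded cell-type graph.

    A triad is a set of three nodes whose induced subgraph is connected
    (two or three of the possible edges present); it is closed if it is a
    triangle. Edge transitivity of (u, v) is the closed fraction of triads
    containing the edge: common neighbors of u and v over all third nodes
    adjacent to u or v. Node transitivity of u is the closed fraction of all
    triads containing u. ``denominator="endpoint"`` switches the edge
    statistic's denominator to all triads containing either endpoint (the
    alternative reading of "triads to which the edge belongs").
    """
    edges = graph.edges[graph.edges["score"] >= edge_threshold].copy()
    adj = _adjacency_sets(edges)
    for n in graph.nodes:
        adj.setdefault(n, set())

    edge_rows = []
    seen = set()
    for _, r in edges.iterrows():
        u, v = r["node_a"], r["node_b"]
        if u == v or (u, v) in seen or (v, u) in seen:
            continue
        seen.add((u, v))
        common = (adj[u] & adj[v]) - {u, v}
        if denominator == "edge":
            third = (adj[u] | adj[v]) - {u, v}
            et = len(common) / len(third) if third else 0.0
        elif denominator == "endpoint":
            # alternative reading: all triads containing either endpoint
            import itertools as it

            closed, total = 0, 0
            for trio in it.combinations(graph.nodes, 3):
                if u not in trio and v not in trio:
                    continue
                a, b, c = trio
                ne = (b in adj[a]) + (c in adj[a]) + (c in adj[b])
                if ne >= 2:
                    total += 1
                    closed += ne == 3
            et = closed / total if total else 0.0
        else:
            raise ValueError("denominator must be 'edge' or 'endpoint'")
        edge_rows.append((u, v, float(r["score"]), et))
    edge_df = pd.DataFrame(
        edge_rows, columns=["node_a", "node_b", "score", "edge_transitivity"]
    )

    node_t = {}
    for u in graph.nodes:
        nbrs = sorted(adj[u])
        closed = 0
        open_centered = 0
        for ii in range(len(nbrs)):
            for jj in range(ii + 1, len(nbrs)):
                if nbrs[jj] in adj[nbrs[ii]]:
                    closed += 1
                else:
                    open_centered += 1
        open_end = 0
        for v in nbrs:
            open_end += len(adj[v] - adj[u] - {u})
        total = closed + open_centered + open_end
        node_t[u] = closed / total if total else 0.0
    node_s = pd.Series(node_t, name="node_transitivity")
    return CellTypeGraph(
        nodes=list(graph.nodes),
        edges=edges.reset_index(drop=True),
        edge_transitivity=edge_df,
        node_transitivity=node_s,
    )


def bootstrap_transitivity_null(
    graph: CellTypeGraph,
    group: list[str],
    reps: int = 100_000,
    seed: int = 0,
    edge_threshold: float = 0.05,
) -> float:
    """Bootstrap p-value for a node group's mean transitivity.

    Repeatedly samples node subsets of the group's size from the cell-type
    graph, computes their mean node transitivity, and reports the add-one
    smoothed fraction of samples at least as transitive as the observed
    group: ``p = (1 + #{null >= observed}) / (reps + 1)``.
    """
    res = transitivity(graph, edge_threshold=edge_threshold)
    nt = res.node_transitivity
    nodes = list(nt.index)
    size = len(group)
    if size > len(nodes):
        raise ValueError(f"group size {size} exceeds node count {len(nodes)}")
    missing = [g for g in group if g not in nt.index]
    if missing:
        raise ValueError(f"group nodes not in graph: {missing}")
    observed = float(nt.loc[list(group)].mean())
    vals = nt.to_numpy()
    rng = np.random.default_rng(seed)
    count = 0
    chunk = max(1, min(reps, 20_000))
    done = 0
    while done < reps:
        b = min(chunk, reps - done)
        keys = rng.random((b, len(nodes)))
        pick = np.argpartition(keys, size - 1, axis=1)[:, :size]
        means = vals[pick].mean(axis=1)
        count += int(np.sum(means >= observed - 1e-15))
        done += b
    return (1 + count) / (reps + 1)


def hypergeometric_enrichment(
    target_genes,
    background_genes,
    term_table: pd.DataFrame,
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of annotation terms.

    ``term_table`` has columns ``gene`` and ``term``. For each term, tests
    whether the target set contains at least as many annotated genes as
    observed, drawing ``|target|`` genes from the background population.

    Raises
    ------
    ValueError
        If the target set is not a subset of the background.
    """
    target = set(target_genes)
    background = set(background_genes)
    if not target <= background:
        extra = sorted(target - background)[:10]
        raise ValueError(f"target genes missing from background: {extra}")
    N = len(background)
    n = len(target)
    rows = []
    for term, sub in term_table.groupby("term"):
        annotated = set(sub["gene"]) & background
        K = len(annotated)
        x = len(annotated & target)
        p = float(hypergeom.sf(x - 1, N, K, n))
        rows.append((term, x, n * K / N, p))
    return pd.DataFrame(rows, columns=["term", "count", "expected", "p"]).sort_values(
        "p", ignore_index=True
    )


def max_weight_one_to_one(
    pairs: list[tuple[str, str, float]]
) -> list[tuple[str, str, float]]:
    """Select a one-to-one gene pairing maximizing total weight.

    Solves maximum-weight bipartite matching (each gene used at most once)
    with the Hungarian algorithm on a dense matrix. Exact ties between
    matchings are broken toward lexicographically smaller gene IDs by an
    infinitesimal bonus. Weights must be nonnegative.
    """
    if not pairs:
        return []
    if any(w < 0 for _, _, w in pairs):
        raise ValueError("weights must be nonnegative")
    genes_1 = sorted({a for a, _, _ in pairs})
    genes_2 = sorted({b for _, b, _ in pairs})
    i1 = {g: i for i, g in enumerate(genes_1)}
    i2 = {g: i for i, g in enumerate(genes_2)}
    m1, m2 = len(genes_1), len(genes_2)
    scale = max(w for _, _, w in pairs) or 1.0
    eps = 1e-9 * scale / (m1 + m2 + 1)
    best: dict[tuple[str, str], float] = {}
    for a, b, w in pairs:
        best[(a, b)] = max(best.get((a, b), 0.0), w)
    W = np.full((m1, m2), -1e-6 * scale)  # discourage non-edges
    for (a, b), w in best.items():
        W[i1[a], i2[b]] = w + eps * ((m1 - i1[a]) + (m2 - i2[b]))
    rows, cols = linear_sum_assignment(W, maximize=True)
    present = best
    out = []
    for r, c in zip(rows, cols):
        key = (genes_1[r], genes_2[c])
        if key in present:
            out.append((key[0], key[1], present[key]))
    return sorted(out)
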