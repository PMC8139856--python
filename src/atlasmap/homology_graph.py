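"""Gene-gene bipartite homology graph: construction from reciprocal BLAST,
bit-score normalization, and correlation-driven reweighting.

The graph connects genes of two species with weighted cross-species edges.
Edges start out weighted by protein/transcript sequence similarity (BLAST bit
scores) and are later reweighted by expression correlation computed on the
aligned manifolds, which prunes many-to-many homologies down to the pairs that
are co-expressed in mapped cell types.

Weights are normalized per gene (per row, in each direction independently)
with a saturating tanh transform::

    w = 0.5 + 0.5 * tanh(10 * s / rowmax(s) - 5)

which maps the best edge of every gene to ~0.99991 and edges at a quarter of
the row maximum to ~0.0067, increasing the contrast between weak and strong
homologies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "BlastHit",
    "HomologyGraph",
    "BlastParseError",
    "parse_blast_table",
    "hits_from_frame",
    "build_reciprocal_graph",
    "filter_and_normalize",
    "update_weights_from_correlation",
    "tanh_row_normalize",
]

#: attainable weight range of the tanh row transform
WEIGHT_MIN = 0.5 + 0.5 * np.tanh(-5.0)  # ~0.0033, open bound
WEIGHT_MAX = 0.5 + 0.5 * np.tanh(5.0)   # ~0.99991, attained by every row max


class BlastParseError(ValueError):
    """Raised for malformed lines in a tabular BLAST file."""


@dataclass(frozen=True)
class BlastHit:
    """A single best-HSP BLAST hit between two genes.

    IDs are species-prefixed (``<tag>_<id>``) so they are globally unique
    across the two gene universes.
    """

    query_gene: str
    subject_gene: str
    bit_score: float
    e_value: float


@dataclass
class HomologyGraph:
    """Weighted bipartite gene-gene graph between two species.

    Attributes
    ----------
    gene_ids_1, gene_ids_2
        Gene identifiers indexing the rows/columns of the matrices.
    raw
        ``m1 x m2`` sparse matrix of combined (direction-averaged) bit scores,
        restricted to reciprocal edges.
    weights_12
        ``m1 x m2`` normalized weights, rows = species-1 genes. ``None`` until
        :func:`filter_and_normalize` has run.
    weights_21
        ``m2 x m1`` normalized weights, rows = species-2 genes.
    support
        ``m1 x m2`` boolean sparse matrix: the *initial unpruned* edge set.
        Refinement iterations compute correlations over exactly these pairs
        and never add edges outside it.
    """

    gene_ids_1: list[str]
    gene_ids_2: list[str]
    raw: sp.csr_matrix
    weights_12: sp.csr_matrix | None = None
    weights_21: sp.csr_matrix | None = None
    support: sp.csr_matrix | None = None
    _index_1: dict[str, int] = field(default_factory=dict, repr=False)
    _index_2: dict[str, int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not self._index_1:
            self._index_1 = {g: i for i, g in enumerate(self.gene_ids_1)}
        if not self._index_2:
            self._index_2 = {g: i for i, g in enumerate(self.gene_ids_2)}

    @property
    def shape(self) -> tuple[int, int]:
        return len(self.gene_ids_1), len(self.gene_ids_2)

    def support_pairs(self) -> pd.DataFrame:
        """The initial unpruned edge set as a (gene_1, gene_2) frame."""
        if self.support is None:
            raise ValueError("graph has no support yet; run filter_and_normalize")
        coo = self.support.tocoo()
        return pd.DataFrame(
            {
                "gene_1": [self.gene_ids_1[i] for i in coo.row],
                "gene_2": [self.gene_ids_2[j] for j in coo.col],
            }
        )

    def reindex(
        self, genes_1: list[str], genes_2: list[str]
    ) -> tuple[sp.csr_matrix, sp.csr_matrix]:
        """Align the directed weight matrices to external gene orderings.

        Genes absent from the graph get empty rows/columns. Returns
        ``(W12, W21)`` with shapes ``len(genes_1) x len(genes_2)`` and the
        transpose-shaped counterpart.
        """
        if self.weights_12 is None or self.weights_21 is None:
            raise ValueError("graph weights not set; run filter_and_normalize")
        r1 = np.array([self._index_1.get(g, -1) for g in genes_1])
        r2 = np.array([self._index_2.get(g, -1) for g in genes_2])
        W12 = _take_submatrix(self.weights_12, r1, r2)
        W21 = _take_submatrix(self.weights_21, r2, r1)
        return W12, W21

    def to_frame(self) -> pd.DataFrame:
        """Edge list with raw scores and (species-1-row) weights."""
        coo = self.raw.tocoo()
        w = np.zeros(coo.nnz)
        if self.weights_12 is not None:
            W = self.weights_12.tocsr()
            for n, (i, j) in enumerate(zip(coo.row, coo.col)):
                w[n] = W[i, j]
        return pd.DataFrame(
            {
                "gene_1": [self.gene_ids_1[i] for i in coo.row],
                "gene_2": [self.gene_ids_2[j] for j in coo.col],
                "raw_score": coo.data,
                "weight": w,
            }
        )

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def write_mtx(self, prefix) -> None:
        """Sparse Matrix Market dump of the two directed weight matrices."""
        from scipy.io import mmwrite

        if self.weights_12 is None or self.weights_21 is None:
            raise ValueError("graph weights not set; run filter_and_normalize")
        mmwrite(f"{prefix}_w12.mtx", self.weights_12)
        mmwrite(f"{prefix}_w21.mtx", self.weights_21)


def _take_submatrix(M: sp.spmatrix, rows: np.ndarray, cols: np.ndarray) -> sp.csr_matrix:
    """Sub/supersample a sparse matrix by row/col index arrays (-1 = missing)."""
    nr, nc = len(rows), len(cols)
    out = sp.lil_matrix((nr, nc))
    Mc = M.tocsr()
    col_map = np.full(M.shape[1], -1, dtype=int)
    valid = cols >= 0
    col_map[cols[valid]] = np.nonzero(valid)[0]
    for i, ri in enumerate(rows):
        if ri < 0:
            continue
        start, end = Mc.indptr[ri], Mc.indptr[ri + 1]
        for j, v in zip(Mc.indices[start:end], Mc.data[start:end]):
            cj = col_map[j]
            if cj >= 0:
                out[i, cj] = v
    return out.tocsr()


def _prefix(tag: str | None, gene: str) -> str:
    return f"{tag}_{gene}" if tag else gene


def parse_blast_table(
    path,
    species_query: str | None = None,
    species_subject: str | None = None,
    evalue_cutoff: float = 1e-6,
) -> list[BlastHit]:
    """Parse a tabular (outfmt-6-like) BLAST file into best-HSP hits.

    Rows need >= 12 whitespace/tab-separated columns with query/subject IDs in
    columns 1-2, E-value in column 11 and bit score in column 12. When a
    (query, subject) pair has several HSPs only the highest-bit-score one is
    kept; hits are then filtered to ``e_value < evalue_cutoff`` (strict).
    Comment lines (``#``) and blank lines are skipped.

    Raises
    ------
    BlastParseError
        On a line with too few columns or non-numeric E-value/bit score,
        naming the offending line number.
    """
    best: dict[tuple[str, str], BlastHit] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 12:
                raise BlastParseError(
                    f"{path}: line {lineno}: expected >=12 columns, got {len(fields)}"
                )
            q = _prefix(species_query, fields[0])
            s = _prefix(species_subject, fields[1])
            try:
                evalue = float(fields[10])
                bit = float(fields[11])
            except ValueError as exc:
                raise BlastParseError(
                    f"{path}: line {lineno}: non-numeric E-value/bit score"
                ) from exc
            if bit < 0:
                raise BlastParseError(f"{path}: line {lineno}: negative bit score")
            key = (q, s)
            if key not in best or bit > best[key].bit_score:
                best[key] = BlastHit(q, s, bit, evalue)
    hits = [h for h in best.values() if h.e_value < evalue_cutoff]
    if not hits:
        warnings.warn(f"no hits below E-value {evalue_cutoff:g} in {path}", stacklevel=2)
    return hits


def hits_from_frame(
    frame: pd.DataFrame,
    species_query: str | None = None,
    species_subject: str | None = None,
    evalue_cutoff: float = 1e-6,
) -> list[BlastHit]:
    """Same contract as :func:`parse_blast_table` for an in-memory outfmt-6 frame.

    Uses positional columns: 0 = query, 1 = subject, 10 = E-value, 11 = bit score.
    """
    best: dict[tuple[str, str], BlastHit] = {}
    arr = frame.to_numpy()
    for row in arr:
        q = _prefix(species_query, str(row[0]))
        s = _prefix(species_subject, str(row[1]))
        bit = float(row[11])
        evalue = float(row[10])
        key = (q, s)
        if key not in best or bit > best[key].bit_score:
            best[key] = BlastHit(q, s, bit, evalue)
    return [h for h in best.values() if h.e_value < evalue_cutoff]


def build_reciprocal_graph(
    hits_12: list[BlastHit], hits_21: list[BlastHit]
) -> HomologyGraph:
    """Combine two directional hit lists into a reciprocal bit-score graph.

    An edge (g, h) is kept only if g hits h in direction 1->2 *and* h hits g
    in direction 2->1; its raw score is the mean of the two directional bit
    scores. One-directional pairs are dropped.

    Raises
    ------
    ValueError
        If no reciprocal edge exists at all.
    """
    A = {(h.query_gene, h.subject_gene): h.bit_score for h in hits_12}
    B = {(h.query_gene, h.subject_gene): h.bit_score for h in hits_21}
    edges: dict[tuple[str, str], float] = {}
    for (g, h), a in A.items():
        b = B.get((h, g))
        if b is not None:
            edges[(g, h)] = 0.5 * (a + b)
    if not edges:
        raise ValueError(
            "no homology between species: no gene pair is supported by both "
            "BLAST directions"
        )
    genes_1 = sorted({g for g, _ in edges})
    genes_2 = sorted({h for _, h in edges})
    idx1 = {g: i for i, g in enumerate(genes_1)}
    idx2 = {h: j for j, h in enumerate(genes_2)}
    rows = np.fromiter((idx1[g] for g, _ in edges), dtype=int, count=len(edges))
    cols = np.fromiter((idx2[h] for _, h in edges), dtype=int, count=len(edges))
    vals = np.fromiter(edges.values(), dtype=float, count=len(edges))
    raw = sp.csr_matrix((vals, (rows, cols)), shape=(len(genes_1), len(genes_2)))
    return HomologyGraph(genes_1, genes_2, raw)


def tanh_row_normalize(
    M: sp.spmatrix, rel_cutoff: float | None = None
) -> sp.csr_matrix:
    """Per-row relative filtering plus the saturating tanh weight transform.

    For each row with positive entries: optionally drop entries strictly below
    ``rel_cutoff * rowmax`` (ties at the boundary are kept), then map each
    surviving score ``s`` to ``0.5 + 0.5*tanh(10*s/rowmax - 5)``. Rows without
    positive entries stay empty.
    """
    M = M.tocsr().copy()
    M.eliminate_zeros()
    rowmax = M.max(axis=1).toarray().ravel()
    out = M.tocoo()
    keep = np.ones(out.nnz, dtype=bool)
    mx = rowmax[out.row]
    assert np.all(mx[out.data > 0] > 0), "gene with edges must have positive rowmax"
    if rel_cutoff is not None:
        keep &= out.data >= rel_cutoff * mx
    data = 0.5 + 0.5 * np.tanh(10.0 * out.data / mx - 5.0)
    res = sp.csr_matrix(
        (data[keep], (out.row[keep], out.col[keep])), shape=M.shape
    )
    res.eliminate_zeros()
    return res


def filter_and_normalize(graph: HomologyGraph, rel_cutoff: float = 0.25) -> HomologyGraph:
    """Fill in normalized weights from the raw reciprocal bit scores.

    Each direction is treated independently: per gene (row), edges with raw
    score strictly below ``rel_cutoff`` times the row maximum are removed and
    the survivors are tanh-normalized (see :func:`tanh_row_normalize`).
    The union of the two directed supports becomes the graph's initial
    unpruned ``support`` used by later refinement rounds.
    """
    if graph.raw.nnz == 0:
        raise ValueError("raw homology graph is empty")
    w12 = tanh_row_normalize(graph.raw, rel_cutoff=rel_cutoff)
    w21 = tanh_row_normalize(graph.raw.T, rel_cutoff=rel_cutoff)
    support = ((w12 > 0) + (w21.T > 0)).astype(bool).tocsr()
    return replace(graph, weights_12=w12, weights_21=w21, support=support)


def update_weights_from_correlation(
    graph: HomologyGraph, correlations: pd.DataFrame
) -> HomologyGraph:
    """Reweight the graph from cross-species expression correlations.

    ``correlations`` has columns ``gene_1``, ``gene_2``, ``r`` covering the
    pairs of the initial unpruned support. Negative correlations are zeroed
    (the edge is pruned); positive ones are re-normalized per row with the
    same tanh transform as the bit scores, in both directions. Pairs naming
    genes outside the graph are ignored; the original raw scores and support
    are retained unchanged.

    Raises
    ------
    ValueError
        If any correlation lies outside [-1, 1].
    """
    r = np.asarray(correlations["r"], dtype=float)
    if np.any(r < -1 - 1e-12) or np.any(r > 1 + 1e-12):
        raise ValueError("correlations must lie in [-1, 1]")
    m1, m2 = graph.shape
    rows, cols, vals = [], [], []
    g1 = correlations["gene_1"].to_numpy()
    g2 = correlations["gene_2"].to_numpy()
    for a, b, v in zip(g1, g2, r):
        if v <= 0:
            continue
        i = graph._index_1.get(a)
        j = graph._index_2.get(b)
        if i is None or j is None:
            continue
        rows.append(i)
        cols.append(j)
        vals.append(v)
    M = sp.csr_matrix((vals, (rows, cols)), shape=(m1, m2))
    w12 = tanh_row_normalize(M)
    w21 = tanh_row_normalize(M.T)
    return replace(graph, weights_12=w12, weights_21=w21)
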