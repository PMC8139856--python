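# Methods

This note documents the model, the defaults and the numerical choices in
`atlasmap`, and what the synthetic studies do and do not demonstrate.

## Homology graph

Directional BLAST tables (outfmt-6-like) are reduced to best-HSP hits per
(query, subject) pair and filtered at E-value < 1e-6 (strict). Reciprocal
pairs get the mean of the two directional bit scores; one-directional pairs
are discarded. Normalization is per gene and per direction: edges strictly
below a quarter of the gene's best score are removed (ties at the boundary
kept), and surviving scores `s` map to `0.5 + 0.5·tanh(10·s/max − 5)`. The
transform saturates the best edge of every gene at ≈0.99991 and pushes weak
edges toward ≈0.0033, increasing contrast between marginal and confident
homologies. Because the normalization is per-gene, the two directions are
kept as separate matrices (`H_1` rows = species-1 genes, `H_2` rows =
species-2 genes) rather than a single symmetric matrix; downstream
operations only ever consume direction-normalized weights.

During refinement, edge weights are replaced by expression correlations
computed over all pairs of the *initial unpruned support* (so edges pruned
in an earlier iteration can recover, but no new pair can appear), negative
correlations are zeroed, and the tanh row transform is reapplied. A gene
whose correlations all vanish loses its edges, and its expression is zeroed
in the next alignment round.

## Per-species manifolds

Counts are rescaled so each cell totals the median library size, then
log2(x+1)-transformed; genes "expressed" (log value > 1) in more than 96% of
cells are removed; zero-count cells are dropped. The manifold builder is a
self-assembling-manifold style iteration: standardize genes, weight them,
run PCA on the top 3000 genes by weight (150 components), build a directed
exact kNN graph (k = 20) under correlation distance, recompute gene weights
as the max-normalized variance of kNN-averaged expression, and repeat until
the RMS weight change falls below 1e-2 (at most 10 iterations; the
convergence tolerance is not externally prescribed, so it is exposed as
configuration). The weight captures how spatially structured a gene is on
the current cell graph. A final PCA over *all* genes (weights folded into
the loadings) yields a 300-row loading matrix so that partner species can be
projected through genes outside the top set; when the data support fewer
than 300 components the loading matrix is zero-padded to keep the joint
space's dimensions fixed. Degenerate inputs (all-identical cells) yield
uniform weights and arbitrary-but-valid neighbor sets rather than errors.

The builder is deliberately pluggable: any object producing `lognorm`,
`knn_graph`, `gene_weights`, `loadings` satisfies the downstream contract,
so a different manifold construction can be swapped in without touching the
alignment code.

## Feature translation and joint projection

Standardized expression (genes with no current homology edge zeroed;
zero-variance genes zeroed, never NaN) is translated into the partner gene
space by the homology graph normalized *over each target gene's homologs*,
making every imputed column a convex combination — a weighted average — of
the gene's homologs. The printed row-of-`H_i` normalization in the source
formula would instead split each source gene's expression across its
targets; the weighted-average reading is the one consistent with the
method's stated intent and is what the worked examples derive, so it is the
implemented semantics. Within- and cross-species projections are
concatenated to a 600-dimensional joint space, ordered [species-1 PCs |
species-2 PCs] for both sides so cosine similarities compare like with like.

## Mutual nearest neighborhoods

Cross-species kNN (cosine, k = 20, exact search; negative similarities
clipped to zero) is made robust by neighborhood coarsening. Each species'
kNN graph is expanded to walk-reachability within t hops (t = 2 below
20,000 cells, 3 otherwise), counting paths; Leiden communities at
resolution 3 cap each cell's neighborhood at its community size, keeping the
geodesically closest cells (ascending hop count, ties broken by descending
path count, then ascending index — fully deterministic). Any
modularity-style clustering at the same resolution would satisfy this
contract; Leiden with a fixed seed is used. A coarsened edge is the
fraction of a cell's L1-normalized outgoing edge mass landing inside a
partner cell's neighborhood; fractions below 0.1 are pruned (before the
geometric mean, matching the order of operations in the method
description). The element-wise geometric mean of the two directions keeps
only mutually supported links, and the top 20 neighborhoods per cell in
each direction become the final biadjacency matrices.

## Stitching and scores

Within-species edges are reweighted by the one-mode projection
`Norm(C_1)·Norm(C_2)` (L1 row normalization; the norm is not prescribed, L1
keeps everything on the fraction scale and is exposed as configuration),
masked to the original kNN edges, floored at 0.3 so unaligned cells keep
their local topology, and attenuated per cell by `1 − (1/k)·ΣC`. The floor
is implemented as `max(0.3, w)`: the printed `min` would cap rather than
floor and contradicts its stated purpose of retaining connectivity.

The overall alignment score is the average cross-species edge mass per cell
divided by k, so it lands in [0, 1] and the reporting thresholds (0.1 for
mapping tables, 0.05 for cell-type graphs) act on that scale. Cell-type
scores `s_ab` divide the inter-type edge mass by `(|c_a|+|c_b|)·k`; the
identity `Σ_ab s_ab(|c_a|+|c_b|) = (n_1+n_2)·S` holds exactly and is
asserted in the tests to 1e-9.

## Refinement correlations

Imputation uses L1-row-normalized graphs so values stay on the expression
scale; correlations use log-normalized (not standardized) expression, since
the imputation formulas reference the raw-scale matrices — the choice is
exposed as configuration. Pearson correlations are computed over the
concatenated (n_1 + n_2)-cell panel, chunked in pair blocks (default 2000);
each pair's arithmetic is independent of the blocking, so results are
bit-identical for any block size (tested). Constant vectors get r = 0. The
iteration count is fixed at 3 by default — the trade-off between alignment
quality and runtime — and a per-iteration RMSE of cluster-level alignment
scores is recorded as the convergence trace; tolerance-based stopping is
deliberately not the default.

## Gene pairs, transitivity, enrichment

Enriched gene pairs for a mapped type pair score each linked pair by the
product of truncated standardized mean signatures over the cells
participating in the cross edges; the top 1000 are filtered by one-vs-rest
Wilcoxon rank-sum DE (tie-corrected normal approximation, one-sided,
p ≤ 1e-2 — the behavior of the standard single-cell implementations),
manifold weight ≥ 0.2, and expressed fraction ≥ 5% of the cluster. Cells
participating in several mapped pairs contribute to each.

Triad transitivity treats a triad as any connected three-node set; an edge's
transitivity is its closed fraction over triads containing the edge (the
alternative denominator — triads containing either endpoint — is available
behind a flag since the verbal definition admits both readings); a node's
transitivity is the closed fraction of triads containing it. Both are
validated against exhaustive triad enumeration. The bootstrap null samples
node subsets of the observed group's size and reports an add-one-smoothed
upper-tail p-value, so p ≥ 1/(reps+1) always.

Hypergeometric term enrichment is the exact upper tail
(`P(X ≥ x)`); one-to-one ortholog selection solves maximum-weight bipartite
matching (Hungarian algorithm) with an infinitesimal lexicographic bonus so
exact ties break deterministically toward smaller gene IDs.

## Paralog substitutions

Pairs are classified from an orthology-group table (gene, level, group):
sharing a group at the species pair's MRCA level makes an ortholog; sharing
only a strictly more ancestral group makes a paralog aged by the most
recent shared level; table gaps are inherited as-is (no interpolation
between levels the table does not provide). A substitution event is emitted
for every paralog whose correlation exceeds the gene's best ortholog
correlation by more than 0.3; the best paralog is flagged, several orthologs
are resolved conservatively by the maximum, a missing ortholog counts as
correlation 0 and is flagged. Correlations are clamped at zero before the
comparison: the refinement's own update zeroes negative correlations, so a
negative value means "not co-expressed" rather than a lower baseline to beat
(without the clamp, an anti-correlated ortholog plus an uncorrelated paralog
would fabricate an event). Per-cell-type substitution scores
`S_k = Σ_{i∈P_k}(1 − n_i)/m_k` normalize for each gene's paralog count and
the type's DE gene count; substitution rates per duplication age divide
substituting paralogs by total paralogs at each level.

## Synthetic data

The generator emulates the structure that makes cross-species mapping hard:
shared cell types with per-type gene programs; homology families that are
one-to-one, one-to-many or many-to-many; species-specific genes with no
homology acting as private markers; program divergence (a fraction of each
type's program families swapped for others in species 2); and planted
paralog substitutions (the species-2 ortholog silenced, a paralog given the
program) plus decoy paralog families that do not substitute. Counts are
negative binomial with lognormal cell size factors and independent dropout
(the standard droplet-data noise model); BLAST tables carry bit scores of
`200·identity + N(0, 10)` floored at 30, with reciprocal hits for true
homologs and one-directional or high-E-value decoys to exercise the
parser's filters. Everything is deterministic given the seed.

What it does *not* emulate: batch effects between platforms, continuous
differentiation trajectories, correlated gene modules within programs,
doublets, or realistic sequence evolution. Passing the recovery studies
therefore shows the pipeline's machinery is correct and well-calibrated
under the stated noise model — not that mapping any particular pair of real
atlases will reach the same scores.

## Study sizes

The self-mapping study uses 8 cell types × 150 cells and 1200 one-to-one
genes per species, mapped against an independently drawn replicate with an
identity homology graph, at three seeds. The cross-species study uses 900
homology families at 30% program divergence, 20% species-specific genes,
30% one-to-many and 5% many-to-many families. The paralog study plants 10
substitutions and 10 decoy paralog families on an otherwise one-to-one
background (20% species-specific genes, 20% divergence) — isolating
substitution detection from unrelated duplicate copies, whose only effect
at this scale is to add chance-correlation opportunities. These sizes run
the full pipeline in well under a minute each on a single CPU.

## Known limitations

- Neighborhood expansion and coarsening are dense-ish at desk scale; the
  exact kNN search is O(n²) and intended for atlases up to a few tens of
  thousands of cells. The contracts allow an approximate search to be
  substituted.
- Alignment scores depend on the Leiden partition through neighborhood
  sizes; different community structures move individual scores slightly
  (the seed is fixed and exposed everywhere).
- The substitution detector inherits the correlation estimator's
  heavy-tailed null when the effective number of distinct expression states
  is small; with few cell types, chance correlations near the 0.3 margin
  among non-expressed homologs are possible.
- Only two-species alignment is supported; multi-species analyses are
  assembled from pairwise maps (as in the cell-type-graph statistics).
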