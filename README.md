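# atlasmap

Cross-species mapping of single-cell transcriptomic atlases through an
iteratively refined gene-homology graph and mutual nearest cross-species
neighborhoods.

## The problem

Comparing cell atlases between distantly related species is hard for two
reasons. First, gene histories are complex: duplications and losses leave
many-to-many homologies and large fractions of each transcriptome with no
counterpart at all, so the one-to-one ortholog lists that within-clade
comparisons rely on discard most of the signal. Second, expression programs
drift, so homologous cell types no longer look alike gene-by-gene.

`atlasmap` addresses both by letting the gene mapping and the cell mapping
reinforce each other. A weighted bipartite gene-gene graph (initialized from
reciprocal BLAST bit scores) translates each species' expression into the
other's gene space; cells are linked across species where their local
within-species neighborhoods are *mutually* connected; and the aligned cell
graph is then used to correlate homologous genes and reweight the homology
graph, pruning homologs that are not co-expressed in the mapped cell types.
The loop runs for three iterations by default.

## The method in brief

For species *i* with expression `Z_i` (cells × genes):

1. **Homology graph.** Reciprocal BLAST hits are combined as
   `G = ½(A + B)` on pairs present in both directions; per gene, edges below
   `0.25·max` are dropped and weights are sharpened with
   `w = 0.5 + 0.5·tanh(10·G/max − 5)`.
2. **Per-species manifolds.** Each atlas is library-normalized
   (`log2`, median library size), and a feature-weighted PCA + directed
   kNN graph `N_i` is iterated until gene weights converge
   (`k = 20`, `npcs = 150`, top 3000 genes); a final PCA over *all* genes
   gives a 300-component loading matrix `L_i`.
3. **Joint space.** Standardized expression `Z̃_i` and its homology-graph
   translation `Z̃_ij` are projected with both species' loadings and
   concatenated to a 600-dimensional joint space
   `P̂_i = [Z̃_i L_iᵀ | Z̃_ij L_jᵀ]`.
4. **Mutual neighborhoods.** Cross-species kNN edges (cosine, `k = 20`) are
   coarsened into fractions of edge mass landing in each partner cell's
   local neighborhood (multi-hop expansion of `N_j`, bounded by Leiden
   community sizes at resolution 3); the element-wise geometric mean
   `C̃ = √(C̃_1 ∘ C̃_2ᵀ)` keeps only reciprocally supported links, from which
   the top-k neighborhoods per cell form `C_1, C_2`.
5. **Stitching.** Within-species edges are reweighted by the one-mode
   projection `Norm(C_1)·Norm(C_2)`, floored at 0.3 and attenuated by each
   cell's cross-species edge mass, then assembled into the combined graph
   `N = [[Ñ_1, C_1], [C_2, Ñ_2]]`.
6. **Refinement.** Expression is imputed across species (`C`-weighted
   averages) and smoothed within species (`N`-weighted averages); Pearson
   correlations over the joint cell panel replace the homology edge weights
   (negatives pruned), and the loop repeats.

Downstream statistics: cell-type alignment scores
`s_ab = Σ C(a,b) / ((|c_a|+|c_b|)·k)` in [0, 1]; the gene pairs driving each
mapping (`h_g = T(S(Y_1))·T(S(Y_2))` with DE, manifold-weight and
expressed-fraction filters); cell-type-graph triad transitivity with a
bootstrap null; hypergeometric term enrichment; ortholog/paralog
classification by orthology-group age; and paralog-substitution detection
(paralog out-correlating the ortholog by > 0.3).

## Worked example

Everything runs on synthetic paired species with known ground truth — no
downloads. Two species share 4 cell types whose programs have diverged by
25%:

```python
from atlasmap import SimConfig, generate_species_pair, map_atlases
from atlasmap.homology_graph import hits_from_frame
from atlasmap.celltype_analysis import celltype_alignment_scores

cfg = SimConfig(n_celltypes=4, cells_per_type=100, divergence=0.25,
                n_ortholog_groups=400, program_size=30, seed=0)
atlas_1, atlas_2, blast_12, blast_21, orthology, truth = generate_species_pair(cfg)
result = map_atlases(
    atlas_1, atlas_2,
    hits_12=hits_from_frame(blast_12), hits_21=hits_from_frame(blast_21),
    num_iters=3, seed=0,
)
print(f"overall alignment score S = {result.score:.3f}")
table = celltype_alignment_scores(
    result.cross.C_1, result.cross.C_2,
    result.labels_1, result.labels_2, k=result.cross.k, z=0.1,
)
print(table.to_string(index=False))
print("rmse trace:", [f"{r:.4f}" for r in result.trace.rmse])
```

prints

```
overall alignment score S = 0.838
type_a type_b    score  n_cells_a  n_cells_b
   t01    t01 0.877241        100        100
   t02    t02 0.855585        100        100
   t00    t00 0.837456        100        100
   t03    t03 0.782721        100        100
rmse trace: ['0.0149', '0.0027']
```

Every true cell-type pair is recovered with alignment score ≈ 0.8 (on the
[0, 1] scale, where 1 means every cell's full mutual-neighborhood capacity
connects the two types), no spurious pair clears the 0.1 reporting
threshold, and the shrinking RMSE between the last two iterations shows the
mapping has converged.

The same workflow is available from the shell:

```bash
atlasmap simulate --outdir sim --seed 0
atlasmap map --atlas1 sim/species1 --atlas2 sim/species2 \
    --blast-12 sim/blast_12.tsv --blast-21 sim/blast_21.tsv \
    --outdir run --seed 0
atlasmap scores --mapdir run --outdir run
atlasmap paralogs --mapdir run --orthology sim/orthology.tsv --outdir run
```

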