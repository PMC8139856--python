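"""Synthetic paired-species atlas generator with ground truth.

Generates two single-cell "species" sharing cell types and a homology
structure typical of cross-species comparisons: one-to-one orthologs,
one-to-many and many-to-many homology families, species-specific genes with
no homology, diverged expression programs, and optionally planted paralog
substitutions (an ortholog silenced in one species while a paralog adopts
its cell-type program). Counts follow a negative binomial with lognormal
cell size factors and independent dropout — the standard noise model for
droplet single-cell data. BLAST-like tables are emitted with bit scores
proportional to simulated sequence identity plus reciprocal and decoy
(one-directional) hits, so the whole pipeline down to the parser is
exercised without any downloaded data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .atlas_manifold import ExpressionAtlas
from .paralog_analysis import DEFAULT_LEVEL_ORDER

__all__ = ["SimConfig", "GroundTruth", "generate_species_pair", "homology_from_truth"]

BLAST_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


@dataclass
class SimConfig:
    """Generator parameters.

    The defaults describe a mid-sized whole-body atlas pair at desk scale:
    8 cell types of 150 cells, ~1100 genes per species, moderate program
    divergence, and homology complexity (one-to-many/many-to-many families,
    species-specific genes) in the proportions such comparisons typically
    show.
    """

    n_celltypes: int = 8
    cells_per_type: int = 150
    n_ortholog_groups: int = 900
    frac_one_to_many: float = 0.2
    frac_many_to_many: float = 0.05
    frac_species_specific: float = 0.2
    program_size: int = 40
    divergence: float = 0.2
    n_substitutions: int = 0
    n_decoy_paralogs: int = 0
    mean_high: float = 8.0
    mean_low: float = 0.2
    dispersion: float = 2.0
    dropout: float = 0.1
    size_factor_sigma: float = 0.3
    n_decoy_blast: int = 200
    seed: int = 0

    def validate(self) -> None:
        for name in (
            "frac_one_to_many",
            "frac_many_to_many",
            "frac_species_specific",
            "divergence",
            "dropout",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in (
            "n_celltypes", "cells_per_type", "n_ortholog_groups", "program_size",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_celltypes * self.program_size > self.n_ortholog_groups:
            raise ValueError(
                "programs larger than gene pool: n_celltypes * program_size "
                "must not exceed n_ortholog_groups"
            )
        n_swap = round(self.divergence * self.program_size)
        reserve = self.n_ortholog_groups - self.n_celltypes * self.program_size
        if self.n_celltypes * n_swap > reserve:
            raise ValueError(
                "not enough non-program families to realize the requested divergence"
            )


@dataclass
class GroundTruth:
    """What the generator planted, for recovery testing."""

    homology: pd.DataFrame          # gene_1, gene_2, relation, age_level
    celltype_pairs: list[tuple[str, str]]
    substitutions: list[dict]       # gene_1, ortholog_2, paralog_2, cell_type
    programs_1: dict[str, list[str]]
    programs_2: dict[str, list[str]]
    config: SimConfig | None = None


def _nb_counts(rng, mu: np.ndarray, dispersion: float, dropout: float) -> np.ndarray:
    """Negative binomial draws with mean mu and shape `dispersion`."""
    r = dispersion
    p = r / (r + mu)
    counts = rng.negative_binomial(r, p)
    if dropout > 0:
        counts = counts * (rng.random(counts.shape) >= dropout)
    return counts.astype(float)


def generate_species_pair(
    config: SimConfig | None = None,
) -> tuple[ExpressionAtlas, ExpressionAtlas, pd.DataFrame, pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Generate a synthetic species pair with full ground truth.

    Returns ``(atlas_1, atlas_2, blast_12, blast_21, orthology_table,
    truth)``. The BLAST frames are in 12-column outfmt-6 layout; gene IDs
    are already species-prefixed, so parse them with an empty species tag.
    Deterministic given ``config.seed``.
    """
    cfg = config or SimConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    F = cfg.n_ortholog_groups
    T = cfg.n_celltypes
    types = [f"t{t:02d}" for t in range(T)]

    # --- assign families to roles -------------------------------------------
    perm = rng.permutation(F)
    program_fams = perm[: T * cfg.program_size].reshape(T, cfg.program_size)
    reserve = list(perm[T * cfg.program_size :])

    flat_prog = program_fams.ravel()
    picks = rng.choice(len(flat_prog), size=cfg.n_substitutions + cfg.n_decoy_paralogs,
                       replace=False) if (cfg.n_substitutions + cfg.n_decoy_paralogs) else np.array([], int)
    sub_fams = set(flat_prog[picks[: cfg.n_substitutions]].tolist())
    decoy_fams = set(flat_prog[picks[cfg.n_substitutions :]].tolist())

    special = sub_fams | decoy_fams
    plain = np.array([f for f in range(F) if f not in special])
    n_otm = int(cfg.frac_one_to_many * F)
    n_mtm = int(cfg.frac_many_to_many * F)
    chosen = rng.choice(len(plain), size=min(n_otm + n_mtm, len(plain)), replace=False)
    otm_fams = set(plain[chosen[:n_otm]].tolist())
    mtm_fams = set(plain[chosen[n_otm:]].tolist())

    # --- gene universe -------------------------------------------------------
    def g1(f):
        return f"sp1_gf{f:05d}"

    def g2(f):
        return f"sp2_gf{f:05d}"

    genes_1 = [g1(f) for f in range(F)]
    genes_1 += [f"sp1_gf{f:05d}p" for f in sorted(mtm_fams)]
    genes_2 = [g2(f) for f in range(F)]
    genes_2 += [f"sp2_gf{f:05d}p" for f in sorted(otm_fams | mtm_fams)]
    genes_2 += [f"sp2_gf{f:05d}q" for f in sorted(sub_fams | decoy_fams)]
    n_specific = int(cfg.frac_species_specific * F)
    specific_1 = [f"sp1_sx{i:05d}" for i in range(n_specific)]
    specific_2 = [f"sp2_sx{i:05d}" for i in range(n_specific)]
    genes_1 += specific_1
    genes_2 += specific_2

    ancestral_levels = DEFAULT_LEVEL_ORDER[1:]
    fam_age = {f: ancestral_levels[rng.integers(len(ancestral_levels))] for f in range(F)}

    # --- orthology table -----------------------------------------------------
    ortho_rows = []
    fam_members_1: dict[int, list[str]] = {f: [g1(f)] for f in range(F)}
    fam_members_2: dict[int, list[str]] = {f: [g2(f)] for f in range(F)}
    for f in sorted(mtm_fams):
        fam_members_1[f].append(f"sp1_gf{f:05d}p")
    for f in sorted(otm_fams | mtm_fams):
        fam_members_2[f].append(f"sp2_gf{f:05d}p")
    for f in sorted(sub_fams | decoy_fams):
        fam_members_2[f].append(f"sp2_gf{f:05d}q")
    for f in range(F):
        ortho_rows.append((g1(f), "Vertebrata", f"V{f:05d}"))
        ortho_rows.append((g2(f), "Vertebrata", f"V{f:05d}"))
        for g in fam_members_1[f] + fam_members_2[f]:
            ortho_rows.append((g, fam_age[f], f"A{f:05d}"))
    orthology = pd.DataFrame(ortho_rows, columns=["gene_id", "level", "group_id"])

    # --- true homology pair list --------------------------------------------
    hom_rows = []
    for f in range(F):
        for a in fam_members_1[f]:
            for b in fam_members_2[f]:
                if a == g1(f) and b == g2(f):
                    rel, age = "ortholog", "Vertebrata"
                else:
                    rel, age = "paralog", fam_age[f]
                hom_rows.append((a, b, rel, age))
    homology = pd.DataFrame(hom_rows, columns=["gene_1", "gene_2", "relation", "age_level"])

    # --- programs ------------------------------------------------------------
    n_swap = round(cfg.divergence * cfg.program_size)
    swap_pool = list(reserve)
    programs_1: dict[str, list[str]] = {}
    programs_2: dict[str, list[str]] = {}
    substitutions: list[dict] = []
    for t, label in enumerate(types):
        fams_t = list(program_fams[t])
        programs_1[label] = [g1(f) for f in fams_t]
        fams_2 = list(fams_t)
        if n_swap:
            # planted substitution/decoy families keep their program so every
            # requested substitution is realized
            droppable = [f for f in fams_2 if f not in special]
            drop_idx = rng.choice(len(droppable), size=min(n_swap, len(droppable)), replace=False)
            dropped = {droppable[i] for i in drop_idx}
            incoming = [swap_pool.pop(0) for _ in range(len(dropped))]
            fams_2 = [f for f in fams_2 if f not in dropped] + incoming
        prog2 = []
        for f in fams_2:
            if f in sub_fams:
                prog2.append(f"sp2_gf{f:05d}q")  # paralog adopts the program
                substitutions.append(
                    {
                        "gene_1": g1(f),
                        "ortholog_2": g2(f),
                        "paralog_2": f"sp2_gf{f:05d}q",
                        "cell_type": label,
                    }
                )
            else:
                prog2.append(g2(f))
        programs_2[label] = prog2
    # species-specific genes are markers of one type in their own species only
    for i, g in enumerate(specific_1):
        programs_1[types[i % T]].append(g)
    for i, g in enumerate(specific_2):
        programs_2[types[i % T]].append(g)

    # --- expression ----------------------------------------------------------
    def _atlas(tag: str, genes: list[str], programs: dict[str, list[str]]) -> ExpressionAtlas:
        gene_index = {g: j for j, g in enumerate(genes)}
        n = T * cfg.cells_per_type
        cell_types = np.repeat(types, cfg.cells_per_type)
        mu_types = np.full((T, len(genes)), cfg.mean_low)
        for t, label in enumerate(types):
            for g in programs[label]:
                mu_types[t, gene_index[g]] = cfg.mean_high
        mu = mu_types[np.repeat(np.arange(T), cfg.cells_per_type)]
        size = np.exp(rng.normal(0.0, cfg.size_factor_sigma, size=n))
        counts = _nb_counts(rng, mu * size[:, None], cfg.dispersion, cfg.dropout)
        cells = [f"{tag}_c{i:05d}" for i in range(n)]
        return ExpressionAtlas(
            sp.csr_matrix(counts), list(genes), cells, cell_types.tolist()
        )

    atlas_1 = _atlas("sp1", genes_1, programs_1)
    atlas_2 = _atlas("sp2", genes_2, programs_2)

    # --- BLAST tables --------------------------------------------------------
    def _blast_row(q, s, identity, evalue=None):
        bit = max(30.0, 200.0 * identity + rng.normal(0.0, 10.0))
        ev = evalue if evalue is not None else 10.0 ** (-bit / 4.0)
        mismatch = int(round((1.0 - identity) * 200))
        return (q, s, round(identity * 100, 2), 200, mismatch, 0, 1, 200, 1, 200, ev, round(bit, 1))

    rows_12, rows_21 = [], []
    for a, b, rel, _ in homology.itertuples(index=False):
        ident = rng.normal(0.85, 0.03) if rel == "ortholog" else rng.normal(0.55, 0.05)
        ident = float(np.clip(ident, 0.35, 0.99))
        rows_12.append(_blast_row(a, b, ident))
        rows_21.append(_blast_row(b, a, ident))
    # decoy hits: one-directional (dropped by reciprocity) and high-E (dropped
    # by the E-value filter)
    for _ in range(cfg.n_decoy_blast):
        a = genes_1[rng.integers(len(genes_1))]
        b = genes_2[rng.integers(len(genes_2))]
        rows_12.append(_blast_row(a, b, 0.3))
    for _ in range(cfg.n_decoy_blast // 4):
        a = genes_1[rng.integers(len(genes_1))]
        b = genes_2[rng.integers(len(genes_2))]
        rows_12.append(_blast_row(a, b, 0.3, evalue=1e-3))
        rows_21.append(_blast_row(b, a, 0.3, evalue=1e-3))
    blast_12 = pd.DataFrame(rows_12, columns=BLAST_COLUMNS)
    blast_21 = pd.DataFrame(rows_21, columns=BLAST_COLUMNS)

    truth = GroundTruth(
        homology=homology,
        celltype_pairs=[(t, t) for t in types],
        substitutions=substitutions,
        programs_1=programs_1,
        programs_2=programs_2,
        config=cfg,
    )
    return atlas_1, atlas_2, blast_12, blast_21, orthology, truth


def homology_from_truth(
    truth: GroundTruth, relations: tuple[str, ...] = ("ortholog",), bit_score: float = 200.0
):
    """Build a clean homology graph from ground-truth pairs.

    With the default ``relations`` this is the identity (one-to-one ortholog)
    graph: every true ortholog pair gets the same bit score in both
    directions, i.e. sequence similarity carries no information beyond the
    pairing itself.
    """
    from .homology_graph import BlastHit, build_reciprocal_graph, filter_and_normalize

    sub = truth.homology[truth.homology["relation"].isin(relations)]
    hits_12 = [BlastHit(a, b, bit_score, 1e-50) for a, b in zip(sub["gene_1"], sub["gene_2"])]
    hits_21 = [BlastHit(b, a, bit_score, 1e-50) for a, b in zip(sub["gene_1"], sub["gene_2"])]
    return filter_and_normalize(build_reciprocal_graph(hits_12, hits_21))
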