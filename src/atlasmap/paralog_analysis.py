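"""Ortholog/paralog classification and paralog-substitution detection.

Homologous gene pairs linked by the mapping carry cross-species expression
correlations. Combined with an orthology-group table (gene, taxonomic level,
group), each pair is classified as ortholog (shared group at the two
species' most recent common ancestor level), paralog (shared group only at a
more ancestral level, whose level dates the duplication), or unannotated.
A gene whose best paralog correlation exceeds its best ortholog correlation
by more than a margin (0.3 by default) is called a paralog substitution:
the paralog appears to have taken over the ortholog's expression program.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_LEVEL_ORDER",
    "HomologPairClassification",
    "SubstitutionEvent",
    "classify_pairs",
    "detect_substitutions",
    "substitution_scores",
    "substitution_rate_by_age",
]

#: taxonomic levels ordered from most recent to most ancestral
DEFAULT_LEVEL_ORDER = [
    "Vertebrata",
    "Chordata",
    "Bilateria",
    "Metazoa",
    "Opisthokonta",
    "Eukaryota",
]


@dataclass(frozen=True)
class HomologPairClassification:
    gene_1: str
    gene_2: str
    relation: str  # "ortholog" | "paralog" | "unannotated"
    age_level: str | None
    correlation: float


@dataclass
class SubstitutionEvent:
    """A gene better correlated with a partner-species paralog than ortholog."""

    gene: str                 # the focal gene whose ortholog was substituted
    ortholog_gene: str | None  # best-correlated ortholog (None if absent)
    substituted_by: str        # the substituting paralog
    corr_ortholog: float
    corr_paralog: float
    diff: float
    age_level: str | None
    ortholog_absent: bool = False
    is_best: bool = False
    cell_types: list[str] = field(default_factory=list)


def _level_groups(orthology_table: pd.DataFrame) -> dict[str, dict[str, set[str]]]:
    """gene -> level -> set of group ids."""
    out: dict[str, dict[str, set[str]]] = {}
    for gene, level, group in orthology_table[
        ["gene_id", "level", "group_id"]
    ].itertuples(index=False):
        out.setdefault(str(gene), {}).setdefault(str(level), set()).add(str(group))
    return out


def classify_pairs(
    pairs: pd.DataFrame,
    orthology_table: pd.DataFrame,
    mrca_level: str = "Vertebrata",
    level_order: list[str] | None = None,
) -> pd.DataFrame:
    """Label linked gene pairs as ortholog / paralog / unannotated.

    ``pairs`` has columns ``gene_1``, ``gene_2``, ``r``; the orthology table
    has columns ``gene_id``, ``level``, ``group_id``. A pair sharing a group
    at the MRCA level (or a more recent one, should the table contain any) is
    an ortholog; sharing only a strictly more ancestral group makes it a
    paralog whose age is the most recent shared level; genes absent from the
    table or sharing no group are unannotated.
    """
    order = level_order or DEFAULT_LEVEL_ORDER
    if mrca_level not in order:
        raise ValueError(f"mrca_level {mrca_level!r} not in level order {order}")
    mrca_idx = order.index(mrca_level)
    lg = _level_groups(orthology_table)
    rows = []
    for g1, g2, r in pairs[["gene_1", "gene_2", "r"]].itertuples(index=False):
        d1 = lg.get(str(g1), {})
        d2 = lg.get(str(g2), {})
        shared_idx = None
        for idx, level in enumerate(order):
            if d1.get(level) and d2.get(level) and d1[level] & d2[level]:
                shared_idx = idx
                break
        if shared_idx is None:
            rel, age = "unannotated", None
        elif shared_idx <= mrca_idx:
            rel, age = "ortholog", order[shared_idx]
        else:
            rel, age = "paralog", order[shared_idx]
        rows.append((g1, g2, rel, age, float(r)))
    return pd.DataFrame(
        rows, columns=["gene_1", "gene_2", "relation", "age_level", "correlation"]
    )


def detect_substitutions(
    classified: pd.DataFrame, diff_threshold: float = 0.3
) -> list[SubstitutionEvent]:
    """Emit a substitution event for every paralog out-correlating the ortholog.

    Each gene (from either species) with at least one scored paralog is
    compared against its best-correlated ortholog (correlation 0 and
    ``ortholog_absent`` flagged when no ortholog is scored). Every paralog
    whose correlation exceeds that by strictly more than ``diff_threshold``
    yields an event; the strongest paralog per gene is flagged ``is_best``.

    Negative correlations are clamped to zero before comparison — the
    refinement loop itself zeroes negative correlations, so a negative value
    means "not co-expressed", not "anti-substituted".
    """
    classified = classified.copy()
    classified["correlation"] = classified["correlation"].clip(lower=0.0)
    events: list[SubstitutionEvent] = []
    for focal_col, partner_col in (("gene_1", "gene_2"), ("gene_2", "gene_1")):
        for gene, sub in classified.groupby(focal_col):
            orthos = sub[sub["relation"] == "ortholog"]
            paras = sub[sub["relation"] == "paralog"]
            if paras.empty:
                continue
            if orthos.empty:
                c_o, best_o, absent = 0.0, None, True
            else:
                i = orthos["correlation"].idxmax()
                c_o = float(orthos.loc[i, "correlation"])
                best_o = str(orthos.loc[i, partner_col])
                absent = False
            hits = []
            for _, row in paras.iterrows():
                diff = float(row["correlation"]) - c_o
                if diff > diff_threshold:
                    hits.append(
                        SubstitutionEvent(
                            gene=str(gene),
                            ortholog_gene=best_o,
                            substituted_by=str(row[partner_col]),
                            corr_ortholog=c_o,
                            corr_paralog=float(row["correlation"]),
                            diff=diff,
                            age_level=row["age_level"],
                            ortholog_absent=absent,
                        )
                    )
            if hits:
                best = max(hits, key=lambda e: e.corr_paralog)
                best.is_best = True
                events.extend(hits)
    return events


def substitution_scores(
    events: list[SubstitutionEvent],
    de_gene_counts: dict[str, int],
    paralog_counts: dict[str, int],
    homolog_map: dict[str, str] | None = None,
) -> dict[str, float]:
    """Per-cell-type paralog substitution score.

    ``S_k = sum_{i in P_k} (1 - n_i) / m_k`` where ``P_k`` is the set of
    best substitution events assigned to cell type k (via their
    ``cell_types``), ``n_i`` is the focal gene's paralog count normalized by
    the maximum paralog count over all genes, and ``m_k`` the number of
    differentially expressed genes of the type. Types with ``m_k = 0`` get
    NaN. If ``homolog_map`` maps cell types to a shared (cross-species)
    name, scores sharing a name are averaged and reported under it.
    """
    max_paralogs = max(paralog_counts.values(), default=0)
    scores: dict[str, float] = {}
    for ct, m_k in de_gene_counts.items():
        if m_k == 0:
            scores[ct] = float("nan")
            continue
        total = 0.0
        for e in events:
            if not e.is_best or ct not in e.cell_types:
                continue
            n_i = (
                paralog_counts.get(e.gene, 0) / max_paralogs
                if max_paralogs > 0
                else 0.0
            )
            total += 1.0 - n_i
        scores[ct] = total / m_k
    if homolog_map:
        grouped: dict[str, list[float]] = {}
        for ct, s in scores.items():
            grouped.setdefault(homolog_map.get(ct, ct), []).append(s)
        scores = {
            name: float(np.nanmean(vals)) if not np.all(np.isnan(vals)) else float("nan")
            for name, vals in grouped.items()
        }
    return scores


def substitution_rate_by_age(
    events: list[SubstitutionEvent], totals: dict[str, int]
) -> dict[str, float]:
    """Fraction of paralogs substituting orthologs, per duplication age level.

    ``totals`` counts all paralog pairs at each level; the rate is the number
    of distinct substituting (gene, paralog) pairs at the level divided by
    that total. Levels with zero paralogs get NaN.
    """
    subs_per_level: dict[str, set[tuple[str, str]]] = {}
    for e in events:
        if e.age_level is None:
            continue
        subs_per_level.setdefault(e.age_level, set()).add((e.gene, e.substituted_by))
    rates: dict[str, float] = {}
    for level, total in totals.items():
        if total == 0:
            rates[level] = float("nan")
        else:
            rates[level] = len(subs_per_level.get(level, ())) / total
    return rates
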