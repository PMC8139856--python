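"""Readers and writers for the standard on-disk formats.

Atlases travel as Matrix Market sparse matrices with gene/barcode ID lists
(or dense TSV); BLAST results as 12-column tabular files; homology graphs,
mapping tables and orthology tables as TSV.
"""

from __future__ import annotations

import json
import os

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

from .atlas_manifold import ExpressionAtlas

__all__ = [
    "read_mtx_atlas",
    "read_dense_atlas",
    "write_mtx_atlas",
    "read_cell_types",
    "write_blast_table",
    "write_species_pair",
]


def read_cell_types(path) -> dict[str, str]:
    """Two-column TSV (cell_id, label) -> dict."""
    df = pd.read_csv(path, sep="\t", header=None, names=["cell_id", "label"], dtype=str)
    return dict(zip(df["cell_id"], df["label"]))


def read_mtx_atlas(
    mtx_path, genes_path, barcodes_path, cell_types_path=None
) -> ExpressionAtlas:
    """Load an atlas from Matrix Market + ID lists.

    Orientation is inferred: if the matrix is genes x cells it is transposed
    so the atlas is cells x genes.
    """
    M = sp.csr_matrix(mmread(mtx_path))
    genes = pd.read_csv(genes_path, sep="\t", header=None)[0].astype(str).tolist()
    cells = pd.read_csv(barcodes_path, sep="\t", header=None)[0].astype(str).tolist()
    if M.shape == (len(genes), len(cells)) and M.shape[0] != M.shape[1]:
        M = M.T.tocsr()
    if M.shape != (len(cells), len(genes)):
        raise ValueError(
            f"matrix shape {M.shape} matches neither (cells, genes)="
            f"({len(cells)}, {len(genes)}) nor its transpose"
        )
    cell_types = None
    if cell_types_path is not None:
        mapping = read_cell_types(cell_types_path)
        missing = [c for c in cells if c not in mapping]
        if missing:
            raise ValueError(f"cells missing from cell-type table: {missing[:10]}")
        cell_types = [mapping[c] for c in cells]
    return ExpressionAtlas(M, genes, cells, cell_types)


def read_dense_atlas(path, cell_types_path=None) -> ExpressionAtlas:
    """Dense TSV: rows = cells (index), columns = genes (header)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    cell_types = None
    if cell_types_path is not None:
        mapping = read_cell_types(cell_types_path)
        cell_types = [mapping[c] for c in df.index.astype(str)]
    return ExpressionAtlas(
        sp.csr_matrix(df.to_numpy(dtype=float)),
        [str(g) for g in df.columns],
        [str(c) for c in df.index],
        cell_types,
    )


def write_mtx_atlas(atlas: ExpressionAtlas, outdir) -> None:
    os.makedirs(outdir, exist_ok=True)
    M = atlas.counts if sp.issparse(atlas.counts) else sp.csr_matrix(atlas.counts)
    mmwrite(os.path.join(outdir, "matrix.mtx"), M)
    pd.Series(atlas.gene_ids).to_csv(
        os.path.join(outdir, "genes.tsv"), sep="\t", index=False, header=False
    )
    pd.Series(atlas.cell_ids).to_csv(
        os.path.join(outdir, "barcodes.tsv"), sep="\t", index=False, header=False
    )
    if atlas.cell_types is not None:
        pd.DataFrame({"cell_id": atlas.cell_ids, "label": atlas.cell_types}).to_csv(
            os.path.join(outdir, "cell_types.tsv"), sep="\t", index=False, header=False
        )


def write_blast_table(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, sep="\t", index=False, header=False)


def write_species_pair(outdir, atlas_1, atlas_2, blast_12, blast_21, orthology, truth) -> None:
    """Write a generated species pair in the exact formats the pipeline reads."""
    os.makedirs(outdir, exist_ok=True)
    write_mtx_atlas(atlas_1, os.path.join(outdir, "species1"))
    write_mtx_atlas(atlas_2, os.path.join(outdir, "species2"))
    write_blast_table(blast_12, os.path.join(outdir, "blast_12.tsv"))
    write_blast_table(blast_21, os.path.join(outdir, "blast_21.tsv"))
    orthology.to_csv(os.path.join(outdir, "orthology.tsv"), sep="\t", index=False)
    payload = {
        "celltype_pairs": truth.celltype_pairs,
        "substitutions": truth.substitutions,
        "homology": truth.homology.to_dict(orient="list"),
        "programs_1": truth.programs_1,
        "programs_2": truth.programs_2,
    }
    with open(os.path.join(outdir, "truth.json"), "w") as fh:
        json.dump(payload, fh, indent=1)
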