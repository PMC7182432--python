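"""Shared constructors for small in-memory fixtures."""

import numpy as np
import pandas as pd
from scipy import sparse

from scgps import LOGNORM, RAW_COUNTS, CellTable, ExpressionMatrix


def make_lognorm(dense, gene_ids=None, cell_ids=None):
    """Wrap a dense genes × cells array as a lognorm-tagged ExpressionMatrix."""
    dense = np.asarray(dense, dtype=float)
    G, N = dense.shape
    return ExpressionMatrix(
        values=sparse.csr_matrix(dense),
        gene_ids=gene_ids if gene_ids is not None else [f"g{i}" for i in range(G)],
        cell_ids=cell_ids if cell_ids is not None else [f"c{i}" for i in range(N)],
        layer=LOGNORM,
    )


def make_counts(dense, gene_ids=None, cell_ids=None):
    dense = np.asarray(dense)
    G, N = dense.shape
    return ExpressionMatrix(
        values=sparse.csr_matrix(dense),
        gene_ids=gene_ids if gene_ids is not None else [f"g{i}" for i in range(G)],
        cell_ids=cell_ids if cell_ids is not None else [f"c{i}" for i in range(N)],
        layer=RAW_COUNTS,
    )


def make_cells(cell_ids, cluster=None, genotype=None):
    df = pd.DataFrame({"barcode": list(cell_ids)})
    if cluster is not None:
        df["cluster"] = list(cluster)
    if genotype is not None:
        df["genotype"] = list(genotype)
    return CellTable(table=df)


def random_sparse_counts(rng, n_genes, n_cells, density=0.3, max_count=20):
    """Random sparse count matrix with engineered tie blocks (repeated values)."""
    dense = np.zeros((n_genes, n_cells), dtype=int)
    mask = rng.random((n_genes, n_cells)) < density
    # few distinct values => many ties within genes
    dense[mask] = rng.integers(1, max_count + 1, size=mask.sum())
    return dense
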