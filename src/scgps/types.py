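"""Core in-memory containers for the scoring pipeline.

The pipeline is built around four small containers:

* :class:`ExpressionMatrix` — a genes × cells matrix of UMI counts or
  log-normalized values, sparse-backed, with gene identifiers and cell
  barcodes. Orientation is fixed as genes on rows and cells on columns,
  matching the 10x triplet convention.
* :class:`GeneSetCollection` — named gene modules (ordered identifier lists),
  e.g. a cell-cycle list or OMIM disease-gene lists.
* :class:`CellTable` — per-cell metadata (cluster, genotype, stage).
* :class:`ScoreTable` — the cell × gene-set matrix of scGPS values in [0, 1].

Containers validate their invariants at construction time so that downstream
code can assume them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

from ._errors import DataError

RAW_COUNTS = "raw_counts"
LOGNORM = "lognorm"
_LAYERS = (RAW_COUNTS, LOGNORM)

UNASSIGNED = "unassigned"


def _check_unique(ids: np.ndarray, what: str) -> None:
    if len(np.unique(ids)) != len(ids):
        vals, counts = np.unique(ids, return_counts=True)
        dup = vals[counts > 1]
        raise DataError(f"duplicate {what}: {', '.join(map(str, dup[:10]))}")


@dataclass
class ExpressionMatrix:
    """Genes × cells expression matrix.

    Parameters
    ----------
    values
        Sparse (CSR) or dense matrix, genes as rows, cells as columns.
        Entries must be non-negative; raw counts must be integral.
    gene_ids, cell_ids
        Ordered, unique identifiers matching the matrix dimensions.
    layer
        ``"raw_counts"`` for UMI counts, ``"lognorm"`` for values produced by
        :func:`scgps.normalize.normalize_log`.
    """

    values: sparse.csr_matrix
    gene_ids: np.ndarray
    cell_ids: np.ndarray
    layer: str

    def __post_init__(self) -> None:
        if self.layer not in _LAYERS:
            raise DataError(f"unknown layer tag {self.layer!r}; expected one of {_LAYERS}")
        if not sparse.issparse(self.values):
            self.values = sparse.csr_matrix(np.asarray(self.values))
        else:
            self.values = self.values.tocsr()
        self.values.eliminate_zeros()
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        g, c = self.values.shape
        if g != len(self.gene_ids) or c != len(self.cell_ids):
            raise DataError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} gene ids × {len(self.cell_ids)} cell ids"
            )
        _check_unique(self.gene_ids, "gene identifiers")
        _check_unique(self.cell_ids, "cell barcodes")
        if self.values.nnz and self.values.data.min() < 0:
            raise DataError("expression matrix contains negative entries")
        if self.layer == RAW_COUNTS and self.values.nnz:
            data = self.values.data
            if not np.array_equal(data, np.floor(data)):
                raise DataError("raw count matrix contains non-integer entries")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def gene_index(self) -> dict:
        """Mapping from gene identifier to row index."""
        return {g: i for i, g in enumerate(self.gene_ids)}

    def to_dense(self) -> np.ndarray:
        return np.asarray(self.values.todense())


@dataclass
class GeneSetCollection:
    """Named gene modules: mapping from set name to an ordered gene list."""

    sets: dict
    descriptions: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            genes = list(genes)
            if not genes:
                raise DataError(f"gene set {name!r} is empty")
            if len(set(genes)) != len(genes):
                raise DataError(f"gene set {name!r} contains duplicate identifiers")
            self.sets[name] = genes

    def __len__(self) -> int:
        return len(self.sets)

    def names(self) -> list:
        return list(self.sets)


@dataclass
class CellTable:
    """Per-cell metadata: barcode plus cluster / genotype / stage labels.

    Missing optional columns are represented by a single ``"unassigned"``
    level so group operations always have a label to work with.
    """

    table: pd.DataFrame

    REQUIRED = ("barcode",)
    OPTIONAL = ("cluster", "genotype", "stage")

    def __post_init__(self) -> None:
        df = self.table.copy()
        for col in self.REQUIRED:
            if col not in df.columns:
                raise DataError(f"cell table is missing required column {col!r}")
        dup = df["barcode"][df["barcode"].duplicated()]
        if len(dup):
            raise DataError(
                "duplicated barcodes in cell table: "
                + ", ".join(map(str, dup.unique()[:10]))
            )
        for col in self.OPTIONAL:
            if col not in df.columns:
                df[col] = UNASSIGNED
            df[col] = df[col].astype(str)
        df["barcode"] = df["barcode"].astype(str)
        self.table = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def barcodes(self) -> np.ndarray:
        return self.table["barcode"].to_numpy()

    def labels_for(self, cell_ids, column: str) -> np.ndarray:
        """Labels from `column` aligned to `cell_ids`; errors on missing cells."""
        lookup = pd.Series(
            self.table[column].to_numpy(), index=self.table["barcode"]
        )
        cell_ids = np.asarray(cell_ids, dtype=object)
        missing = [c for c in cell_ids if c not in lookup.index]
        if missing:
            raise DataError(
                "cells absent from cell table: " + ", ".join(map(str, missing[:10]))
            )
        return lookup.loc[cell_ids].to_numpy()


@dataclass
class ScoreTable:
    """Cell × gene-set matrix of scGPS scores.

    ``genes_used`` records, per retained set, the number ``m`` of module genes
    actually found in the expression matrix — the divisor of the score.
    ``dropped_sets`` lists sets with no overlap that were skipped.
    """

    scores: np.ndarray
    cell_ids: np.ndarray
    set_names: list
    genes_used: dict
    dropped_sets: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        self.set_names = list(self.set_names)
        if self.scores.ndim != 2 or self.scores.shape != (
            len(self.cell_ids),
            len(self.set_names),
        ):
            raise DataError(
                f"score matrix shape {self.scores.shape} does not match "
                f"{len(self.cell_ids)} cells × {len(self.set_names)} sets"
            )
        if self.scores.size and (
            self.scores.min() < 0.0 or self.scores.max() > 1.0
        ):
            raise DataError("scores outside [0, 1]")
        for name in self.set_names:
            if self.genes_used.get(name, 0) < 1:
                raise DataError(f"retained set {name!r} has genes_used < 1")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.scores, index=pd.Index(self.cell_ids, name="barcode"),
            columns=self.set_names,
        )
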