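"""Library-size normalization and cluster-level summary statistics.

``normalize_log`` produces the "normalized and log-transformed" values the
scoring statistic consumes: each cell's counts are scaled to a common total
(default 10,000) and transformed with ln(1 + x). ``cluster_summary`` computes
the per-cluster mean expression, the fraction of expressing cells, and the
per-gene z-score of cluster means used in heat-map / dot-plot style displays.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse

from ._errors import DataError
from .types import LOGNORM, RAW_COUNTS, CellTable, ExpressionMatrix


@dataclass
class ClusterSummary:
    """Cluster × gene summaries of a log-normalized matrix.

    mean_expr
        Per-cluster arithmetic mean of log-normalized values.
    pct_expr
        Fraction of cells in the cluster with value > 0, in [0, 1].
    z_expr
        mean_expr z-scored per gene across clusters (sample SD, n−1); genes
        with zero variance across clusters get 0 everywhere.
    """

    mean_expr: pd.DataFrame
    pct_expr: pd.DataFrame
    z_expr: pd.DataFrame


def normalize_log(counts: ExpressionMatrix, scale_total: float = 1e4) -> ExpressionMatrix:
    """Total-count normalize to `scale_total` per cell, then ln(1 + x).

    entry(g, c) = ln(1 + count(g, c) * scale_total / total(c)).

    Zeros map to zeros, so the sparsity pattern is preserved. Cells with a
    zero total have no defined scaling and raise :class:`DataError` listing
    their barcodes.
    """
    if counts.layer != RAW_COUNTS:
        raise DataError(f"normalize_log expects raw counts, got layer {counts.layer!r}")
    if scale_total <= 0:
        raise DataError("scale_total must be positive")
    totals = np.asarray(counts.values.sum(axis=0)).ravel()
    zero = totals == 0
    if zero.any():
        bad = counts.cell_ids[zero]
        raise DataError(
            f"{zero.sum()} cell(s) have zero total counts: "
            + ", ".join(map(str, bad[:10]))
        )
    # scale each column (cell) by scale_total / total, then log1p the data
    scale = scale_total / totals
    X = (counts.values.astype(float) @ sparse.diags(scale)).tocsc()
    X.data = np.log1p(X.data)
    return ExpressionMatrix(
        values=X.tocsr(), gene_ids=counts.gene_ids, cell_ids=counts.cell_ids,
        layer=LOGNORM,
    )


def _require_genes(lognorm: ExpressionMatrix, genes) -> np.ndarray:
    index = lognorm.gene_index()
    missing = [g for g in genes if g not in index]
    if missing:
        raise DataError("unknown gene(s): " + ", ".join(map(str, missing[:10])))
    return np.array([index[g] for g in genes], dtype=int)


def cluster_summary(lognorm: ExpressionMatrix, cells: CellTable, genes) -> ClusterSummary:
    """Per-cluster mean, percent-expressing, and z-scored mean for `genes`.

    Cluster labels come from `cells` (every cell in the matrix must appear
    there). Cluster order is first appearance in the cell table; gene order
    follows the request.
    """
    if lognorm.layer != LOGNORM:
        raise DataError("cluster_summary expects a log-normalized matrix")
    genes = list(genes)
    rows = _require_genes(lognorm, genes)
    labels = cells.labels_for(lognorm.cell_ids, "cluster")
    clusters = list(pd.unique(cells.table["cluster"]))
    clusters = [c for c in clusters if c in set(labels)]
    sub = lognorm.values[rows, :].tocsc()
    mean = np.zeros((len(clusters), len(genes)))
    pct = np.zeros_like(mean)
    for i, cl in enumerate(clusters):
        mask = labels == cl
        block = sub[:, mask]
        n = mask.sum()
        mean[i] = np.asarray(block.sum(axis=1)).ravel() / n
        pct[i] = np.asarray((block > 0).sum(axis=1)).ravel() / n
    mu = mean.mean(axis=0)
    if len(clusters) >= 2:
        sd = mean.std(axis=0, ddof=1)
    else:
        sd = np.zeros(len(genes))
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 0, (mean - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    idx = pd.Index(clusters, name="cluster")
    cols = pd.Index(genes, name="gene")
    return ClusterSummary(
        mean_expr=pd.DataFrame(mean, index=idx, columns=cols),
        pct_expr=pd.DataFrame(pct, index=idx, columns=cols),
        z_expr=pd.DataFrame(z, index=idx, columns=cols),
    )


def percent_expressing(lognorm: ExpressionMatrix, cells: CellTable, genes) -> pd.DataFrame:
    """Cluster × gene fraction of cells with value > 0 (standalone view)."""
    return cluster_summary(lognorm, cells, genes).pct_expr
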