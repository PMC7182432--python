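"""Single-cell Geneset Percentile Score (scGPS).

The statistic scores each cell against a gene module in two steps:

1. **Per-gene percent rank.** For gene *g*, each cell's log-normalized value
   is ranked against that gene's values in all cells. Tied values take the
   lowest rank (rank(c) = 1 + #{c' : x(c') < x(c)}), and ranks are rescaled
   to [0, 1] as (rank − 1) / (N − 1). A constant gene therefore scores 0 in
   every cell, and a gene with all-distinct values spans exactly
   {0, 1/(N−1), …, 1}.
2. **Module mean.** The scGPS of a cell for a module of m genes is the mean
   of the m per-gene percent ranks. A score of p reads as: the module's mean
   expression sits at the p-th percentile for that cell.

Module genes absent from the matrix are dropped and m reduced (with a
warning); optionally they can instead be kept at percent rank 0 via
``missing_as_zero``.

Ranks are computed on the log-normalized layer; percent ranks are invariant
under any strictly increasing per-gene transform, so the choice of scale
factor or log base does not change the score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.stats import rankdata

from ._errors import DataError
from .types import LOGNORM, ExpressionMatrix, GeneSetCollection, ScoreTable

logger = logging.getLogger("scgps")


@dataclass
class PercentRankMatrix:
    """Per-gene, per-cell percent ranks in [0, 1]; same shape as the input."""

    values: sparse.csr_matrix
    gene_ids: np.ndarray
    cell_ids: np.ndarray

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def gene_index(self) -> dict:
        return {g: i for i, g in enumerate(self.gene_ids)}


def percent_rank(lognorm: ExpressionMatrix, allow_raw: bool = False) -> PercentRankMatrix:
    """Cell-wise percent rank of each gene's expression, ties to lowest rank.

    For each gene independently over all N cells:
    rank(c) = 1 + #{c' : x(c') < x(c)}; PR(c) = (rank(c) − 1) / (N − 1).

    Requires N ≥ 2 (percent rank is undefined for a single cell) and a
    log-normalized matrix unless ``allow_raw`` is set. Because values are
    non-negative and zero is the minimum whenever any zero is present, ranks
    only need to be computed over each gene's nonzero entries: all zeros tie
    at the lowest rank and keep percent rank 0 exactly.
    """
    if lognorm.layer != LOGNORM and not allow_raw:
        raise DataError(
            f"percent_rank expects log-normalized values (layer {lognorm.layer!r}); "
            "pass allow_raw=True to override"
        )
    N = lognorm.n_cells
    if N < 2:
        raise DataError(f"percent rank needs at least 2 cells, got {N}")
    X = lognorm.values.tocsr()
    X.eliminate_zeros()
    out_data = np.empty_like(X.data, dtype=float)
    indptr, data = X.indptr, X.data
    denom = N - 1
    for g in range(X.shape[0]):
        lo, hi = indptr[g], indptr[g + 1]
        if lo == hi:
            continue
        v = data[lo:hi]
        n_zero = N - (hi - lo)
        r_nz = rankdata(v, method="min")
        if n_zero:
            # zeros occupy ranks 1..n_zero; nonzero rank = n_zero + within-nonzero rank
            out_data[lo:hi] = (n_zero + r_nz - 1) / denom
        else:
            out_data[lo:hi] = (r_nz - 1) / denom
    pr = sparse.csr_matrix((out_data, X.indices.copy(), X.indptr.copy()), shape=X.shape)
    pr.eliminate_zeros()
    return PercentRankMatrix(values=pr, gene_ids=lognorm.gene_ids, cell_ids=lognorm.cell_ids)


def score_gene_set(
    pr: PercentRankMatrix,
    set_genes,
    set_name: str = "gene_set",
    missing_as_zero: bool = False,
    case_insensitive: bool = False,
):
    """Mean percent rank over a module; returns (per-cell scores, m).

    m counts the module genes found in the matrix; absent genes are dropped
    with a warning (or, with ``missing_as_zero``, kept as percent rank 0 so
    they still dilute the mean). Zero overlap raises :class:`DataError`.
    """
    set_genes = list(set_genes)
    index = pr.gene_index()
    if case_insensitive:
        lower = {str(g).lower(): i for g, i in index.items()}
        found = [lower[str(g).lower()] for g in set_genes if str(g).lower() in lower]
        missing = [g for g in set_genes if str(g).lower() not in lower]
    else:
        found = [index[g] for g in set_genes if g in index]
        missing = [g for g in set_genes if g not in index]
    if not found:
        raise DataError(
            f"gene set {set_name!r} has no overlap with the expression matrix"
        )
    if missing:
        logger.warning(
            "gene set %r: %d of %d gene(s) absent from matrix, dropped: %s",
            set_name, len(missing), len(set_genes), ", ".join(map(str, missing[:20])),
        )
    m = len(set_genes) if missing_as_zero else len(found)
    scores = np.asarray(pr.values[found, :].sum(axis=0)).ravel() / m
    return scores, m


def score_collection(
    lognorm: ExpressionMatrix,
    collection: GeneSetCollection,
    missing_as_zero: bool = False,
    case_insensitive: bool = False,
    allow_raw: bool = False,
) -> ScoreTable:
    """Score every set in a collection; one percent-rank pass, shared by all.

    Sets with zero overlap are dropped with a warning and recorded in
    ``ScoreTable.dropped_sets``; if every set drops, :class:`DataError`.
    Output ordering is deterministic: sets in collection order, cells in
    matrix order.
    """
    if len(collection) == 0:
        raise DataError("empty gene set collection")
    pr = percent_rank(lognorm, allow_raw=allow_raw)
    cols, names, genes_used, dropped = [], [], {}, []
    for name in collection.names():
        try:
            scores, m = score_gene_set(
                pr, collection.sets[name], set_name=name,
                missing_as_zero=missing_as_zero, case_insensitive=case_insensitive,
            )
        except DataError:
            logger.warning("gene set %r dropped: no genes found in matrix", name)
            dropped.append(name)
            continue
        cols.append(scores)
        names.append(name)
        genes_used[name] = m
    if not names:
        raise DataError("all gene sets were dropped (no overlap with matrix)")
    return ScoreTable(
        scores=np.column_stack(cols),
        cell_ids=lognorm.cell_ids,
        set_names=names,
        genes_used=genes_used,
        dropped_sets=dropped,
    )
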