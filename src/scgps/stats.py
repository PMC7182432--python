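"""Two-group comparisons: rank-sum tests, BH correction, marker detection.

The Wilcoxon rank-sum (Mann–Whitney U) test is used in two places, mirroring
the analysis shape the scoring statistic was built for:

* ``compare_scores`` — compare per-cell module scores between clusters
  (one-vs-rest) or between genotypes within each cluster (e.g. wild-type vs
  knockout in a given cell state), two-sided, BH-adjusted.
* ``find_markers`` — one-vs-rest marker-gene detection per cluster on
  log-normalized expression, with percent-expressed and log-fold-change
  pre-filters.

Small tie-free samples use the exact permutation distribution of U; larger
or tied samples use the tie-corrected normal approximation with continuity
correction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

from ._errors import DataError
from .types import LOGNORM, CellTable, ExpressionMatrix, ScoreTable

logger = logging.getLogger("scgps")

#: designs understood by :func:`compare_scores`
BY_CLUSTER = "by_cluster_one_vs_rest"
BY_GENOTYPE = "by_genotype_within_cluster"

RESULT_COLUMNS = [
    "unit", "group_a", "group_b", "n_a", "n_b",
    "statistic", "effect", "p_value", "p_adjusted",
]


@dataclass
class ComparisonResult:
    """One two-group contrast for one unit (gene set or gene)."""

    unit: str
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    statistic: float
    effect: float
    p_value: float
    p_adjusted: float = np.nan


def results_to_frame(results) -> pd.DataFrame:
    """Results as a DataFrame with the fixed export column order."""
    if not results:
        return pd.DataFrame(columns=RESULT_COLUMNS)
    return pd.DataFrame([asdict(r) for r in results])[RESULT_COLUMNS]


def rank_sum_test(
    values_a,
    values_b,
    exact_threshold: int = 16,
    alternative: str = "two-sided",
):
    """Mann–Whitney U test; returns (U statistic for group a, p value).

    Uses exact enumeration of the permutation distribution of U when
    n_a + n_b ≤ `exact_threshold` and there are no ties; otherwise the
    tie-corrected normal approximation with continuity correction. Fully
    tied data (all values equal) is degenerate: U sits at its null mean and
    p = 1.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise DataError("rank_sum_test requires non-empty groups")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return a.size * b.size / 2.0, 1.0
    has_ties = len(np.unique(pooled)) < pooled.size
    if (a.size + b.size) <= exact_threshold and not has_ties:
        res = mannwhitneyu(a, b, alternative=alternative, method="exact")
    else:
        res = mannwhitneyu(
            a, b, alternative=alternative, method="asymptotic", use_continuity=True
        )
    return float(res.statistic), float(min(res.pvalue, 1.0))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p values, in input order.

    p_(i) is multiplied by m/i, monotonicity enforced from the largest rank
    down, capped at 1. Values outside [0, 1] raise :class:`DataError`.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(np.isnan(p)) or p.min() < 0 or p.max() > 1:
        raise DataError("p values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _attach_bh(results, within: str = "unit"):
    """BH-adjust in place, within groups of the given attribute."""
    if not results:
        return results
    keys = {getattr(r, within) for r in results}
    for key in keys:
        idx = [i for i, r in enumerate(results) if getattr(r, within) == key]
        adj = bh_adjust([results[i].p_value for i in idx])
        for i, q in zip(idx, adj):
            results[i].p_adjusted = float(q)
    return results


def compare_scores(
    scores: ScoreTable,
    cells: CellTable,
    design: str = BY_CLUSTER,
    exact_threshold: int = 16,
    alternative: str = "two-sided",
):
    """Compare module scores between groups of cells.

    Designs:

    * ``by_cluster_one_vs_rest`` — for each set and each cluster, cells in the
      cluster vs all other cells.
    * ``by_genotype_within_cluster`` — for each set and each cluster, first
      genotype level vs second (exactly two genotype levels required);
      clusters missing a genotype are skipped with a warning.

    Effect is the difference of group mean scores (group_a − group_b). BH is
    applied within each gene set across its contrasts. Ordering is
    deterministic: sets in table order, groups in first-appearance order.
    """
    cluster = cells.labels_for(scores.cell_ids, "cluster")
    results: list = []
    if design == BY_CLUSTER:
        levels = list(pd.unique(cluster))
        if len(levels) < 2:
            raise DataError("one-vs-rest comparison needs at least 2 clusters")
        for j, name in enumerate(scores.set_names):
            col = scores.scores[:, j]
            for lv in levels:
                mask = cluster == lv
                results.append(_contrast(name, str(lv), "rest", col[mask], col[~mask],
                                         exact_threshold, alternative))
    elif design == BY_GENOTYPE:
        genotype = cells.labels_for(scores.cell_ids, "genotype")
        glevels = list(pd.unique(genotype))
        if len(glevels) != 2:
            raise DataError(
                f"genotype comparison needs exactly 2 genotype levels, got {glevels}"
            )
        ga, gb = glevels
        for j, name in enumerate(scores.set_names):
            col = scores.scores[:, j]
            for lv in pd.unique(cluster):
                in_cl = cluster == lv
                va = col[in_cl & (genotype == ga)]
                vb = col[in_cl & (genotype == gb)]
                if va.size == 0 or vb.size == 0:
                    logger.warning(
                        "cluster %r skipped for set %r: a genotype group is empty",
                        lv, name,
                    )
                    continue
                results.append(_contrast(f"{name}", f"{ga}|{lv}", f"{gb}|{lv}",
                                         va, vb, exact_threshold, alternative))
        if not results:
            raise DataError("no cluster had both genotype groups populated")
    else:
        raise DataError(f"unknown design {design!r}")
    return _attach_bh(results, within="unit")


def _contrast(unit, ga, gb, va, vb, exact_threshold, alternative) -> ComparisonResult:
    stat, p = rank_sum_test(va, vb, exact_threshold=exact_threshold,
                            alternative=alternative)
    return ComparisonResult(
        unit=unit, group_a=ga, group_b=gb, n_a=int(va.size), n_b=int(vb.size),
        statistic=stat, effect=float(va.mean() - vb.mean()), p_value=p,
    )


def find_markers(
    lognorm: ExpressionMatrix,
    cells: CellTable,
    min_pct: float = 0.1,
    min_effect: float = 0.25,
    exact_threshold: int = 16,
    alternative: str = "two-sided",
):
    """One-vs-rest rank-sum marker detection per cluster.

    For each cluster, genes are pre-filtered: expressed (value > 0) in at
    least `min_pct` of either group, and |log-fold-change| ≥ `min_effect`,
    where the log-fold-change is ln((mean(expm1 x_in) + 1) /
    (mean(expm1 x_out) + 1)) — i.e. fold change of de-logged mean expression
    with a pseudocount of 1. Passing genes are tested, BH-adjusted across
    genes within the cluster, and sorted by p value then decreasing effect.
    """
    if lognorm.layer != LOGNORM:
        raise DataError("find_markers expects a log-normalized matrix")
    labels = cells.labels_for(lognorm.cell_ids, "cluster")
    levels = list(pd.unique(labels))
    if len(levels) < 2:
        raise DataError("marker detection needs at least 2 clusters")
    X = lognorm.values.tocsr()
    dense = np.asarray(X.todense())
    expm1 = np.expm1(dense)
    results: list = []
    for lv in levels:
        mask = labels == lv
        n_in, n_out = mask.sum(), (~mask).sum()
        pct_in = (dense[:, mask] > 0).sum(axis=1) / n_in
        pct_out = (dense[:, ~mask] > 0).sum(axis=1) / n_out
        lfc = np.log(
            (expm1[:, mask].mean(axis=1) + 1.0)
            / (expm1[:, ~mask].mean(axis=1) + 1.0)
        )
        keep = (np.maximum(pct_in, pct_out) >= min_pct) & (np.abs(lfc) >= min_effect)
        cluster_res = []
        for g in np.flatnonzero(keep):
            stat, p = rank_sum_test(
                dense[g, mask], dense[g, ~mask],
                exact_threshold=exact_threshold, alternative=alternative,
            )
            cluster_res.append(ComparisonResult(
                unit=str(lognorm.gene_ids[g]), group_a=str(lv), group_b="rest",
                n_a=int(n_in), n_b=int(n_out), statistic=stat,
                effect=float(lfc[g]), p_value=p,
            ))
        if cluster_res:
            adj = bh_adjust([r.p_value for r in cluster_res])
            for r, q in zip(cluster_res, adj):
                r.p_adjusted = float(q)
            cluster_res.sort(key=lambda r: (r.p_value, -r.effect))
        results.extend(cluster_res)
    return results
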