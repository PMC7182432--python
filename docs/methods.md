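# Methods

## The score

scGPS (single-cell Geneset Percentile Score) summarizes, per cell, where a
gene module's expression sits relative to the rest of the dataset. For each
gene independently, every cell's log-normalized value is ranked against all
N cells, tied values all taking the **lowest** rank of their block
(rank = 1 + number of strictly smaller values). Ranks are rescaled to [0, 1]
as (rank − 1)/(N − 1), and a module's score for a cell is the mean rescaled
rank of its genes. The interpretation is percentile-like: a score of p means
the module's mean expression is at the p-th percentile for that cell.

Two consequences of the tie rule are worth keeping in mind:

* a gene that is zero (or constant) in every cell contributes exactly 0 to
  every cell's score — unexpressed module genes pull scores down rather than
  adding noise;
* in sparse UMI data the zero block is usually large, so the lowest-rank
  rule makes scores conservative: a cell must express a module gene at all
  before that gene can contribute anything above 0.

**Scaling choice.** Rescaling by (rank − 1)/(N − 1) rather than rank/N is
the single most consequential interpretation made here: it maps the lowest
value to exactly 0 and a unique maximum to exactly 1, and matches the
standard percent-rank definition in the dplyr/pandas ecosystem. The test
suite pins this choice so any future change is visible.

**Missing module genes.** m counts only module genes present in the matrix
(drop-and-renormalize, with a warning and the per-set m recorded in
outputs). The alternative — treating a missing gene as percent rank 0 so it
dilutes the mean — is available via `missing_as_zero` but off by default:
missing features usually reflect annotation mismatch between the gene-set
namespace and the matrix, not absence of expression. Gene matching is exact
and case-sensitive by default (`case_insensitive` flag available), because
silent case-folding across species conventions (e.g. mouse *Foxj1* vs human
*FOXJ1*) hides real mismatches.

**Population choice.** Ranks are computed over whatever cell population is
passed in. Scoring a subset (one stage, one compartment) changes the
reference distribution and therefore the scores; subsetting is deliberately
left to the caller rather than hidden behind options.

**Computation.** Values are non-negative, so whenever a gene has any zero,
zero is its minimum and the whole zero block takes percent rank 0 exactly.
Ranks therefore only need computing over each gene's nonzero entries
(`n_zero + within-nonzero rank`), keeping the pass sparse. A literal
O(G·N²) implementation of the definition lives in the test suite and the
vectorized path is required to match it bit for bit on randomized fixtures
with engineered tie blocks.

## Normalization and summaries

`normalize_log` maps count(g, c) to ln(1 + count · s / total(c)) with
s = 10,000 by default — the de facto convention for "normalized and
log-transformed" scRNA-seq values; both the scale factor and (via the rank
invariance of the score) the log base are inconsequential for scGPS itself,
but the values are also used directly for marker detection and summaries.
Cells with zero total counts have no defined scaling and are rejected by
name. Zeros map to zeros, preserving sparsity.

`cluster_summary` produces the three statistics dot plots and heat maps are
built from: per-cluster mean of log-normalized values, fraction of cells
with value > 0 ("expressing", equivalently raw count ≥ 1), and the
per-gene z-score of cluster means across clusters. z-scoring uses the
sample SD (n − 1); genes with zero variance across clusters get z = 0
rather than NaN so downstream displays render.

## Group comparisons

Two-group location tests are unpaired two-sided Wilcoxon rank-sum
(Mann–Whitney U), the standard nonparametric choice for skewed, tied,
zero-inflated expression data. For pooled sizes ≤ 16 without ties the exact
permutation distribution of U is used; otherwise the tie-corrected normal
approximation with continuity correction. The exact path is checked against
exhaustive enumeration of all labelings; the approximation's worst-case
deviation from exact over all tie-free splits with pooled size ≤ 16 is
0.0375 (at 3 vs 3) and < 0.03 once both groups have ≥ 5 members — tests pin
these bounds. Fully tied inputs are degenerate and return p = 1. One-sided
alternatives are available by flag.

Effect sizes: for module scores, the difference of group means (scores
already share the [0, 1] scale); for expression, the log-fold-change of
de-logged group means, ln((mean expm1 + 1)/(mean expm1 + 1)), the pseudocount
keeping the effect finite when a gene is absent from one group.

Multiple testing uses Benjamini–Hochberg step-up FDR control — applied
within each gene set across its contrasts in `compare_scores`, and within
each cluster across genes in `find_markers`. `find_markers` pre-filters
genes (expressed in ≥ 10% of either group, |LFC| ≥ 0.25 by default) before
testing, the usual practice to keep the test count and FDR denominator
meaningful; both filters can be set to 0 to test everything.

## The synthetic generator

`simulate_counts` emulates the features of droplet UMI data that the
pipeline is sensitive to, and nothing more:

* **gene baselines** μ_g ~ LogNormal(−1.5, 1.0) — median ~0.22 expected
  UMI per gene per cell, spanning roughly 0.01–5 across genes, a realistic
  spread for a few-thousand-UMI-per-cell experiment;
* **depth variation** d_c ~ LogNormal(0, 0.35) — roughly ±40% per-cell
  library-size variation;
* **counting noise** negative binomial with shared size r = 2 (variance
  μ + μ²/2), a typical overdispersion level for UMI counts; per-gene
  dispersion is deliberately not modeled;
* **planted signal** a module's genes have their mean multiplied by a
  fold change (default modules: one 50-gene module, 4-fold) in a target
  cluster; fold change 1 plants nothing and is the null. Optional
  per-genotype overrides within the target cluster make wild-type vs
  knockout contrasts plantable.

All draws flow from one seed in a fixed order (gene baselines, module gene
assignment, genotype labels, depth factors, counts), so a config reproduces
its matrix bit-exactly. Default problem sizes (2,000 genes, three clusters
of 300 cells for recovery; 150 genes × 200 cells × 200 replicates for null
calibration) are chosen so the full suite runs comfortably on a laptop
while leaving the planted effect and the calibration estimate far from
their decision boundaries.

What the generator does **not** model — doublets, ambient RNA, batch
effects, zero inflation beyond NB sparsity, continuous trajectories,
cluster-specific library sizes — bounds what passing tests show: they
demonstrate that the statistic and its comparisons behave as designed under
clean cluster structure, not that they are robust to every artifact of real
data. In particular, ambient contamination shared across clusters would
shift all scores together (rank-based scoring absorbs this), while strong
batch structure confounded with the grouping would not be corrected here.

## Numerical and design notes

* Matrix Market indices are 1-based on disk, 0-based in memory; the
  boundary lives entirely in the I/O module. Duplicate gene identifiers on
  ingest are collapsed by summation (deterministic and order-independent;
  one identifier must map to one row for identifier-driven scoring), with a
  warning naming the identifiers.
* Score TSVs are written at full repr precision, so write-then-read is
  bit-exact.
* Output ordering is deterministic everywhere: sets in collection order,
  cells in matrix order, contrasts in first-appearance group order; CLI
  writes are atomic (temp file + rename) so failed runs leave no partial
  files.
* Percent rank requires N ≥ 2; single-cell inputs are rejected rather than
  given an arbitrary score.

## Limitations

* scGPS is non-competitive: it does not compare a module against matched
  background sets, so modules of broadly expressed genes score high
  everywhere. Interpretation is relative across cells, not across modules
  of different sizes and expression regimes.
* Small modules inherit the rank granularity of their genes; with heavy
  sparsity the score distribution is strongly discrete.
* The rank-sum comparisons treat cells as exchangeable units; they make no
  allowance for per-sample (pseudoreplication) structure.
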