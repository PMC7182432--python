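"""Synthetic UMI count matrices with planted co-regulated gene modules.

The generator emulates the structure a droplet scRNA-seq count matrix needs
for the scoring pipeline to be exercisable end to end: discrete cell clusters,
gene modules upregulated in a target cluster by a known fold change, negative
binomial counting noise with shared overdispersion, and lognormal variation
in per-cell sequencing depth.

Model, for gene g in cell c:

    mu_g ~ LogNormal(base_mean_log_mu, base_mean_log_sigma)   (gene baseline)
    d_c  ~ LogNormal(0, libsize_log_sigma)                    (cell depth)
    E[count] = mu_g * d_c * FC(g, c)
    count ~ NegativeBinomial(mean = E[count], size = dispersion)

FC(g, c) is the module fold change when g belongs to a module targeting
cluster(c) (optionally overridden per genotype), else 1. The NB size
parameter r gives variance mu + mu^2 / r; large r approaches Poisson.

All randomness flows from the single seed in a fixed draw order (gene
baselines, module gene assignment, genotype labels, depth factors, counts),
so a config reproduces its counts bit-exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml
from scipy import sparse

from ._errors import ConfigError
from .types import RAW_COUNTS, CellTable, ExpressionMatrix, GeneSetCollection


@dataclass
class ModuleSpec:
    """A planted co-regulated gene module.

    fold_change multiplies the baseline mean of the module's genes in cells
    of `target_cluster` (fold_change = 1 plants no signal — the null).
    `genotype_fold_changes`, if given, overrides fold_change for cells of the
    named genotype within the target cluster, so wild-type-vs-mutant
    contrasts can be planted.
    """

    name: str
    n_genes: int
    target_cluster: str
    fold_change: float = 1.0
    genotype_fold_changes: dict = field(default_factory=dict)


@dataclass
class SimConfig:
    """Full parameterization of a synthetic dataset.

    Defaults describe a desk-scale dataset: 2,000 genes, three clusters of
    300 cells, gene baseline means lognormal around ~0.2 UMI, moderate
    overdispersion (NB size 2), ±40% depth variation, and one 50-gene module
    upregulated 4-fold in its target cluster.
    """

    n_genes: int = 2000
    n_cells_per_cluster: list = field(default_factory=lambda: [300, 300, 300])
    base_mean_log_mu: float = -1.5
    base_mean_log_sigma: float = 1.0
    dispersion: float = 2.0
    libsize_log_sigma: float = 0.35
    modules: list = field(default_factory=lambda: [
        ModuleSpec(name="module_1", n_genes=50, target_cluster="cluster_1",
                   fold_change=4.0),
    ])
    genotype_split: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        self.modules = [
            m if isinstance(m, ModuleSpec) else ModuleSpec(**m) for m in self.modules
        ]
        if self.n_genes < 1:
            raise ConfigError("n_genes must be >= 1")
        if not self.n_cells_per_cluster or any(n < 1 for n in self.n_cells_per_cluster):
            raise ConfigError("every cluster needs at least 1 cell")
        if self.dispersion <= 0:
            raise ConfigError("dispersion (NB size) must be > 0")
        if self.libsize_log_sigma < 0:
            raise ConfigError("libsize_log_sigma must be >= 0")
        if self.base_mean_log_sigma < 0:
            raise ConfigError("base_mean_log_sigma must be >= 0")
        total_module_genes = sum(m.n_genes for m in self.modules)
        if total_module_genes > self.n_genes:
            raise ConfigError(
                f"module gene counts sum to {total_module_genes} > n_genes={self.n_genes}"
            )
        clusters = set(self.cluster_names())
        for m in self.modules:
            if m.n_genes < 1:
                raise ConfigError(f"module {m.name!r}: n_genes must be >= 1")
            if m.fold_change < 1:
                raise ConfigError(f"module {m.name!r}: fold_change must be >= 1")
            if m.target_cluster not in clusters:
                raise ConfigError(
                    f"module {m.name!r}: target cluster {m.target_cluster!r} does not "
                    f"exist (clusters: {sorted(clusters)})"
                )
        if self.genotype_split is not None and not (0 < self.genotype_split < 1):
            raise ConfigError("genotype_split must lie strictly in (0, 1)")

    def cluster_names(self) -> list:
        return [f"cluster_{k + 1}" for k in range(len(self.n_cells_per_cluster))]


def load_sim_config(path) -> SimConfig:
    """Read a SimConfig from a YAML (or JSON — a YAML subset) file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: expected a mapping of SimConfig fields")
    try:
        return SimConfig(**raw)
    except TypeError as exc:
        raise ConfigError(f"{path}: {exc}") from exc


@dataclass
class SimTruth:
    """Ground truth for a simulated dataset (for recovery tests)."""

    cluster: np.ndarray            # per cell
    genotype: np.ndarray           # per cell
    module_genes: dict             # module name -> list of gene ids
    expected_mean: pd.DataFrame    # gene × cluster mean (mu_g * FC, WT depth 1)
    seed: int
    config: SimConfig


def simulate_counts(config: SimConfig):
    """Draw a count matrix from the config; returns (counts, cells, truth)."""
    rng = np.random.default_rng(config.seed)
    G = config.n_genes
    sizes = list(config.n_cells_per_cluster)
    N = int(sum(sizes))
    gene_ids = np.array([f"gene_{i + 1}" for i in range(G)], dtype=object)
    cell_ids = np.array([f"cell_{i + 1}" for i in range(N)], dtype=object)
    cluster_names = config.cluster_names()
    cluster = np.repeat(np.array(cluster_names, dtype=object), sizes)

    # draw order is fixed: baselines, module genes, genotypes, depths, counts
    mu = rng.lognormal(config.base_mean_log_mu, config.base_mean_log_sigma, size=G)

    available = np.arange(G)
    module_rows: dict = {}
    for mod in config.modules:
        pick = rng.choice(available.size, size=mod.n_genes, replace=False)
        module_rows[mod.name] = np.sort(available[pick])
        available = np.delete(available, np.sort(pick))

    if config.genotype_split is not None:
        genotype = np.where(rng.random(N) < config.genotype_split, "KO", "WT").astype(object)
    else:
        genotype = np.full(N, "WT", dtype=object)

    depth = rng.lognormal(0.0, config.libsize_log_sigma, size=N)

    fc = np.ones((G, N))
    for mod in config.modules:
        rows = module_rows[mod.name]
        in_target = cluster == mod.target_cluster
        fc[np.ix_(rows, in_target)] = mod.fold_change
        for geno, override in mod.genotype_fold_changes.items():
            sel = in_target & (genotype == geno)
            fc[np.ix_(rows, sel)] = override

    mean = mu[:, None] * depth[None, :] * fc
    r = config.dispersion
    counts = rng.negative_binomial(r, r / (r + mean))

    em = ExpressionMatrix(
        values=sparse.csr_matrix(counts), gene_ids=gene_ids, cell_ids=cell_ids,
        layer=RAW_COUNTS,
    )
    cells = CellTable(table=pd.DataFrame({
        "barcode": cell_ids, "cluster": cluster, "genotype": genotype,
    }))

    expected = np.tile(mu[:, None], (1, len(cluster_names)))
    for mod in config.modules:
        k = cluster_names.index(mod.target_cluster)
        expected[module_rows[mod.name], k] *= mod.fold_change
    truth = SimTruth(
        cluster=cluster, genotype=genotype,
        module_genes={name: list(gene_ids[rows]) for name, rows in module_rows.items()},
        expected_mean=pd.DataFrame(expected, index=gene_ids, columns=cluster_names),
        seed=config.seed, config=config,
    )
    return em, cells, truth


def make_true_gene_sets(truth: SimTruth) -> GeneSetCollection:
    """Planted modules as a GMT-compatible gene set collection."""
    if not truth.module_genes:
        raise ConfigError("simulation truth contains no modules")
    return GeneSetCollection(
        sets={name: list(genes) for name, genes in truth.module_genes.items()},
        descriptions={name: "planted synthetic module" for name in truth.module_genes},
    )


def config_to_dict(config: SimConfig) -> dict:
    """JSON/YAML-serializable form of a SimConfig (for run logs)."""
    d = asdict(config)
    return d
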