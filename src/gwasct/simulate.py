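"""Synthetic-data generators with planted ground truth.

Every input the pipeline consumes can be generated here: an annotated
single-nucleus count matrix with hierarchical cell labels and marker-gene
structure, GWAS summary statistics whose gene-level signal tracks the
specificity of a chosen target cell type, and colocalization loci drawn
under each of the five causal hypotheses.  All generators take an explicit
seed and use their own ``numpy.random.Generator``; there is no global
random state, and identical seeds give bit-identical outputs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .gtf import GeneModel

_AUTOSOMES = [str(c) for c in range(1, 23)]
_BASES = np.array(["A", "C", "G", "T"])


def _default_cell_types() -> list[tuple[str, str, str]]:
    # (supercluster, class) pairs loosely mirroring broad brain cell types:
    # two superclusters per class so both annotation levels are non-trivial.
    return [
        ("Microglia", "Immune"),
        ("Macrophage", "Immune"),
        ("Upper_layer_IT", "Excitatory"),
        ("Deep_layer_IT", "Excitatory"),
        ("MGE_interneuron", "Inhibitory"),
        ("CGE_interneuron", "Inhibitory"),
    ]


@dataclass
class ScSimConfig:
    """Configuration for the single-nucleus count simulator.

    ``cell_types`` lists (supercluster, class) label pairs; every
    supercluster belongs to exactly one class.  Counts follow a negative
    binomial with mean mu and variance mu + mu^2 / dispersion; marker genes
    of a type have mean mu * marker_fold_change in cells of that type.

    Sibling superclusters of the same class share part of each other's
    transcriptional program, as related brain cell types do: a type's
    markers are also upregulated in sibling cells by
    marker_fold_change ** class_marker_leak (0 = fully exclusive
    signatures, 1 = class-wide markers).
    """

    n_genes: int = 500
    n_cells_per_type: int = 100
    cell_types: list[tuple[str, str]] = field(default_factory=_default_cell_types)
    n_marker_genes_per_type: int = 25
    marker_fold_change: float = 5.0
    class_marker_leak: float = 0.5
    baseline_mean: float = 0.5
    dispersion: float = 2.0
    gene_length_range: tuple[int, int] = (2_000, 100_000)
    seed: int = 0

    def __post_init__(self) -> None:
        supers = [t[0] for t in self.cell_types]
        if len(set(supers)) != len(supers):
            raise ValueError("duplicate supercluster labels")
        if self.n_marker_genes_per_type * len(self.cell_types) > self.n_genes:
            raise ValueError("marker genes exceed total genes")
        if self.marker_fold_change < 1:
            raise ValueError("marker_fold_change must be >= 1")
        if self.baseline_mean <= 0 or self.dispersion <= 0:
            raise ValueError("baseline_mean and dispersion must be positive")
        if not (0.0 <= self.class_marker_leak <= 1.0):
            raise ValueError("class_marker_leak must be in [0, 1]")


@dataclass
class ScDataset:
    counts: np.ndarray          # gene x cell integer counts
    genes: list[str]
    cells: pd.DataFrame         # columns: cell_id, supercluster, class
    gene_models: list[GeneModel]
    truth_markers: dict[str, list[str]]  # supercluster -> marker gene ids


def simulate_sc_dataset(config: ScSimConfig) -> ScDataset:
    """Simulate an annotated gene x cell count matrix plus gene models.

    Per-gene baseline means are drawn log-normally around
    ``baseline_mean`` so libraries differ between genes, as in real
    snRNA-seq; marker genes of type t are upregulated by
    ``marker_fold_change`` in cells of t only.
    """
    rng = np.random.default_rng(config.seed)
    n_types = len(config.cell_types)
    genes = [f"G{i:05d}" for i in range(config.n_genes)]
    supers = [t[0] for t in config.cell_types]
    classes = {t[0]: t[1] for t in config.cell_types}

    marker_ids = rng.choice(
        config.n_genes, size=config.n_marker_genes_per_type * n_types, replace=False
    )
    truth = {
        sc: [genes[g] for g in marker_ids[i * config.n_marker_genes_per_type:(i + 1) * config.n_marker_genes_per_type]]
        for i, sc in enumerate(supers)
    }

    gene_base = config.baseline_mean * rng.lognormal(0.0, 0.5, size=config.n_genes)
    # mean matrix gene x type
    mu_type = np.tile(gene_base[:, None], (1, n_types))
    gene_row = {g: i for i, g in enumerate(genes)}
    sibling_fold = config.marker_fold_change ** config.class_marker_leak
    for i, sc in enumerate(supers):
        rows = [gene_row[g] for g in truth[sc]]
        mu_type[rows, i] *= config.marker_fold_change
        for j, other in enumerate(supers):
            if j != i and classes[other] == classes[sc]:
                mu_type[rows, j] *= sibling_fold

    n_cells = config.n_cells_per_type * n_types
    counts = np.empty((config.n_genes, n_cells), dtype=np.int64)
    cell_rows = []
    for i, sc in enumerate(supers):
        sl = slice(i * config.n_cells_per_type, (i + 1) * config.n_cells_per_type)
        mu = mu_type[:, i][:, None]
        size = config.dispersion
        p = size / (size + mu)
        counts[:, sl] = rng.negative_binomial(size, p, size=(config.n_genes, config.n_cells_per_type))
        for j in range(config.n_cells_per_type):
            cell_rows.append((f"{sc}_c{j:04d}", sc, classes[sc]))
    cells = pd.DataFrame(cell_rows, columns=["cell_id", "supercluster", "class"])

    gene_models = _simulate_gene_models(genes, config.gene_length_range, rng)
    return ScDataset(counts=counts, genes=genes, cells=cells,
                     gene_models=gene_models, truth_markers=truth)


def _simulate_gene_models(
    genes: list[str], length_range: tuple[int, int], rng: np.random.Generator
) -> list[GeneModel]:
    """Lay genes along the 22 autosomes with multi-exon transcripts."""
    models = []
    chrom_cursor = {c: 1_000_000 for c in _AUTOSOMES}
    chrom_cycle = itertools.cycle(_AUTOSOMES)
    for gid in genes:
        chrom = next(chrom_cycle)
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        start = chrom_cursor[chrom]
        end = start + length - 1
        chrom_cursor[chrom] = end + 200_000  # intergenic gap
        n_exons = int(rng.integers(1, 9))
        bounds = np.sort(rng.choice(np.arange(start, end), size=2 * n_exons, replace=False))
        exons = [(int(bounds[2 * k]), int(bounds[2 * k + 1])) for k in range(n_exons)]
        exons[0] = (start, exons[0][1])
        exons[-1] = (exons[-1][0], end)
        strand = "+" if rng.random() < 0.5 else "-"
        models.append(GeneModel(gene_id=gid, chrom=chrom, strand=strand,
                                tx_start=start, tx_end=end, exons=exons))
    return models


@dataclass
class GwasSimConfig:
    """Configuration for GWAS summary-statistic simulation.

    The gene-level signal for gene g is b * s_{g,t} where s is the
    specificity of g for the target cell type and b the enrichment slope;
    with no target the slope must be zero and every SNP z-score is an
    exact draw from MVN(0, R).
    """

    target_cell_type: str | None = None
    enrichment_slope: float = 0.0
    snps_per_gene_range: tuple[int, int] = (1, 10)
    ld_rho: float = 0.0
    sample_size: int = 100_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.target_cell_type is None and self.enrichment_slope != 0.0:
            raise ValueError("enrichment_slope must be 0 without a target cell type")
        if not (0.0 <= self.ld_rho < 1.0):
            raise ValueError("ld_rho must be in [0, 1)")


def ar1_matrix(n: int, rho: float) -> np.ndarray:
    """AR(1) correlation matrix R_ij = rho^|i-j| (positive definite for |rho|<1)."""
    idx = np.arange(n)
    return rho ** np.abs(idx[:, None] - idx[None, :])


def simulate_gwas_sumstats(
    gene_models: list[GeneModel],
    specificity: pd.DataFrame,
    config: GwasSimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate per-SNP GWAS summary statistics with per-gene planted signal.

    For each gene, m SNPs are placed inside the transcript span and their
    z-scores drawn as z = L @ eta + b * s_{g,t} * 1 with L the Cholesky
    factor of the AR(1) LD matrix.  The mean shift is broadcast
    identically to every SNP of the gene (scaling constant 1 per SNP): a
    fully shared signal, so the single-SNP case reduces exactly to the
    latent model z = b*s + eps with standard-normal eps.  Under a zero
    slope z is exactly MVN(0, R), making downstream gene p-values uniform.

    Returns (sumstats table, truth table of per-gene deterministic signal).
    """
    rng = np.random.default_rng(config.seed)
    if config.target_cell_type is not None:
        if config.target_cell_type not in specificity.columns:
            raise ValueError(f"unknown target cell type {config.target_cell_type!r}")
        sig = config.enrichment_slope * specificity[config.target_cell_type]
    else:
        sig = pd.Series(0.0, index=specificity.index)

    lo, hi = config.snps_per_gene_range
    rows = []
    truth_rows = []
    for gm in gene_models:
        if gm.gene_id not in sig.index:
            continue
        m = int(rng.integers(lo, hi + 1))
        shift = float(sig.loc[gm.gene_id])
        pos = np.sort(rng.choice(np.arange(gm.tx_start, gm.tx_end + 1), size=m, replace=False))
        if config.ld_rho == 0.0:
            z = rng.standard_normal(m) + shift
        else:
            L = np.linalg.cholesky(ar1_matrix(m, config.ld_rho))
            z = L @ rng.standard_normal(m) + shift
        maf = rng.uniform(0.05, 0.5, size=m)
        se = 1.0 / np.sqrt(2.0 * config.sample_size * maf * (1.0 - maf))
        beta = z * se
        p = 2.0 * stats.norm.sf(np.abs(z))
        a1 = rng.choice(4, size=m)
        a2 = (a1 + rng.integers(1, 4, size=m)) % 4
        for j in range(m):
            rows.append((
                f"rs{gm.chrom}_{pos[j]}", gm.chrom, int(pos[j]),
                _BASES[a1[j]], _BASES[a2[j]],
                beta[j], se[j], max(p[j], 5e-324), config.sample_size, maf[j],
            ))
        truth_rows.append((gm.gene_id, shift, m))

    sumstats = pd.DataFrame(
        rows, columns=["SNP", "CHR", "BP", "A1", "A2", "BETA", "SE", "P", "N", "MAF"]
    )
    truth = pd.DataFrame(truth_rows, columns=["gene_id", "signal", "n_snps"])
    return sumstats, truth


@dataclass
class ColocSimConfig:
    """One simulated locus under a named colocalization hypothesis.

    H0: neither trait associated; H1/H2: one trait only; H3: both traits,
    distinct causal SNPs; H4: both traits, one shared causal SNP.
    ``causal_effect_*`` are per-allele effect sizes; per-SNP standard
    errors follow SE = 1/sqrt(2 N maf (1-maf)).
    """

    scenario: str = "H0"
    n_snps: int = 100
    ld_rho: float = 0.5
    causal_effect_1: float = 0.05
    causal_effect_2: float = 0.05
    n1: int = 50_000
    n2: int = 50_000
    maf_range: tuple[float, float] = (0.05, 0.5)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scenario not in {"H0", "H1", "H2", "H3", "H4"}:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if self.scenario == "H3" and self.n_snps < 2:
            raise ValueError("H3 needs at least 2 SNPs")
        if not (0.0 <= self.ld_rho < 1.0):
            raise ValueError("ld_rho must be in [0, 1)")


def simulate_coloc_locus(
    config: ColocSimConfig,
    chrom: str = "1",
    start: int = 1_000_000,
    spacing: int = 1_000,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Simulate paired summary statistics for one locus.

    Marginal z-scores follow the standard summary-statistic model
    z_hat ~ MVN(R z_true, R) with R the AR(1) LD matrix and z_true the
    sparse causal vector (effect/SE at the causal SNP).  Returns the two
    locus tables plus a truth record naming the scenario and causal
    indices (empty sets under H0).
    """
    rng = np.random.default_rng(config.seed)
    m = config.n_snps
    maf = rng.uniform(config.maf_range[0], config.maf_range[1], size=m)
    pos = start + spacing * np.arange(m)
    R = ar1_matrix(m, config.ld_rho)
    L = np.linalg.cholesky(R + 1e-10 * np.eye(m))

    causal_1: list[int] = []
    causal_2: list[int] = []
    if config.scenario in {"H1", "H3", "H4"}:
        causal_1 = [int(rng.integers(0, m))]
    if config.scenario in {"H2", "H4"}:
        causal_2 = causal_1 if config.scenario == "H4" else [int(rng.integers(0, m))]
    if config.scenario == "H3":
        choices = [i for i in range(m) if i not in causal_1]
        causal_2 = [int(rng.choice(choices))]

    snp_ids = [f"rs{chrom}_{p}" for p in pos]
    a1 = rng.choice(4, size=m)
    a2 = (a1 + rng.integers(1, 4, size=m)) % 4
    tables = []
    for (n_samp, effect, causal) in (
        (config.n1, config.causal_effect_1, causal_1),
        (config.n2, config.causal_effect_2, causal_2),
    ):
        se = 1.0 / np.sqrt(2.0 * n_samp * maf * (1.0 - maf))
        z_true = np.zeros(m)
        for c in causal:
            z_true[c] = effect / se[c]
        z_hat = R @ z_true + L @ rng.standard_normal(m)
        beta = z_hat * se
        p = np.maximum(2.0 * stats.norm.sf(np.abs(z_hat)), 5e-324)
        tables.append(pd.DataFrame({
            "SNP": snp_ids, "CHR": chrom, "BP": pos,
            "A1": _BASES[a1], "A2": _BASES[a2],
            "BETA": beta, "SE": se, "P": p, "N": n_samp, "MAF": maf,
        }))
    truth = {"scenario": config.scenario, "causal_1": causal_1, "causal_2": causal_2}
    return tables[0], tables[1], truth
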