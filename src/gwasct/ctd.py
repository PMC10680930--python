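"""Cell-type specificity dataset (CTD) construction.

The CTD holds, per annotation level, the mean library-size-normalized
expression of every gene in every cell type and the derived specificity —
the proportion of a gene's summed mean expression attributable to each
type, so rows over cell types sum to one.  The linear enrichment mode
consumes the per-type specificity quantile bins; the top-10% mode consumes
the top-decile gene sets.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

DEFAULT_N_BINS = 40


@dataclass
class SpecificityMatrix:
    """Specificity data for one annotation level.

    ``mean_expr`` and ``specificity`` are gene x cell-type frames;
    ``quantile_bins`` holds integer bins 0..n_bins where bin 0 is reserved
    for zero-specificity genes and bins are monotone in specificity within
    each type.  ``zero_genes`` flags genes with no expression in any cell.
    """

    level: str
    mean_expr: pd.DataFrame
    specificity: pd.DataFrame
    quantile_bins: pd.DataFrame
    zero_genes: pd.Series
    n_bins: int = DEFAULT_N_BINS

    @property
    def genes(self) -> pd.Index:
        return self.specificity.index

    @property
    def cell_types(self) -> pd.Index:
        return self.specificity.columns

    def save(self, outdir: str) -> None:
        os.makedirs(outdir, exist_ok=True)
        self.mean_expr.to_csv(os.path.join(outdir, "mean_expr.tsv"), sep="\t")
        self.specificity.to_csv(os.path.join(outdir, "specificity.tsv"), sep="\t")
        self.quantile_bins.to_csv(os.path.join(outdir, "quantile_bins.tsv"), sep="\t")
        meta = {"level": self.level, "n_bins": self.n_bins,
                "n_zero_genes": int(self.zero_genes.sum())}
        with open(os.path.join(outdir, "meta.json"), "w") as fh:
            json.dump(meta, fh, indent=2)


def compute_specificity(
    counts: np.ndarray | pd.DataFrame,
    cells: pd.DataFrame,
    level: str,
    genes: list[str] | None = None,
    n_bins: int = DEFAULT_N_BINS,
) -> SpecificityMatrix:
    """Build the specificity matrix for one annotation level.

    Each cell is first scaled to unit library size, so sequencing-depth
    differences between cells cannot masquerade as type specificity; the
    per-type mean of the normalized profile then defines mean_expr, and
    specificity[g, t] = mean_expr[g, t] / sum_t' mean_expr[g, t'].  Genes
    expressed in no cell get an all-zero specificity row and are flagged.

    Within each type, genes with nonzero specificity are assigned to
    ``n_bins`` equal-size quantile bins (1 = least specific); bin 0 is
    reserved for zero-specificity genes.
    """
    if isinstance(counts, pd.DataFrame):
        genes = list(counts.index)
        mat = counts.to_numpy(dtype=float)
    else:
        mat = np.asarray(counts, dtype=float)
        if genes is None:
            genes = [f"G{i:05d}" for i in range(mat.shape[0])]
    if level not in cells.columns:
        raise ValueError(f"annotation level {level!r} not in cell table")
    labels = cells[level].to_numpy()
    types = list(pd.unique(labels))
    if len(types) < 2:
        raise ValueError(f"level {level!r} has fewer than 2 cell types")

    lib = mat.sum(axis=0)
    empty_cells = lib == 0
    if empty_cells.any():
        logger.warning("%d cells have zero counts; left as all-zero profiles",
                       int(empty_cells.sum()))
    norm = np.divide(mat, np.where(lib == 0, 1.0, lib)[None, :])

    mean_expr = np.empty((mat.shape[0], len(types)))
    for j, t in enumerate(types):
        mask = labels == t
        if not mask.any():
            raise ValueError(f"cell type {t!r} has no cells")
        mean_expr[:, j] = norm[:, mask].mean(axis=1)

    total = mean_expr.sum(axis=1)
    zero = total == 0
    spec = np.divide(mean_expr, np.where(zero, 1.0, total)[:, None])

    bins = np.zeros_like(spec, dtype=np.int64)
    for j in range(len(types)):
        col = spec[:, j]
        nz = col > 0
        n_nz = int(nz.sum())
        if n_nz:
            ranks = stats.rankdata(col[nz], method="average")
            bins[nz, j] = np.ceil(ranks * n_bins / n_nz).astype(np.int64).clip(1, n_bins)

    gene_index = pd.Index(genes, name="gene_id")
    return SpecificityMatrix(
        level=level,
        mean_expr=pd.DataFrame(mean_expr, index=gene_index, columns=types),
        specificity=pd.DataFrame(spec, index=gene_index, columns=types),
        quantile_bins=pd.DataFrame(bins, index=gene_index, columns=types),
        zero_genes=pd.Series(zero, index=gene_index, name="zero"),
        n_bins=n_bins,
    )


def top_decile_sets(spec: SpecificityMatrix, fraction: float = 0.10) -> dict[str, set[str]]:
    """Per-cell-type sets of genes in the top specificity decile.

    The candidate pool for a type is its genes with nonzero specificity;
    the set holds the top ``fraction`` of the pool, with boundary ties
    resolved by including every tied gene (the set may exceed 10%).
    """
    sets: dict[str, set[str]] = {}
    for t in spec.cell_types:
        col = spec.specificity[t]
        pool = col[col > 0]
        if pool.empty:
            sets[t] = set()
            continue
        k = max(1, int(np.floor(fraction * len(pool))))
        cutoff = np.sort(pool.to_numpy())[::-1][k - 1]
        chosen = pool[pool >= cutoff]
        if len(chosen) == len(pool):
            logger.warning("top-decile set for %s contains every gene (all tied)", t)
        sets[t] = set(chosen.index)
    return sets
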