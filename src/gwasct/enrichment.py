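"""Competitive cell-type enrichment of gene-level GWAS signal.

Two modes, mirroring the established cell-typing practice:

* **linear** — for each cell type, OLS of the gene z-score on that type's
  specificity quantile-bin covariate (scaled to [0, 1]) plus gene-level
  covariates; the slope answers "do genes more specific to this type carry
  more GWAS signal?".
* **top10** — OLS on a top-decile set-membership indicator instead of the
  full gradient.

Both report the slope, its analytic SE and the one-sided p for a positive
slope; ``bonferroni`` divides alpha by the family size and flags
significance with a strict inequality (p < alpha / n).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .ctd import SpecificityMatrix

logger = logging.getLogger(__name__)

DEFAULT_COVARIATES = ("log_n_snps", "gene_length", "log_gene_length", "n_snps")
MIN_SHARED_GENES = 30


@dataclass
class OlsFit:
    beta: float
    se: float
    p_one_sided: float
    degenerate: bool = False


def ols_one_sided(y: np.ndarray, x: np.ndarray, covariates: np.ndarray | None) -> OlsFit:
    """OLS slope of y on x adjusting for covariates; one-sided p for slope > 0.

    The design is [1, covariates, x]; the p-value is the upper tail of the
    t statistic of the x coefficient with n - p residual df.  A covariate
    design in which x is constant (or collinear with the covariates) is
    flagged degenerate with p = NaN rather than dropped.
    """
    n = len(y)
    parts = [np.ones((n, 1))]
    if covariates is not None and covariates.size:
        # standardize covariates for numerical stability; constant columns
        # are absorbed by the intercept and dropped.  The slope and SE of
        # x are invariant to affine transforms of the covariates.
        sd = covariates.std(axis=0)
        keep = sd > 0
        if keep.any():
            C = (covariates[:, keep] - covariates[:, keep].mean(axis=0)) / sd[keep]
            parts.append(C)
    parts.append(x[:, None])
    X = np.column_stack(parts)
    p = X.shape[1]
    if np.std(x) == 0 or n <= p:
        return OlsFit(np.nan, np.nan, np.nan, degenerate=True)
    xtx = X.T @ X
    try:
        xtx_inv = np.linalg.inv(xtx)
    except np.linalg.LinAlgError:
        return OlsFit(np.nan, np.nan, np.nan, degenerate=True)
    if np.linalg.cond(xtx) > 1e12:
        return OlsFit(np.nan, np.nan, np.nan, degenerate=True)
    coef = xtx_inv @ (X.T @ y)
    resid = y - X @ coef
    df = n - p
    s2 = float(resid @ resid) / df
    se = float(np.sqrt(s2 * xtx_inv[-1, -1]))
    beta = float(coef[-1])
    p_one = float(stats.t.sf(beta / se, df=df))
    return OlsFit(beta, se, p_one)


def _prepare(gene_table: pd.DataFrame, gene_index: pd.Index,
             covariate_list: tuple[str, ...]) -> tuple[pd.DataFrame, np.ndarray]:
    shared = gene_table[gene_table["gene_id"].isin(gene_index)]
    if len(shared) < MIN_SHARED_GENES:
        raise ValueError(
            f"only {len(shared)} genes shared between gene table and CTD "
            f"(need >= {MIN_SHARED_GENES})"
        )
    cov = shared[list(covariate_list)].to_numpy(dtype=float) if covariate_list else None
    return shared.reset_index(drop=True), cov


def linear_enrichment(
    gene_table: pd.DataFrame,
    spec: SpecificityMatrix,
    covariate_list: tuple[str, ...] = DEFAULT_COVARIATES,
    disease: str = "trait",
) -> pd.DataFrame:
    """Linear-mode enrichment for every cell type of one annotation level."""
    shared, cov = _prepare(gene_table, spec.genes, covariate_list)
    y = shared["gene_z"].to_numpy(dtype=float)
    rows = []
    for t in spec.cell_types:
        x = spec.quantile_bins.loc[shared["gene_id"], t].to_numpy(dtype=float) / spec.n_bins
        fit = ols_one_sided(y, x, cov)
        rows.append((disease, spec.level, "linear", t, fit.beta, fit.se,
                     fit.p_one_sided, fit.degenerate))
    return pd.DataFrame(rows, columns=["disease", "level", "mode", "cell_type",
                                       "beta", "se", "p", "degenerate"])


def top10_enrichment(
    gene_table: pd.DataFrame,
    gene_sets: dict[str, set[str]],
    covariate_list: tuple[str, ...] = DEFAULT_COVARIATES,
    level: str = "supercluster",
    disease: str = "trait",
) -> pd.DataFrame:
    """Top-decile-set enrichment: OLS on set membership per cell type."""
    shared = gene_table.reset_index(drop=True)
    if len(shared) < MIN_SHARED_GENES:
        raise ValueError(f"only {len(shared)} genes in gene table (need >= {MIN_SHARED_GENES})")
    cov = shared[list(covariate_list)].to_numpy(dtype=float) if covariate_list else None
    y = shared["gene_z"].to_numpy(dtype=float)
    rows = []
    for t, members in gene_sets.items():
        x = shared["gene_id"].isin(members).to_numpy(dtype=float)
        if x.sum() == 0 or x.sum() == len(x):
            rows.append((disease, level, "top10", t, np.nan, np.nan, np.nan, True))
            logger.warning("top10 set for %s is empty or spans every gene", t)
            continue
        fit = ols_one_sided(y, x, cov)
        rows.append((disease, level, "top10", t, fit.beta, fit.se,
                     fit.p_one_sided, fit.degenerate))
    return pd.DataFrame(rows, columns=["disease", "level", "mode", "cell_type",
                                       "beta", "se", "p", "degenerate"])


def bonferroni(results: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Attach alpha_corrected = alpha / n_tests and strict-< significance flags.

    The family is the set of rows passed in — one (disease, level, mode)
    combination by convention; the family size is echoed in the output so
    every run records what the correction divided by.
    """
    if results.empty:
        raise ValueError("empty result family")
    out = results.copy()
    n = len(out)
    out["n_tests"] = n
    out["alpha_corrected"] = alpha / n
    out["significant"] = out["p"] < out["alpha_corrected"]
    out.loc[out["p"].isna(), "significant"] = False
    return out
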