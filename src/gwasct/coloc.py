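"""Bayesian colocalization of GWAS loci with eQTL probes.

Per-SNP evidence is the Wakefield log approximate Bayes factor
lABF = 0.5 * (log(1 - r) + r * z^2) with r = W / (V + W), V the squared
standard error and W the prior effect variance.  Assuming at most one
causal variant per trait at the locus, the five-hypothesis posterior
(PP0..PP4: no association / trait 1 only / trait 2 only / both via
distinct variants / both via one shared variant) is accumulated in log
space with stable log-sum-exp.

``run_pairwise_coloc`` is the locus-iteration driver: genome-wide
significant autosomal GWAS SNPs (p <= 5e-8) are greedily clumped into
loci; at each locus every probe with at least one eQTL record at
p <= 1e-4 inside the window is tested marginally; results with
PP4 >= 0.90 are flagged as passing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from . import sumstats as ss

logger = logging.getLogger(__name__)


@dataclass
class ColocPriors:
    """Per-SNP prior probabilities: p1 (trait 1 causal), p2 (trait 2), p12 (shared)."""

    p1: float = 1e-4
    p2: float = 1e-4
    p12: float = 1e-5

    def __post_init__(self) -> None:
        for name in ("p1", "p2", "p12"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must be in (0,1)")
        if self.p1 + self.p2 + self.p12 >= 1.0:
            raise ValueError("p1 + p2 + p12 must be < 1")
        if self.p12 > min(self.p1, self.p2):
            logger.warning("p12 exceeds min(p1, p2); unusual prior, proceeding")


#: Default prior standard deviation of the causal effect: 0.15 on the
#: phenotype-SD scale for quantitative traits, 0.2 on log-odds for
#: case-control.
PRIOR_SD_QUANT = 0.15
PRIOR_SD_CC = 0.2


@dataclass
class ColocResult:
    gwas_trait: str
    probe_id: str
    n_snps: int
    pp: np.ndarray  # PP0..PP4
    lead_snp: str
    passes: bool
    locus: str = ""


def wakefield_labf(
    beta: np.ndarray | float,
    se: np.ndarray | float,
    prior_sd: float = PRIOR_SD_QUANT,
) -> np.ndarray | float:
    """Log approximate Bayes factor for association at one SNP (vectorized)."""
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise ValueError("standard errors must be positive")
    if prior_sd <= 0:
        raise ValueError("prior_sd must be positive")
    V = se ** 2
    W = prior_sd ** 2
    r = W / (V + W)
    z = beta / se
    out = 0.5 * (np.log1p(-r) + r * z ** 2)
    return out if out.ndim else float(out)


def coloc_posterior(
    labf1: np.ndarray,
    labf2: np.ndarray,
    priors: ColocPriors | None = None,
) -> np.ndarray:
    """Five-hypothesis posterior from per-SNP log Bayes factors.

    The H3 sum over distinct causal pairs is exp(L1 + L2) - exp(L12) with
    L1 = lse(labf1), L2 = lse(labf2), L12 = lse(labf1 + labf2); it is set
    to zero when only one SNP is present or when the difference is
    non-positive within floating tolerance.
    """
    priors = priors or ColocPriors()
    labf1 = np.asarray(labf1, dtype=float)
    labf2 = np.asarray(labf2, dtype=float)
    if labf1.shape != labf2.shape or labf1.ndim != 1:
        raise ValueError("labf vectors must be 1-D with equal length")
    n = labf1.size
    if n < 1:
        raise ValueError("need at least one SNP")
    for name, v in (("trait 1", labf1), ("trait 2", labf2)):
        bad = np.flatnonzero(~np.isfinite(v))
        if bad.size:
            raise ValueError(f"non-finite lABF for {name} at SNP index {bad[0]}")

    L1 = logsumexp(labf1)
    L2 = logsumexp(labf2)
    L12 = logsumexp(labf1 + labf2)
    log_h = np.empty(5)
    log_h[0] = 0.0
    log_h[1] = np.log(priors.p1) + L1
    log_h[2] = np.log(priors.p2) + L2
    a, b = L1 + L2, L12
    if n == 1 or b >= a - 1e-12:
        log_h[3] = -np.inf
    else:
        log_h[3] = np.log(priors.p1) + np.log(priors.p2) + a + np.log1p(-np.exp(b - a))
    log_h[4] = np.log(priors.p12) + L12
    pp = np.exp(log_h - logsumexp(log_h))
    return pp / pp.sum()


def clump_loci(
    sig: pd.DataFrame,
    radius: int = 500_000,
) -> list[pd.Series]:
    """Greedy clumping of significant SNPs into lead loci.

    SNPs are taken in order of ascending p; each lead absorbs all
    remaining significant SNPs within ``radius`` bp on its chromosome.
    """
    remaining = sig.sort_values("p").reset_index(drop=True)
    leads: list[pd.Series] = []
    while not remaining.empty:
        lead = remaining.iloc[0]
        leads.append(lead)
        close = (remaining["chrom"] == lead["chrom"]) & (
            (remaining["pos"] - lead["pos"]).abs() <= radius
        )
        remaining = remaining[~close].reset_index(drop=True)
    return leads


def run_pairwise_coloc(
    gwas: pd.DataFrame,
    eqtl: pd.DataFrame,
    window: int = 500_000,
    gwas_threshold: float = ss.GWAS_P_THRESHOLD,
    eqtl_threshold: float = ss.EQTL_P_THRESHOLD,
    pp4_threshold: float = 0.90,
    priors: ColocPriors | None = None,
    prior_sd_gwas: float = PRIOR_SD_QUANT,
    prior_sd_eqtl: float = PRIOR_SD_QUANT,
    clump_radius: int = 500_000,
    trait: str = "trait",
    allow_single_snp: bool = False,
) -> list[ColocResult]:
    """Colocalize every (GWAS locus, significant probe) pair.

    Pipeline: (1) significant lead SNPs = autosomal GWAS records at
    p <= ``gwas_threshold``, greedily clumped by distance; (2) per locus,
    every probe with >= 1 eQTL record at p <= ``eqtl_threshold`` within
    the window is tested marginally; (3) SNPs are matched by snp_id (the
    posterior depends on z only through z^2, so allele flips do not change
    it); (4) pairs sharing < 2 SNPs are skipped with a logged reason
    unless ``allow_single_snp``.
    """
    priors = priors or ColocPriors()
    sig = ss.filter_significant(gwas, gwas_threshold, side="gwas")
    if sig.empty:
        logger.info("no genome-wide significant autosomal GWAS SNP; nothing to colocalize")
        return []
    leads = clump_loci(sig, clump_radius)
    results: list[ColocResult] = []
    eqtl_by_probe = dict(tuple(eqtl.groupby("probe_id")))
    for lead in leads:
        locus_id = f"{lead['chrom']}:{lead['pos']}"
        lo, hi = lead["pos"] - window, lead["pos"] + window
        gw = gwas[(gwas["chrom"] == lead["chrom"]) & gwas["pos"].between(lo, hi)]
        gw = gw.drop_duplicates("snp_id").set_index("snp_id")
        for probe_id, eq in eqtl_by_probe.items():
            eq_loc = eq[(eq["chrom"] == lead["chrom"]) & eq["pos"].between(lo, hi)]
            if eq_loc.empty or eq_loc["p"].min() > eqtl_threshold:
                continue
            eq_loc = eq_loc.drop_duplicates("snp_id").set_index("snp_id")
            shared = gw.index.intersection(eq_loc.index)
            if len(shared) < 2 and not (allow_single_snp and len(shared) == 1):
                logger.info("locus %s x probe %s skipped: %d shared SNPs",
                            locus_id, probe_id, len(shared))
                continue
            g = gw.loc[shared]
            e = eq_loc.loc[shared]
            labf1 = np.asarray(wakefield_labf(g["beta"].to_numpy(), g["se"].to_numpy(), prior_sd_gwas))
            labf2 = np.asarray(wakefield_labf(e["beta"].to_numpy(), e["se"].to_numpy(), prior_sd_eqtl))
            pp = coloc_posterior(labf1, labf2, priors)
            lead_snp = shared[int(np.argmax(labf1 + labf2))]
            results.append(ColocResult(
                gwas_trait=trait, probe_id=str(probe_id), n_snps=len(shared),
                pp=pp, lead_snp=str(lead_snp), passes=bool(pp[4] >= pp4_threshold),
                locus=locus_id,
            ))
    return results


def results_to_frame(results: list[ColocResult]) -> pd.DataFrame:
    rows = [
        (r.gwas_trait, r.locus, r.probe_id, r.n_snps, *r.pp, r.lead_snp, r.passes)
        for r in results
    ]
    return pd.DataFrame(rows, columns=[
        "trait", "locus", "probe_id", "n_snps",
        "PP0", "PP1", "PP2", "PP3", "PP4", "lead_snp", "passes",
    ])
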