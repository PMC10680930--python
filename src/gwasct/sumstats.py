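"""Reading, harmonizing and quality-controlling summary statistics.

GWAS and cis-eQTL association tables arrive with heterogeneous headers;
``munge_sumstats`` resolves them against an editable synonym dictionary,
applies the QC filters, derives z = beta/se where absent and returns a
harmonized table plus a per-reason drop-count report.  ``filter_significant``
applies the inclusive significance thresholds used for locus selection
(p <= 5e-8 on the GWAS side, autosomes only; p <= 1e-4 on the eQTL side).
"""

from __future__ import annotations

import gzip
import json
import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

GWAS_P_THRESHOLD = 5e-8
EQTL_P_THRESHOLD = 1e-4

#: Header synonyms, lower-cased; edit or extend via the ``column_map``
#: argument of :func:`munge_sumstats`.
COLUMN_SYNONYMS: dict[str, list[str]] = {
    "snp_id": ["snp", "snp_id", "rsid", "rs_id", "markername", "variant_id", "id"],
    "chrom": ["chr", "chrom", "chromosome", "#chr", "#chrom"],
    "pos": ["bp", "pos", "position", "base_pair_location", "bp_hg19", "bp_hg38"],
    "effect_allele": ["a1", "effect_allele", "ea", "allele1", "alt"],
    "other_allele": ["a2", "other_allele", "oa", "nea", "allele2", "ref"],
    "beta": ["beta", "b", "effect", "log_odds", "logor"],
    "or": ["or", "odds_ratio"],
    "se": ["se", "standard_error", "stderr", "sebeta"],
    "p": ["p", "pval", "p_value", "pvalue", "p_val", "p.value"],
    "n": ["n", "samplesize", "sample_size", "neff", "n_total"],
    "maf": ["maf", "eaf", "frq", "freq", "effect_allele_frequency", "af"],
    "z": ["z", "zscore", "z_score", "stat"],
    "probe_id": ["probe", "probe_id", "gene", "gene_id", "phenotype_id", "feature"],
}

_ACGT = frozenset("ACGT")
_AMBIGUOUS_PAIRS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


class SumstatsFormatError(ValueError):
    """Raised when mandatory columns cannot be resolved."""


class EmptySumstatsError(ValueError):
    """Raised when QC removes every row."""


def read_table(path: str) -> pd.DataFrame:
    """Read a delimited text table, sniffing tab/comma/whitespace and gzip."""
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        header = fh.readline()
    sep = "\t" if "\t" in header else ("," if "," in header else r"\s+")
    return pd.read_csv(path, sep=sep)


def _resolve_columns(columns, column_map: dict[str, str] | None) -> dict[str, str]:
    """Map canonical field -> actual column name, explicit mapping first."""
    lower = {c.lower(): c for c in columns}
    resolved: dict[str, str] = {}
    explicit = {k: v for k, v in (column_map or {}).items()}
    for canon, syns in COLUMN_SYNONYMS.items():
        if canon in explicit and explicit[canon] in columns:
            resolved[canon] = explicit[canon]
            continue
        for s in syns:
            if s in lower:
                resolved[canon] = lower[s]
                break
    return resolved


def munge_sumstats(
    raw: pd.DataFrame,
    column_map: dict[str, str] | None = None,
    require_alleles: bool = False,
    require_positions: bool = True,
) -> tuple[pd.DataFrame, dict]:
    """Harmonize a raw summary-statistics table.

    Rows are dropped (and counted in the returned QC report) for duplicate
    SNP ids (first kept), p outside (0, 1], non-positive SE, non-ACGT
    single-base alleles (only when ``require_alleles``) and missing
    chromosome/position (only when ``require_positions``).  Odds ratios
    are converted to log-odds; z is derived as beta/se where absent.
    Strand-ambiguous (A/T, C/G) pairs are flagged, not dropped.  Output is
    sorted by (chrom, pos).

    Returns ``(harmonized, qc_report)``.

    Raises
    ------
    SumstatsFormatError
        if no p-value column, or neither (beta, se) nor z, is resolvable.
    EmptySumstatsError
        if every row is removed by QC.
    """
    cols = _resolve_columns(raw.columns, column_map)
    if "p" not in cols:
        raise SumstatsFormatError("no p-value column resolvable")
    if "snp_id" not in cols:
        raise SumstatsFormatError("no SNP id column resolvable")
    if "beta" not in cols and "or" not in cols and "z" not in cols:
        raise SumstatsFormatError("need beta/OR with SE, or a z column")

    df = pd.DataFrame({"snp_id": raw[cols["snp_id"]].astype(str)})
    for canon in ("chrom", "effect_allele", "other_allele", "probe_id"):
        if canon in cols:
            df[canon] = raw[cols[canon]].astype(str)
    if "chrom" in df:
        df["chrom"] = df["chrom"].str.replace("^chr", "", regex=True)
    for canon in ("pos", "beta", "se", "p", "n", "maf", "z"):
        if canon in cols:
            df[canon] = pd.to_numeric(raw[cols[canon]], errors="coerce")
    if "beta" not in df and "or" in cols:
        df["beta"] = np.log(pd.to_numeric(raw[cols["or"]], errors="coerce"))

    report: dict[str, int | dict] = {"rows_in": int(len(df))}
    drops: dict[str, int] = {}

    # eQTL tables legitimately repeat a SNP across probes: the duplicate
    # key is (probe_id, snp_id) when a probe column is present
    dup_key = ["probe_id", "snp_id"] if "probe_id" in df else ["snp_id"]
    dup = df.duplicated(subset=dup_key, keep="first")
    drops["duplicate_snp_id"] = int(dup.sum())
    df = df[~dup]

    bad_p = ~((df["p"] > 0) & (df["p"] <= 1))
    drops["invalid_p"] = int(bad_p.sum())
    df = df[~bad_p]

    if "se" in df:
        bad_se = df["se"].notna() & (df["se"] <= 0)
        # rows carrying a z can survive a missing SE; non-positive SE is invalid
        drops["invalid_se"] = int(bad_se.sum())
        df = df[~bad_se]

    if require_alleles:
        if "effect_allele" not in df or "other_allele" not in df:
            raise SumstatsFormatError("allele columns required but not resolvable")
        ok = df["effect_allele"].str.fullmatch("[ACGT]") & df["other_allele"].str.fullmatch("[ACGT]")
        drops["invalid_alleles"] = int((~ok).sum())
        df = df[ok]

    if require_positions:
        if "chrom" not in df or "pos" not in df:
            raise SumstatsFormatError("chrom/pos required but not resolvable")
        missing = df["chrom"].isin(["nan", ""]) | df["pos"].isna()
        drops["missing_position"] = int(missing.sum())
        df = df[~missing]
        df["pos"] = df["pos"].astype(np.int64)

    if df.empty:
        raise EmptySumstatsError("all rows removed by QC")

    df = df.copy()
    if "z" not in df or df["z"].isna().any():
        if "beta" in df and "se" in df:
            derived = df["beta"] / df["se"]
            df["z"] = df["z"].fillna(derived) if "z" in df else derived
    if "effect_allele" in df and "other_allele" in df:
        df["ambiguous"] = [
            (a, b) in _AMBIGUOUS_PAIRS
            for a, b in zip(df["effect_allele"], df["other_allele"])
        ]

    if "chrom" in df:
        key = df["chrom"].map(_chrom_sort_key)
        df = df.assign(_k=key).sort_values(["_k", "pos"]).drop(columns="_k")
    df = df.reset_index(drop=True)

    report["drops"] = drops
    report["rows_out"] = int(len(df))
    for reason, k in drops.items():
        if k:
            logger.info("munge: dropped %d rows (%s)", k, reason)
    return df, report


def _chrom_sort_key(c: str) -> float:
    try:
        return float(int(c))
    except (TypeError, ValueError):
        return {"X": 23.0, "Y": 24.0, "MT": 25.0, "M": 25.0}.get(str(c).upper(), 26.0)


def filter_significant(records: pd.DataFrame, threshold: float, side: str) -> pd.DataFrame:
    """Keep records with p <= threshold (inclusive).

    On the GWAS side only autosomal records (chrom 1..22) are retained,
    matching locus selection for colocalization.
    """
    if side not in {"gwas", "eqtl"}:
        raise ValueError("side must be 'gwas' or 'eqtl'")
    out = records[records["p"] <= threshold]
    if side == "gwas":
        autosomes = {str(c) for c in range(1, 23)}
        out = out[out["chrom"].astype(str).isin(autosomes)]
    return out.reset_index(drop=True)


def write_qc_report(report: dict, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2)
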