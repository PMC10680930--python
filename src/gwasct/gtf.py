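"""Gene models and GTF input/output.

Coordinates are 1-based inclusive externally (GTF convention): a single
exon spanning 100-200 has length 101.  Any half-open arithmetic is kept
internal to the functions that need it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd


@dataclass
class GeneModel:
    """One gene: transcript span plus the exon intervals of all transcripts.

    ``exons`` holds (start, end) pairs, 1-based inclusive, possibly
    overlapping across transcripts; ``union_exon_length`` is the total
    length of the merged exon intervals (the maximal nonredundant,
    intron-removed extent of the gene).
    """

    gene_id: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    exons: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.tx_start > self.tx_end:
            raise ValueError(f"{self.gene_id}: tx_start > tx_end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")

    @property
    def length(self) -> int:
        """Transcript-span length in bp (inclusive coordinates)."""
        return self.tx_end - self.tx_start + 1

    @property
    def union_exon_length(self) -> int:
        return sum(e - s + 1 for s, e in merge_intervals(self.exons))


def merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of 1-based inclusive intervals; bookended intervals merge.

    Adjacent intervals such as (100, 200) and (201, 300) are contiguous in
    base space and collapse into (100, 300).
    """
    if not intervals:
        return []
    ordered = sorted(intervals)
    merged = [list(ordered[0])]
    for s, e in ordered[1:]:
        if s <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def write_gtf(gene_models: list[GeneModel], path: str, source: str = "gwasct") -> None:
    """Write gene/transcript/exon features, one transcript per gene."""
    rows = []
    for gm in gene_models:
        attr_g = f'gene_id "{gm.gene_id}";'
        attr_t = f'gene_id "{gm.gene_id}"; transcript_id "{gm.gene_id}.t1";'
        rows.append((gm.chrom, source, "gene", gm.tx_start, gm.tx_end, ".", gm.strand, ".", attr_g))
        rows.append((gm.chrom, source, "transcript", gm.tx_start, gm.tx_end, ".", gm.strand, ".", attr_t))
        for s, e in gm.exons:
            rows.append((gm.chrom, source, "exon", s, e, ".", gm.strand, ".", attr_t))
    with open(path, "w") as fh:
        for r in rows:
            fh.write("\t".join(str(x) for x in r) + "\n")


def read_gene_models(path: str) -> list[GeneModel]:
    """Read gene models from a GTF file.

    Uses pyranges for parsing; pyranges stores 0-based half-open
    coordinates internally, so starts are shifted back to 1-based here.
    Genes lacking exon records, or with exons on mixed chromosomes,
    raise ``ValueError``.
    """
    import pyranges

    df = pyranges.read_gtf(path).df
    df["Start"] = df["Start"] + 1  # back to 1-based inclusive
    genes: list[GeneModel] = []
    exon_df = df[df["Feature"] == "exon"]
    gene_df = df[df["Feature"] == "gene"]
    if gene_df.empty:
        # tolerate exon-only GTFs: infer spans from exons
        gene_df = (
            exon_df.groupby("gene_id")
            .agg(Chromosome=("Chromosome", "first"), Strand=("Strand", "first"),
                 Start=("Start", "min"), End=("End", "max"))
            .reset_index()
        )
    exon_groups = {g: sub for g, sub in exon_df.groupby("gene_id")}
    for row in gene_df.itertuples(index=False):
        gid = row.gene_id
        sub = exon_groups.get(gid)
        if sub is None or len(sub) == 0:
            raise ValueError(f"gene {gid} has no exon records")
        if sub["Chromosome"].nunique() > 1:
            raise ValueError(f"gene {gid} has exons on multiple chromosomes")
        genes.append(
            GeneModel(
                gene_id=str(gid),
                chrom=str(row.Chromosome),
                strand=str(row.Strand),
                tx_start=int(row.Start),
                tx_end=int(row.End),
                exons=[(int(s), int(e)) for s, e in zip(sub["Start"], sub["End"])],
            )
        )
    if not genes:
        raise ValueError(f"no gene models parsed from {path}")
    return genes


def gene_models_to_frame(gene_models: list[GeneModel]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in gene_models],
            "chrom": [g.chrom for g in gene_models],
            "strand": [g.strand for g in gene_models],
            "tx_start": [g.tx_start for g in gene_models],
            "tx_end": [g.tx_end for g in gene_models],
            "union_exon_length": [g.union_exon_length for g in gene_models],
        }
    )
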