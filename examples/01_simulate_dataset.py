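"""Generate a synthetic single-nucleus dataset with planted marker genes.

The simulator emulates an annotated brain snRNA-seq atlas at desk scale:
overdispersed (negative binomial) counts, two hierarchical annotation
levels (supercluster within class), per-type marker genes upregulated by
a known fold change, and GTF gene models with multi-exon transcripts.
"""

from gwasct import ScSimConfig, simulate_sc_dataset

cfg = ScSimConfig(n_genes=300, n_cells_per_type=50, seed=1)
ds = simulate_sc_dataset(cfg)

print(f"counts: {ds.counts.shape[0]} genes x {ds.counts.shape[1]} cells")
print(f"annotation levels: {list(ds.cells.columns[1:])}")
print(f"superclusters: {sorted(ds.cells['supercluster'].unique())}")
first_type = next(iter(ds.truth_markers))
print(f"planted markers for {first_type}: {ds.truth_markers[first_type][:5]} ...")
print(f"gene models: {len(ds.gene_models)}; first spans "
      f"{ds.gene_models[0].chrom}:{ds.gene_models[0].tx_start}-{ds.gene_models[0].tx_end} "
      f"with {len(ds.gene_models[0].exons)} exon(s)")
# The marker lists are the ground truth that downstream stages
# (specificity, enrichment) are expected to recover.
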