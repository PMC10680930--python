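import numpy as np
import pandas as pd
import pytest

from gwasct import ctd as ctd_mod
from gwasct import simulate as sim


@pytest.fixture(scope="session")
def sc_small() -> sim.ScDataset:
    """A small annotated dataset with planted markers (6 types, 3 classes)."""
    return sim.simulate_sc_dataset(
        sim.ScSimConfig(n_genes=240, n_cells_per_type=50, seed=11)
    )


@pytest.fixture(scope="session")
def spec_super(sc_small) -> ctd_mod.SpecificityMatrix:
    return ctd_mod.compute_specificity(
        sc_small.counts, sc_small.cells, "supercluster", genes=sc_small.genes
    )


@pytest.fixture(scope="session")
def null_gene_table(sc_small, spec_super) -> pd.DataFrame:
    """Gene-level association table from a null GWAS (no target cell type)."""
    from gwasct import gene_assoc as ga
    from gwasct import sumstats as ss

    raw, _ = sim.simulate_gwas_sumstats(
        sc_small.gene_models, spec_super.specificity,
        sim.GwasSimConfig(seed=5, snps_per_gene_range=(1, 5)),
    )
    rec, _ = ss.munge_sumstats(raw)
    return ga.gene_zscores(rec, sc_small.gene_models)


def toy_sumstats(rows: list[dict]) -> pd.DataFrame:
    """Build a harmonized-shape summary-statistics frame from dict rows."""
    base = {"snp_id": "rs1", "chrom": "1", "pos": 1000, "effect_allele": "A",
            "other_allele": "G", "beta": 0.1, "se": 0.05, "p": 0.5, "n": 10_000}
    out = []
    for i, r in enumerate(rows):
        rec = dict(base)
        rec["snp_id"] = f"rs{i+1}"
        rec["pos"] = 1000 + i
        rec.update(r)
        out.append(rec)
    df = pd.DataFrame(out)
    df["z"] = df["beta"] / df["se"]
    return df
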