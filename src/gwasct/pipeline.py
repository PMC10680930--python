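"""End-to-end orchestration: munge -> CTD -> gene association -> enrichment
-> colocalization -> expression summary, as one configured, logged run.

A run reads (or synthesizes) its inputs, executes the stages in order,
writes every intermediate as TSV into the run directory and records a
provenance JSON holding the full resolved configuration, the package
version and a content hash of every written table — so a rerun with the
same configuration and seed is bit-identical and verifiably so.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os

import numpy as np
import pandas as pd

from . import __version__
from . import coloc as cl
from . import ctd as ctd_mod
from . import enrichment as enr
from . import epr as epr_mod
from . import gene_assoc as ga
from . import simulate as sim
from . import sumstats as ss
from .gtf import write_gtf

logger = logging.getLogger(__name__)

DEFAULT_CONFIG = {
    "disease": "synthetic_trait",
    "seed": 0,
    "levels": ["supercluster", "class"],
    "modes": ["linear", "top10"],
    "alpha": 0.05,
    "n_bins": 40,
    "window": {"upstream": 35_000, "downstream": 10_000},
    "ld": {"provider": "identity", "rho": 0.0},
    "coloc": {
        "window": 500_000,
        "clump_radius": 500_000,
        "pp4_threshold": 0.90,
        "gwas_threshold": 5e-8,
        "eqtl_threshold": 1e-4,
        "priors": {"p1": 1e-4, "p2": 1e-4, "p12": 1e-5},
    },
    "epr": {"genes": "coloc_passes", "statistic": "mean"},
    "synthetic": None,
    "inputs": None,
}


def _merge(base: dict, override: dict | None) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _write(df: pd.DataFrame, path: str, hashes: dict) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
    hashes[os.path.basename(path)] = _sha256(path)


def _ld_provider(cfg: dict) -> ga.LdProvider:
    if cfg["provider"] == "identity":
        return ga.identity_ld
    if cfg["provider"] == "ar1":
        return ga.ar1_ld(float(cfg.get("rho", 0.0)))
    raise ValueError(f"unknown LD provider {cfg['provider']!r}")


def synthesize_inputs(config: dict, outdir: str, hashes: dict) -> dict:
    """Generate the full synthetic input bundle defined by config['synthetic'].

    Returns a dict with the in-memory objects every later stage consumes;
    serialized copies (GTF, sumstats TSV, counts, annotations, truth JSON)
    are written into ``outdir`` alongside.
    """
    syn = config["synthetic"]
    seed = int(config["seed"])
    sc_cfg = sim.ScSimConfig(**_merge({"seed": seed}, syn.get("sc")))
    ds = sim.simulate_sc_dataset(sc_cfg)

    spec_super = ctd_mod.compute_specificity(
        ds.counts, ds.cells, "supercluster", genes=ds.genes, n_bins=config["n_bins"]
    )
    gwas_cfg = sim.GwasSimConfig(**_merge({"seed": seed + 1}, syn.get("gwas")))
    gwas_raw, gwas_truth = sim.simulate_gwas_sumstats(
        ds.gene_models, spec_super.specificity, gwas_cfg
    )

    # Colocalization probes: each probe is one simulated locus; the planted
    # H4 probes are named after marker genes of the GWAS target type so the
    # expression summary of fine-mapped genes is meaningful downstream.
    coloc_cfg = dict(syn.get("coloc_loci") or {})
    n_probes = int(coloc_cfg.pop("n_probes", 0))
    n_h4 = int(coloc_cfg.pop("n_h4", 1 if n_probes else 0))
    eqtl_tables = []
    gwas_locus_tables = []
    truth_loci = []
    if n_probes:
        target = gwas_cfg.target_cell_type or list(ds.truth_markers)[0]
        probe_genes = ds.truth_markers[target][:n_probes]
        for i in range(n_probes):
            scenario = "H4" if i < n_h4 else "H0"
            locus_cfg = sim.ColocSimConfig(
                **_merge({"scenario": scenario, "seed": seed + 100 + i}, coloc_cfg)
            )
            # park loci on distinct chromosomes far beyond the gene territory
            chrom = str(1 + i % 22)
            t1, t2, truth = sim.simulate_coloc_locus(
                locus_cfg, chrom=chrom, start=400_000_000 + 10_000_000 * (i // 22)
            )
            probe = probe_genes[i] if i < len(probe_genes) else f"PROBE{i:03d}"
            t2 = t2.assign(PROBE=probe)
            gwas_locus_tables.append(t1)
            eqtl_tables.append(t2)
            truth_loci.append({"probe": probe, **truth})

    gwas_all = pd.concat([gwas_raw, *gwas_locus_tables], ignore_index=True)
    eqtl_all = (
        pd.concat(eqtl_tables, ignore_index=True)
        if eqtl_tables
        else pd.DataFrame(columns=["SNP", "CHR", "BP", "BETA", "SE", "P", "N", "PROBE"])
    )

    write_gtf(ds.gene_models, os.path.join(outdir, "genes.gtf"))
    hashes["genes.gtf"] = _sha256(os.path.join(outdir, "genes.gtf"))
    _write(gwas_all, os.path.join(outdir, "gwas_sumstats.tsv"), hashes)
    _write(eqtl_all, os.path.join(outdir, "eqtl_sumstats.tsv"), hashes)
    _write(ds.cells, os.path.join(outdir, "cell_annotations.tsv"), hashes)
    truth = {
        "markers": ds.truth_markers,
        "gwas_target": gwas_cfg.target_cell_type,
        "enrichment_slope": gwas_cfg.enrichment_slope,
        "coloc_loci": truth_loci,
    }
    with open(os.path.join(outdir, "truth.json"), "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
    hashes["truth.json"] = _sha256(os.path.join(outdir, "truth.json"))
    return {
        "dataset": ds,
        "gwas_raw": gwas_all,
        "eqtl_raw": eqtl_all,
        "gwas_truth": gwas_truth,
        "truth": truth,
    }


def run_pipeline(config: dict, outdir: str) -> dict:
    """Execute the full pipeline; returns a summary dict of key outputs.

    Stages run in order and halt on the first error, naming the stage;
    everything written so far stays in the run directory.
    """
    config = _merge(DEFAULT_CONFIG, config)
    os.makedirs(outdir, exist_ok=True)
    hashes: dict[str, str] = {}
    summary: dict = {}
    stage = "setup"
    try:
        stage = "inputs"
        if config["synthetic"] is not None:
            bundle = synthesize_inputs(config, outdir, hashes)
        else:
            raise NotImplementedError(
                "external-input runs: load tables with gwasct.io / gwasct.sumstats "
                "and call the stage functions directly, or provide a synthetic block"
            )
        ds = bundle["dataset"]

        stage = "munge"
        gwas, qc = ss.munge_sumstats(bundle["gwas_raw"])
        ss.write_qc_report(qc, os.path.join(outdir, "gwas_qc.json"))
        eqtl, eqc = (None, None)
        if not bundle["eqtl_raw"].empty:
            eqtl, eqc = ss.munge_sumstats(bundle["eqtl_raw"])
            ss.write_qc_report(eqc, os.path.join(outdir, "eqtl_qc.json"))

        stage = "ctd"
        specs = {
            level: ctd_mod.compute_specificity(
                ds.counts, ds.cells, level, genes=ds.genes, n_bins=config["n_bins"]
            )
            for level in config["levels"]
        }
        for level, spec in specs.items():
            spec.save(os.path.join(outdir, f"ctd_{level}"))

        stage = "gene_assoc"
        wcfg = config["window"]
        gene_table = ga.gene_zscores(
            gwas, ds.gene_models, ld=_ld_provider(config["ld"]),
            window=(int(wcfg["upstream"]), int(wcfg["downstream"])),
        )
        _write(gene_table, os.path.join(outdir, "gene_assoc.tsv"), hashes)

        stage = "enrichment"
        all_results = []
        for level, spec in specs.items():
            if "linear" in config["modes"]:
                res = enr.linear_enrichment(gene_table, spec, disease=config["disease"])
                all_results.append(enr.bonferroni(res, config["alpha"]))
            if "top10" in config["modes"]:
                sets = ctd_mod.top_decile_sets(spec)
                res = enr.top10_enrichment(
                    gene_table, sets, level=level, disease=config["disease"]
                )
                all_results.append(enr.bonferroni(res, config["alpha"]))
        enrich_table = pd.concat(all_results, ignore_index=True)
        _write(enrich_table, os.path.join(outdir, "enrichment.tsv"), hashes)

        stage = "coloc"
        coloc_table = pd.DataFrame()
        if eqtl is not None:
            ccfg = config["coloc"]
            results = cl.run_pairwise_coloc(
                gwas, eqtl,
                window=int(ccfg["window"]),
                gwas_threshold=float(ccfg["gwas_threshold"]),
                eqtl_threshold=float(ccfg["eqtl_threshold"]),
                pp4_threshold=float(ccfg["pp4_threshold"]),
                priors=cl.ColocPriors(**ccfg["priors"]),
                clump_radius=int(ccfg["clump_radius"]),
                trait=config["disease"],
            )
            coloc_table = cl.results_to_frame(results)
            _write(coloc_table, os.path.join(outdir, "coloc.tsv"), hashes)

        stage = "epr"
        epr_cfg = config["epr"]
        if epr_cfg["genes"] == "coloc_passes":
            genes_of_interest = (
                sorted(set(coloc_table[coloc_table["passes"]]["probe_id"]))
                if not coloc_table.empty else []
            )
            genes_of_interest = [g for g in genes_of_interest if g in ds.genes]
        else:
            genes_of_interest = list(epr_cfg["genes"])
        epr_table = pd.DataFrame()
        if genes_of_interest:
            nominated = sorted(
                set(enrich_table[enrich_table["significant"]
                                 & (enrich_table["level"] == "supercluster")]["cell_type"])
            ) or list(specs[config["levels"][0]].cell_types)
            lengths = epr_mod.exon_union_lengths(ds.gene_models)
            tpm = epr_mod.counts_to_tpm(ds.counts, lengths, genes=ds.genes)
            epr_table = epr_mod.epr_summary(
                tpm, ds.cells, genes_of_interest, nominated,
                level="supercluster", genes=ds.genes,
                class_statistic=epr_cfg["statistic"],
            )
            _write(epr_table, os.path.join(outdir, "epr.tsv"), hashes)
        else:
            logger.info("EPR stage skipped: no genes of interest")

        stage = "figures"
        try:
            _figures(enrich_table, epr_table, outdir)
        except Exception as exc:  # plotting must never sink a run
            logger.warning("figure generation failed: %s", exc)

        stage = "provenance"
        prov = {
            "package": "gwasct",
            "version": __version__,
            "config": config,
            "config_hash": hashlib.sha256(
                json.dumps(config, sort_keys=True).encode()
            ).hexdigest(),
            "file_hashes": hashes,
        }
        with open(os.path.join(outdir, "provenance.json"), "w") as fh:
            json.dump(prov, fh, indent=2, sort_keys=True)

        summary = {
            "n_genes_tested": int(len(gene_table)),
            "significant_enrichments": enrich_table[enrich_table["significant"]][
                ["level", "mode", "cell_type", "beta", "p"]
            ].to_dict("records"),
            "coloc_passes": [] if coloc_table.empty else coloc_table[
                coloc_table["passes"]
            ][["probe_id", "PP4"]].to_dict("records"),
            "epr_rows": int(len(epr_table)),
            "provenance": prov["config_hash"],
        }
        return summary
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc


def _figures(enrich_table: pd.DataFrame, epr_table: pd.DataFrame, outdir: str) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if not enrich_table.empty:
        piv = enrich_table.assign(
            neglogp=-np.log10(enrich_table["p"].clip(lower=1e-300))
        ).pivot_table(index="cell_type", columns=["level", "mode"], values="neglogp")
        fig, ax = plt.subplots(figsize=(6, max(2, 0.3 * len(piv))))
        im = ax.imshow(piv.to_numpy(), aspect="auto", cmap="viridis")
        ax.set_yticks(range(len(piv)), piv.index)
        ax.set_xticks(range(piv.shape[1]), ["/".join(c) for c in piv.columns], rotation=45)
        fig.colorbar(im, label="-log10 p")
        fig.tight_layout()
        fig.savefig(os.path.join(outdir, "enrichment_tiles.png"), dpi=120)
        plt.close(fig)
    if not epr_table.empty:
        order = {"off": 0, "low": 1, "high": 2}
        piv = epr_table.pivot_table(
            index="gene_id", columns="cell_type", values="epr_class",
            aggfunc=lambda s: order[s.iloc[0]],
        )
        fig, ax = plt.subplots(figsize=(max(3, 0.5 * piv.shape[1]), max(2, 0.3 * len(piv))))
        im = ax.imshow(piv.to_numpy(), aspect="auto", cmap="RdYlBu", vmin=0, vmax=2)
        ax.set_yticks(range(len(piv)), piv.index)
        ax.set_xticks(range(piv.shape[1]), piv.columns, rotation=45)
        fig.colorbar(im, ticks=[0, 1, 2], label="off / low / high")
        fig.tight_layout()
        fig.savefig(os.path.join(outdir, "epr_classes.png"), dpi=120)
        plt.close(fig)


def load_config(path: str) -> dict:
    import yaml

    with open(path) as fh:
        return yaml.safe_load(fh)
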