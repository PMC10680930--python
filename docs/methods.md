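# Methods

This note documents the statistical models, default parameters and
numerical choices behind `gwasct`, and what the synthetic-data tests do
and do not establish about behavior on real data.

## Synthetic data

The generators are first-class, tested code: they define the conditions
under which every downstream property is verified.

**Single-nucleus counts** (`simulate.ScSimConfig`).  Counts are negative
binomial with per-gene mean `μ_g` and variance `μ_g + μ_g²/φ`
(dispersion `φ`, default 2.0) — the standard overdispersed model for
UMI-based snRNA-seq.  Per-gene baselines are log-normal
(`baseline_mean` = 0.5, σ = 0.5 on the log scale) so library content
varies across genes.  Cell types are (supercluster, class) pairs, default
six superclusters in three classes, 100 cells per type.  Each type owns
`n_marker_genes_per_type` (default 25) markers upregulated by
`marker_fold_change` (default 5).  Sibling superclusters of the same
class additionally express each other's markers at
`fold_change^class_marker_leak` (default leak 0.5, i.e. √5 ≈ 2.24):
related brain cell types share transcriptional programs, and this overlap
is what differentiates the two enrichment modes (see below).  Gene models
are laid along the 22 autosomes with 1–8 exons and transcript spans drawn
from `gene_length_range` (default 2–100 kb), written in GTF dialect with
1-based inclusive coordinates.

What the generator does *not* emulate: donor effects, ambient RNA,
doublets, realistic human LD panels, isoform structure.  Passing tests
therefore establish the correctness and calibration of the statistics
under the stated models, not robustness to those artefacts.

**GWAS summary statistics** (`simulate.GwasSimConfig`).  For each gene,
`m` SNPs (uniform in `snps_per_gene_range`) are placed in the transcript
span; z-scores are `z = L η + b·s_{g,t}·1` with `L` the Cholesky factor
of the AR(1) LD matrix `R_ij = ρ^|i−j|` and `b·s_{g,t}` the planted
gene-level signal (enrichment slope × target-type specificity),
broadcast identically to each SNP (scaling constant 1).  Two consequences
matter: with `b = 0` the z-vector is exactly MVN(0, R), so downstream
gene p-values are exactly uniform under the null; with one SNP the model
reduces to `z = b·s + ε`, the latent single-gene model.  Standard errors
follow `SE = 1/√(2N·maf(1−maf))`, the usual approximation for a
standardized quantitative trait; betas, p-values and alleles are derived
consistently.

**Colocalization loci** (`simulate.ColocSimConfig`).  Marginal z-scores
follow the standard summary-statistic model `ẑ ~ MVN(R z_true, R)` with a
sparse causal vector: H4 shares one causal index between the traits, H3
uses distinct indices, H1/H2 are single-trait, H0 is empty.  Defaults:
100 SNPs, ρ = 0.5, N = 50,000 per trait, causal effect 0.15 per allele
(z ≈ 15–25 at the causal SNP — a clearly detectable, "strong" signal).

## Gene-level association

The snp-wise mean statistic is `Q = Σ z_i²` over a gene's mapped SNPs.
Under the null with LD `R`, `Q ~ Σ λ_i χ²₁` with `λ` the eigenvalues of
`R`.  Three evaluation methods are provided:

* **exact** (default): Ruben's expansion of the weighted sum as a mixture
  of central chi-squares with scale `β = 2λ_min λ_max/(λ_min+λ_max)`.
  All mixture weights are nonnegative and sum to one, so truncation error
  is bounded by the unaccumulated mass, driven below 1e-11.  When the
  computed tail is at or below that guarantee the Kuonen (Lugannani–Rice)
  saddlepoint takes over; its relative error stays bounded into the deep
  tail, keeping the probit `Φ⁻¹(1−p)` finite down to the p floor of
  1e-300.  Equal eigenvalues (identity or rank-one LD) short-circuit to
  the closed-form scaled chi-square, so a single SNP reduces exactly to
  its two-sided normal p.
* **satterthwaite**: the two-moment gamma match via `tr(R)` and `tr(R²)`.
  Kept as a cheap cross-check; its bulk error (~5×10⁻³ absolute at
  p ≈ 0.5 for 10-SNP AR(1) toys, worse at ρ = 0.9) is measurable against
  the exact method, which is why it is not the default.
* **montecarlo**: empirical null `p = (1 + #{Q* ≥ Q})/(B+1)`, for
  validation.

SNP→gene mapping uses a strand-aware window, default 35 kb upstream /
10 kb downstream (the cell-typing literature's convention; the window is
echoed in every run record).  LD is supplied by a pluggable provider —
identity, AR(1) by adjacency of position-sorted SNPs, or a user matrix —
because no reference panel is bundled.  Gene-size covariates attached for
enrichment: `n_snps`, `log n_snps`, transcript-span length and its log
(the exon-union length belongs to the expression summary, not to the
association covariates).

## Cell-type specificity and enrichment

Cells are scaled to unit library size before type means, so depth cannot
masquerade as specificity; `s_gt` rows then sum to one for any expressed
gene, all-zero genes are flagged and excluded from bins (bin 0).  Within
each type the nonzero-specificity genes are ranked into 40 equal-size
quantile bins (configurable), the linear mode's covariate (scaled to
(0, 1]).  Top-decile sets take the top 10% of the nonzero pool with
boundary ties included.

Enrichment is one OLS per cell type of `Z_g` on the specificity covariate
(linear) or the set indicator (top10), plus covariates, with the
one-sided p for a positive slope from the analytic t statistic.
Covariates are standardized internally (affine transforms leave the
tested slope and its SE unchanged); a constant or collinear covariate
design yields a flagged degenerate result rather than a silent drop.
Bonferroni families are all cell types within one (disease, level, mode);
the family size and corrected threshold are written into every output
row, and significance is strict (`p < α/n`).

**Why linear flags more cell types than top10.**  With partially shared
within-class signatures, a target type's signal bleeds into its siblings'
specificity gradients; the linear covariate picks this up while the
sibling's top-decile indicator (dominated by its own exclusive markers)
dilutes it.  The evaluation measures this as the total number of
Bonferroni-significant cell-type flags over replicates.  With fully
exclusive signatures the two modes are statistically indistinguishable on
this generator — the planted signal is then nearly binary in specificity,
which an indicator matches as well as a gradient — so the mode comparison
is meaningful only under overlap, which is also the regime real atlases
occupy.

The planted-recovery evaluation uses an enrichment slope of 7: with six
types the realized specificity range tops out near 0.45, so slope 7
yields a latent contrast of about 3 z-units between the least and most
target-specific genes.

Null calibration (1,000 replicates) draws gene z-scores directly from
N(0,1) — exactly the null distribution of the gene stage, whose
uniformity is verified separately — so the regression calibration is
isolated from the association stage at full replicate count; recovery
runs the complete simulate → munge → gene-association → enrichment path.

## Colocalization

Wakefield ABF per SNP with prior effect SD 0.15 (phenotype-SD scale,
quantitative traits) or 0.2 (log-odds, case-control); priors
p1 = p2 = 1e-4, p12 = 1e-5 per SNP (long-standing field defaults; a p12
above min(p1, p2) warns).  The posterior is accumulated in log space:
`L1 = lse(labf1)`, `L2 = lse(labf2)`, `L12 = lse(labf1+labf2)`, with the
distinct-variant hypothesis `H3 = exp(L1+L2) − exp(L12)` computed by
log-difference and set to zero for single-SNP loci or when non-positive
within tolerance.  Exactness is verified against linear-space enumeration
over all causal configurations on loci of ≤ 5 SNPs (1e-10).

The driver clumps genome-wide significant autosomal GWAS SNPs
(`p ≤ 5×10⁻⁸`, greedy by ascending p, ±500 kb radius) into lead loci,
then tests every probe with at least one eQTL record at `p ≤ 1×10⁻⁴`
inside the ±500 kb window — each probe marginally, as an independent
test.  SNPs are matched by identifier, not alleles: PP depends on z only
through z², so allele flips cannot change it (ambiguous pairs are flagged
upstream).  Pairs sharing fewer than two SNPs are skipped with a logged
reason (single-SNP colocalization only behind a flag).  `PP4 ≥ 0.90` is
the reporting threshold.

## Expression summary

Exon-union length merges all exon intervals of all transcripts, with
bookended intervals (e.g. 100–200, 201–300) treated as contiguous in
1-based inclusive coordinates; a per-transcript alternative is
deliberately not the default — the union is the maximal nonredundant
intron-removed extent.  TPM per cell: `rate_g = count_g / length_g`,
scaled by `10⁶ / Σ rate`; all-zero cells remain zero with a warning.
Percentile rank is the right-continuous ECDF over all genes of the cell
(`100·#{TPM ≤ TPM_g}/G`, ties share the maximal rank), computed per cell
and only then aggregated per (gene, type) as mean and median.

Because snRNA-seq is zero-heavy, the raw ECDF gives tied zero-TPM genes a
high shared rank (19 of 20 genes at zero all rank 95).  Class assignment
therefore defaults to a zero-adjusted statistic in which zero-TPM genes
score 0, while the reported mean/median columns always carry the raw
ECDF values; the raw behavior is available via
`zero_adjusted_class=False`.  Classes: *off* (< 10), *high* (> 90), *low*
otherwise — both boundaries strict, so exactly 10 or 90 is *low*.  The
binned statistic is the mean by default; the median is always reported
alongside and can be binned instead via configuration.

## Harmonization

Column synonyms are resolved from an editable dictionary; odds ratios are
converted to log-odds; z is derived as beta/SE where absent.  Drop rules
(each counted in the QC report, which satisfies
`rows_in = rows_out + Σ drops`): duplicate (probe, SNP) keys keep the
first record; p outside (0, 1]; non-positive SE; non-ACGT single-base
alleles only when allele-level work is requested; missing coordinates
only when positional work is requested.  Strand-ambiguous (A/T, C/G)
pairs are flagged, never dropped, because colocalization matches on
identifiers.  Genome-build liftover is out of scope: builds are asserted
equal by configuration.  Munging harmonized data is a no-op.

## Pipeline

`run_pipeline` executes munge → CTD → gene association → enrichment →
colocalization → expression summary from one configuration (YAML or
dict), writing every intermediate as TSV plus two summary figures
(enrichment tiles, EPR class grid) into a run directory.  A provenance
JSON records the resolved configuration, its hash, the package version
and a SHA-256 per written table; reruns with identical configuration and
seed are bit-identical, which the test suite asserts.  Genes for the
expression summary default to the probes fine-mapped by colocalization,
restricted to the nominated (significantly enriched) supercluster types;
an explicit gene list overrides.  Any stage error halts the run naming
the stage, with earlier outputs preserved.  External-input runs go
through the same stage functions (and the CLI subcommands) on files;
the single-call `run_pipeline` convenience path currently requires a
synthetic block.

## Problem sizes in the shipped evaluations

Acceptance-style evaluations use: 100 enumeration loci (≤ 5 SNPs), 200
null and 200 shared-causal loci of 100 SNPs at N = 50,000; 2,000 null
genes per LD regime with 1–10 SNPs each; a 10⁶-draw Monte-Carlo null on
10-SNP AR(1) toys; 1,000 null enrichment replicates and 100 recovery
replicates on a 1,000-gene, six-type atlas; and a 200-gene,
three-type end-to-end run with three probes, one carrying a shared
causal variant.  These sizes were chosen so each property is measured
with comfortable statistical resolution (e.g. binomial SE ≈ 0.007 on a
0.05 type-I rate at 1,000 replicates) on a single CPU.

## Known limitations

* The AR(1) LD family is a convenience, full-rank by construction; real
  LD blocks are lumpier and can make the weighted-χ² spectrum more
  extreme.  The exact tail method is spectrum-agnostic, but mapping
  windows and clumping radii matter more on real data.
* Specificity bins follow one established convention (40 quantile bins,
  ties by average rank, ceiling); other implementations differ at ties,
  which can move genes across bin boundaries.
* Colocalization assumes at most one causal variant per trait per locus;
  multi-causal loci dilute PP4 (no SuSiE-style decomposition).
* The expression summary reports classes per (gene, type) without
  uncertainty; n_cells is carried so users can judge stability.
* eQTL and GWAS inputs are assumed to share a genome build; no liftover.
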