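# Methods

This note documents the statistical models behind `xcimap`, the defaults
of the synthetic-data generator, the numerical and design choices that
were genuinely open, and what the package's validation does and does not
establish about real data.

## Allelic model

At a heterozygous SNP in an XX individual, let π be the fraction of cells
whose active X is parental haplotype A, and ρ_g the gene's expression
from the inactive X relative to the active X (Xi/Xa ratio). Cells with A
active contribute 1 unit from the A allele and ρ_g from the B allele, and
vice versa, so the expected read fraction of the allele on haplotype A is

    p_A = (π + (1 − π) ρ_g) / (1 + ρ_g).

Special cases anchor the whole pipeline: an inactive gene (ρ_g = 0) in a
completely skewed individual (π = 1) is fully monoallelic (p_A = 1); an
escape gene with ρ_g = 0.4 under π = 1 has p_A = 1/1.4 ≈ 0.71, i.e. a
deviation D = |RR − 0.5| ≈ 0.21, safely below the 0.4 inactive
threshold; any gene in an unskewed individual (π = 0.5) is balanced
regardless of ρ_g — which is exactly why direct bulk ASE readout of XCI
requires a cXCI donor, and why the unskewed donor is the one used for
single-cell haplotype inference.

XIST is modeled as transcribed exclusively from the inactive X. Its
bulk reference fraction is therefore 1 − p_A-like (driven by which
haplotype is inactive), and in single cells its allele directly labels
the cell's inactive haplotype.

## ASE filtering and scoring

Two site filters are implemented. The strict filter (used for XCI
calling) requires WES depth ≥ 20 reads *per allele*, a WES minor-allele
fraction ≥ 10% (both are heterozygosity confirmation — a contaminating
homozygous site shows extreme DNA imbalance), and RNA depth ≥ 10. The
`minor_allele` filter (RNA ≥ 10, WES total > 20) trades genotype
stringency for more sites and feeds the minor-allele read-count
summaries only. When a gene has several surviving sites in a sample, the
one with the highest RNA depth represents the gene; ties break to the
smallest position so the choice is deterministic. A configuration switch
exposes the alternative reading in which the 10% minor-allele filter may
be satisfied by either RNA or DNA; the default applies it to DNA, since
its purpose is genotype confirmation, not expression filtering.

Per-gene deviation is averaged over the cell types that retained a site;
cell types without a surviving site simply do not contribute (the
alternative — imputing them — would mix a missingness model into a
threshold rule). Mean deviation exactly at 0.4 is called escape
("lower or equal" wins over "higher than").

## Sex-biased expression

Genes with mean TPM < 1 across samples are dropped. The fold change is
log2((mean_F + 0.5)/(mean_M + 0.5)); the 0.5 offset matches the
log2(x + 0.5) transform under which the test operates. Significance is a
Welch two-sample t-test per gene on log2(TPM + 0.5) with BH correction;
a gene is sex-biased at p < 1e-5 and |log2FC| > 0.2 (both configurable —
a second published regime, BH-corrected p < 0.01, is expressible through
the same knobs). The female/male contrast is computed over
karyotypically normal (XX/XY) samples by default: an X0 donor is female
but carries a single X, so including her would conflate karyotype dosage
with sex. Class summaries (PAR/escape/inactive medians ± IQR) always
compute statistics on raw fold changes; display capping (±1 or ±0.5) is
reporting-only.

## Promoter methylation

Probes are summarized over [TSS − 500, TSS] on the transcribed strand
(reflected in genome coordinates for minus-strand genes), averaging
probes within a sample first, then samples. Categories: low β < 0.25,
intermediate 0.25–0.75, high > 0.75. Published boundary wordings for the
low/intermediate edge are mutually inconsistent (≤ 0.25 vs < 0.25 vs
≥ 0.25); the classifier-facing default is strict (< 0.25), with
`low_inclusive=True` available. A display-oriented wider window
(−500/+1500) is selectable but never feeds the classifier.

## Combined classifier

ASE evidence, when present, is decisive — allelic counts measure XCI
directly, while methylation and sex bias are correlates; a conflict
(e.g. biallelic ASE at a methylated promoter) is informative about the
correlates, not about the ASE. Without ASE: low methylation with
FC > 0.2 ⇒ escape_high, low methylation with 0 < FC ≤ 0.2 ⇒ escape_low,
methylation ≥ 0.25 with FC < 0.2 ⇒ inactive; the two remaining corners
(unmethylated but not female-biased; methylated yet female-biased) are
unclassified. Boundary values (FC exactly 0 or 0.2) fall to the lower
band; the inequalities are config-exposed. Significance gating of the FC
criterion is off by default (only the FC value appears in the rule) but
available; when on, a non-significant FC is treated as 0. Agreement with
a prior annotation is computed over genes with a binary call and an
escape/inactive prior; priors recorded as variable or unknown are
excluded and counted separately, since they cannot match a binary call.

## Single-cell Xi inference

Cells failing QC (mitochondrial fraction > 10%, ribosomal fraction
> 20%, total reads outside 125k–1M) are removed first. Cluster 1 is
*defined* as the XIST-reference-allele cluster; the numbering is a fixed
convention, and all downstream quantities are invariant under relabeling
(tested). Cells with biallelic XIST, or with tied anchor votes, are left
unassigned: doublets and index hopping are likelier than true biallelic
XIST. Anchor discovery is automated — a hetSNP anchors the clustering
iff, among XIST-assigned cells expressing it, each cluster shows exactly
one allele, the two alleles are opposite, and each cluster has ≥ 3
expressing cells — rather than hard-coding the seven genes used in the
original design; that list ships as `ANCHOR_GENE_PRESET` for real-data
runs. The anchor unit is the SNP, because allele phase is per-SNP; a
gene qualifies through its SNPs. Detection of an allele within a cell
means ≥ 1 read (configurable). Per-SNP escape calls use the unweighted
mean RR over cells with any reads, per cluster, with the 0.1–0.9 escape
window and a ≥ 2-cell detection requirement; both escape routes are
honored (biallelism within a cell, or opposite monoallelic cells within
a cluster).

## Skewing and leakage

π̂ is the median over informative inactive-gene SNPs of the folded
major-allele fraction max(RR, 1 − RR), clipped to [0.5, 1]. RR here is
the SNP's reference ratio averaged across cell types *before* folding:
phase is fixed within an individual, and folding per cell type would
rectify sampling noise into an upward bias near RR = 0.5 (for a binomial
RR at depth n, E|RR − 0.5| ≈ √(1/2πn) even when π = 0.5). The median
(not mean) guards against residual escape genes contaminating the
inactive set. cXCI is flagged when ≥ 95% of informative SNPs have
deviation > 0.4; below 10 informative SNPs both estimates are returned
as indeterminate rather than defaulting to "not skewed".

The leak bound models a fraction f of cells re-expressing a silenced
allele at ratio ρ relative to the active allele, giving an expected
minor-read fraction p = fρ/(1 + fρ). A one-sided exact
(Clopper–Pearson) 95% upper bound p_u on p — beta.ppf(0.95, m+1, n−m) —
inverts to f ≤ p_u/(ρ(1 − p_u)), capped at 1. Exact tails matter because
the regime of interest is m near 0, where normal approximations fail.
ρ is not identifiable from the data (ρ = 0 errors out), so the bound is
reported over a sensitivity grid {0.33, 0.5, 1} by default. At m = 0,
n = 10,000, ρ = 1 the bound is f ≤ 3.0 × 10⁻⁴, which excludes a 2–5%
reactivated subpopulation by two orders of magnitude.

## Synthetic-data generator

The generator's defaults are the study conditions, not tuning knobs:

| parameter | default | rationale |
|---|---|---|
| gene classes | 8 PAR / 30 escape / 120 inactive / 50 autosomal | escape ≈ 19% of X-linked genes, inside the accepted 15–20% range |
| donors | 4 XX (π = 0.75, 0.60, 1.00, 0.50), 3 XY, 1 X0 | mirrors the study roster: one cXCI female, one unskewed female for single cells, a Turner-syndrome donor |
| cell types | 6 thymocyte stages (ETP … CD8SP) | the developmental axis across which XCI stability is assessed |
| xi_ratio ρ | 0.4 | midpoint of the reported 0.22–0.59× female excess at escape genes; log2(1.4) ≈ 0.49 emerges as their female bias |
| leak_fraction f | 0 | high-fidelity XCI is the null; set 0.02–0.05 to emulate the loss-of-XCI scenario |
| rna_depth / dna_depth | 100 / 60 | desk-scale analogues of deep RNA-seq and WES site coverage |
| overdispersion | 0.02 | beta-binomial intra-class correlation typical of RNA-seq allelic counts |
| het_rate | 1.5 hetSNPs/gene (Poisson) | most genes informative, some not — as with real exome heterozygosity; `het_sites_per_gene` fixes the count exactly when a design requires it |
| promoter β | escape/PAR/autosome Beta(4, 36) (mean 0.1), inactive Beta(30, 30) (mean 0.5) | unmethylated vs one-allele-methylated promoters, with realistic spread |
| single cells | 75/cell type, detect prob 0.35, ~3 reads/SNP, XIST detected in 30% of cells, 10% QC failures injected | Smart-seq2-like sparsity; XIST capture matches the ~29% detection that motivates anchor propagation |

DNA counts are Binomial(dna_depth, 0.5) (a heterozygous site sequenced
without allelic bias); RNA counts are beta-binomial around the expected
fraction (allelic RNA ratios are overdispersed relative to binomial).
One XIST hetSNP is emitted per female, since the cluster-1 convention is
defined relative to a single marker SNP. X0 donors carry no heterozygous
chrX site at all (single X, PAR included); XY donors are heterozygous
only in the PAR. All sampling flows through named substreams spawned
from one master seed, so outputs are identical for a given config
regardless of which products are generated.

What the generator does **not** model — and therefore what passing tests
do not establish about real data: reference/alignment bias at hetSNPs
(handled upstream by WASP-style filtering in real pipelines), genotyping
error, cell-type-specific expression of individual genes, correlated
probe noise and cross-reactive probes on methylation arrays, ambient RNA
and doublets in single cells (conflict policies exist but see only clean
conflicts), and sequencing error as a floor on minor-allele counts. The
last point matters for the leak bound's coverage check: with f = 0 and
no error floor, simulated minor counts are exactly zero and the bound
trivially covers; on real data the bound is conservative because errors
inflate m.

## Validation problem sizes

The acceptance script and test suite run at desk scale: 300 simulated
cohorts (6 π values × 50 replicates) of 30 SNPs at depth 500 for skewing
recovery; one default cohort (~160 X-linked genes, 48 samples) for
classifier recovery; ~200 single cells for cluster recovery; 1,000
replicates each for leak-bound coverage and power at pooled N ≈ 2,400;
2,000 null genes at 20 vs 20 samples for t-test calibration. These sizes
keep each check well-powered for the thresholds asserted while running
in seconds.
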