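# xcimap

Inference of X-chromosome inactivation (XCI) status from bulk and
single-cell transcriptomics, promoter DNA methylation and sex-biased
expression.

In female (XX) cells one X chromosome is transcriptionally silenced, but
roughly 15–20% of X-linked genes *escape* silencing and stay biallelically
expressed — with direct consequences for sex differences in immunity and
for X-linked disease penetrance. `xcimap` implements the downstream
analysis needed to map escape at gene resolution:

- **Allele-specific expression (ASE).** At a heterozygous SNP with
  reference ratio RR = ref reads / total reads, the allelic deviation
  D = |RR − 0.5| separates monoallelic (D → 0.5) from biallelic (D → 0)
  expression. Sites are filtered on WES genotype confidence (≥20 reads
  per allele, minor-allele fraction ≥10%) and RNA depth (≥10); one site
  per gene per cell type (highest RNA depth) is scored, and genes with
  mean D > 0.4 across cell types are called inactive, mean D ≤ 0.4
  escape. Direct ASE readout of XCI in bulk requires a donor with
  completely skewed XCI (cXCI), in whom the same parental X is inactive
  in every cell.
- **Sex-biased expression.** log2FC = log2((TPM̄_F + ε)/(TPM̄_M + ε)),
  ε = 0.5, with a Welch t-test on log2(TPM + ε) and Benjamini–Hochberg
  correction; escape genes show female-biased expression because the
  inactive-X allele adds a fractional second dose.
- **Promoter methylation.** Mean β of array probes in the strand-aware
  [TSS − 500 bp, TSS] window, categorized low (β < 0.25), intermediate
  (0.25–0.75) or high (> 0.75); escape promoters are unmethylated, XCI
  promoters intermediate (one methylated allele of two).
- **Combined classifier.** ASE evidence, when present, is decisive;
  otherwise low methylation with log2FC > 0.2 ⇒ high-confidence escape,
  low methylation with 0 < log2FC ≤ 0.2 ⇒ low-confidence escape,
  methylation ≥ 0.25 with log2FC < 0.2 ⇒ inactive, everything else
  unclassified. Calls carry their evidence trail and can be compared to a
  prior escape annotation.
- **Single-cell Xi inference.** XIST is expressed only from the inactive
  X, so a cell's XIST allele identifies its inactive haplotype; XIST⁺
  cells seed two clusters, inactive "anchor" genes with opposed
  monoallelic expression propagate the assignment, and per-SNP escape is
  called per cluster from the mean RR (escape window 0.1–0.9, SNPs
  detected in ≥2 cells).
- **Skewing and leakage.** Skewing π (fraction of cells sharing the same
  active X) is estimated as the median folded major-allele fraction
  max(RR, 1 − RR) over inactive-gene SNPs; complete skewing is flagged
  when ≥95% of such SNPs are monoallelic. An exact Clopper–Pearson bound
  on the minor-read fraction converts to a 95% upper bound on the
  fraction of cells with loss of XCI:
  f ≤ p_u / (ρ · (1 − p_u)), where ρ is the assumed reactivated/active
  expression ratio.

The real data this kind of analysis targets are typically under
restricted access, so the package ships a synthetic-cohort generator
(`xcimap.synthetic`) that emulates the full study design — XX/XY/X0
donors across six thymocyte developmental stages, beta-binomial allelic
counts, promoter β values, Smart-seq2-style single cells — with complete
ground truth (true status per gene, skewing, leak events, per-cell
inactive haplotype), making every stage testable end to end.

## Worked example

```python
from xcimap.synthetic import SimConfig, simulate_cohort
from xcimap.ase import run_ase
from xcimap.methylation import promoter_mean_beta
from xcimap.sexbias import sex_bias_test, tpm_filter
from xcimap.classifier import classify_all, compare_with_reference
from xcimap.skewing import estimate_skewing, leak_upper_bound

cohort = simulate_cohort(SimConfig(seed=1))

# ASE in the completely skewed donor (F3)
f3_sites = [s for s in cohort.allelic_sites if s.sample_id.startswith("F3_")]
ase_calls = run_ase(f3_sites, mode="strict")
print(f"{sum(c.ase_status != 'no_call' for c in ase_calls)} genes "
      "with informative hetSNPs in the cXCI donor")

est = estimate_skewing([c for c in ase_calls if c.gene_id.startswith("INAG")],
                       individual="F3")
print(f"F3 skewing estimate: pi = {est.pi_hat:.3f} (cXCI: {est.cxci_flag})")

proms = promoter_mean_beta(cohort.methylation, cohort.annotation)
biases = sex_bias_test(tpm_filter(cohort.expression))
xgenes = [g.gene_id for g in cohort.annotation
          if g.chrom == "chrX" and g.gene_id != "XIST"]
status = classify_all(ase_calls, proms, biases, genes=xgenes)
report = compare_with_reference(status, cohort.annotation)
print(f"agreement with the prior annotation: {report.agreement:.1%} "
      f"over {report.n_comparable} genes")

bound = leak_upper_bound(m=3, n=12000, rho_leak=1.0)
print(f"leak bound: f <= {bound.f_upper:.2e} at 95% confidence")
```

Output:

```
157 genes with informative hetSNPs in the cXCI donor
F3 skewing estimate: pi = 1.000 (cXCI: True)
agreement with the prior annotation: 100.0% over 156 genes
leak bound: f <= 6.46e-04 at 95% confidence
```

In words: of the simulated X-linked genes, 157 carried a heterozygous SNP
surviving the strict filters in the completely skewed donor; the folded
allelic ratios at inactive genes put her skewing at π = 1 (cXCI); the
combined classifier reproduces the cohort's prior escape/inactive
annotation for all 156 comparable genes; and observing 3 minor-allele
reads out of 12,000 caps the fraction of cells with full loss of XCI at
about 0.06% — two orders of magnitude below a hypothetical 2–5%
reactivated subpopulation.

The same pipeline is scriptable from the shell (`xcimap simulate`,
`xcimap ase`, `xcimap sexbias`, `xcimap meth`, `xcimap classify`,
`xcimap sc-xi`, `xcimap skew`, `xcimap leak`); run `xcimap --help`.

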