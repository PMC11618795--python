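"""Bulk allele-specific expression: site filtering, per-gene scoring, calls.

The allelic unit is a heterozygous SNP (hetSNP) with RNA-seq and WES (DNA)
read counts. Sites are filtered for genotype confidence and expression
depth, one site per gene per cell type is selected (highest RNA depth),
and the gene's allelic deviation D = |RR - 0.5| is averaged across cell
types: genes with mean D > 0.4 are monoallelic (inactive), with mean
D <= 0.4 biallelic (escape).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .io_formats import AllelicSite, GeneAnnotation

__all__ = [
    "SiteAse",
    "GeneAseCall",
    "MinorAlleleSummary",
    "filter_ase_sites",
    "select_gene_site",
    "ase_score",
    "run_ase",
    "minor_allele_summary",
]

ASE_INACTIVE_THRESHOLD = 0.4


@dataclass(frozen=True)
class SiteAse:
    """The selected site's allelic readout in one cell type."""

    pos: int
    rna_ref: int
    rna_alt: int

    @property
    def ref_ratio(self) -> float:
        return self.rna_ref / (self.rna_ref + self.rna_alt)

    @property
    def deviation(self) -> float:
        return abs(self.ref_ratio - 0.5)


@dataclass
class GeneAseCall:
    """Per-gene ASE summary across cell types and the resulting XCI call.

    ``ase_status`` is ``no_call`` iff no site survived filtering in any
    cell type; otherwise ``inactive`` if the mean deviation across the
    available cell types exceeds the threshold, else ``escape``.
    """

    gene_id: str
    per_cell_type: dict[str, SiteAse] = field(default_factory=dict)
    mean_deviation: float | None = None
    ase_status: str = "no_call"


def filter_ase_sites(sites: Sequence[AllelicSite], mode: str = "strict") -> list[AllelicSite]:
    """Filter hetSNP sites for downstream ASE analysis; order preserved.

    strict
        WES depth >= 20 reads per allele, WES minor-allele fraction >= 10%
        (heterozygosity confirmation), and RNA total depth >= 10.
    minor_allele
        RNA total depth >= 10 and WES total depth > 20 — the looser filter
        used for minor-allele read-count summaries, keeping more hetSNPs
        while retaining high-confidence genotypes.

    Filtering is idempotent and symmetric under ref/alt relabeling.
    """
    if mode == "strict":
        def keep(s: AllelicSite) -> bool:
            if s.dna_ref < 20 or s.dna_alt < 20:
                return False
            if min(s.dna_ref, s.dna_alt) / s.dna_total < 0.10:
                return False
            return s.rna_total >= 10
    elif mode == "minor_allele":
        def keep(s: AllelicSite) -> bool:
            return s.rna_total >= 10 and s.dna_total > 20
    else:
        raise ValueError(f"unknown filter mode {mode!r}")
    return [s for s in sites if keep(s)]


def select_gene_site(sites_of_gene: Sequence[AllelicSite]) -> AllelicSite | None:
    """Pick the one site to represent a gene: highest RNA read count,
    ties broken by smallest genomic position. None if no site survives.
    """
    if not sites_of_gene:
        return None
    return min(sites_of_gene, key=lambda s: (-s.rna_total, s.pos))


def ase_score(
    gene_id: str,
    selected: Mapping[str, AllelicSite],
    threshold: float = ASE_INACTIVE_THRESHOLD,
) -> GeneAseCall:
    """Score a gene from its selected site per cell type.

    The mean deviation averages over cell types that retained a site.
    Mean D at exactly the threshold goes to ``escape`` ("lower or equal").
    """
    call = GeneAseCall(gene_id=gene_id)
    for ct, site in selected.items():
        if site.rna_total == 0:
            continue
        call.per_cell_type[ct] = SiteAse(site.pos, site.rna_ref, site.rna_alt)
    if not call.per_cell_type:
        return call
    devs = [s.deviation for s in call.per_cell_type.values()]
    call.mean_deviation = sum(devs) / len(devs)
    call.ase_status = "inactive" if call.mean_deviation > threshold else "escape"
    return call


def run_ase(
    sites: Sequence[AllelicSite],
    mode: str = "strict",
    threshold: float = ASE_INACTIVE_THRESHOLD,
) -> list[GeneAseCall]:
    """Full bulk ASE pipeline for one individual's sites.

    Filters sites, selects the top site per gene per cell type, and scores
    each gene. Sites are expected to come from a single individual (ASE
    phases are not comparable across donors).
    """
    kept = filter_ase_sites(sites, mode=mode)
    by_gene_ct: dict[str, dict[str, list[AllelicSite]]] = defaultdict(
        lambda: defaultdict(list)
    )
    for s in kept:
        by_gene_ct[s.gene_id][s.cell_type].append(s)
    calls = []
    for gene_id in sorted(by_gene_ct):
        selected = {}
        for ct, ct_sites in by_gene_ct[gene_id].items():
            site = select_gene_site(ct_sites)
            if site is not None:
                selected[ct] = site
        calls.append(ase_score(gene_id, selected, threshold=threshold))
    return calls


@dataclass
class MinorAlleleSummary:
    """Minor-allele read counts over a gene set, per cell type and per gene.

    ``per_cell_type`` columns: total_reads, minor_reads, minor_fraction,
    n_genes, n_snps. ``per_gene`` columns: cell_type, gene_id, minor_reads,
    total_reads.
    """

    gene_set: str
    per_cell_type: pd.DataFrame
    per_gene: pd.DataFrame


def minor_allele_summary(
    sites: Sequence[AllelicSite],
    gene_set: str,
    annotation: Iterable[GeneAnnotation],
) -> MinorAlleleSummary:
    """Total minor-allele (putative Xi) read counts over inactive or immune
    genes, per cell type.

    The minor allele at each site is the one with fewer reads; under
    complete skewing it is the silenced (Xi) allele, so these totals bound
    expression leaking from the inactive X. Sites should already be
    filtered in ``minor_allele`` mode.
    """
    if gene_set == "inactive":
        genes = {g.gene_id for g in annotation if g.prior_status == "inactive"}
    elif gene_set == "immune":
        genes = {g.gene_id for g in annotation if g.immune_flag}
    else:
        raise ValueError(f"unknown gene_set {gene_set!r}; use 'inactive' or 'immune'")
    rows = []
    for s in sites:
        if s.gene_id in genes:
            rows.append(
                {
                    "cell_type": s.cell_type,
                    "gene_id": s.gene_id,
                    "minor_reads": s.rna_minor,
                    "total_reads": s.rna_total,
                }
            )
    per_gene = pd.DataFrame(rows, columns=["cell_type", "gene_id", "minor_reads", "total_reads"])
    if per_gene.empty:
        per_ct = pd.DataFrame(
            columns=["total_reads", "minor_reads", "minor_fraction", "n_genes", "n_snps"]
        )
    else:
        grouped = per_gene.groupby("cell_type")
        per_ct = grouped.agg(
            total_reads=("total_reads", "sum"),
            minor_reads=("minor_reads", "sum"),
            n_genes=("gene_id", "nunique"),
            n_snps=("gene_id", "size"),
        )
        per_ct["minor_fraction"] = per_ct["minor_reads"] / per_ct["total_reads"]
        per_ct = per_ct[["total_reads", "minor_reads", "minor_fraction", "n_genes", "n_snps"]]
    return MinorAlleleSummary(gene_set, per_ct, per_gene)
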