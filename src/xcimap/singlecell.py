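"""Inactive-X haplotype inference from single-cell allelic counts.

In a non-skewed female, cells split into two populations by which parental
X is inactive. XIST is transcribed exclusively from the inactive X (Xi),
so a cell's XIST allele identifies its Xi haplotype directly; cells with
XIST reads seed two clusters (cluster 1 = XIST reference allele, by
convention). Because XIST is captured in only a fraction of cells, genes
subject to XCI that show perfectly consistent monoallelic expression per
cluster ("anchor" genes) propagate the assignment to the remaining cells
by majority vote. Per-SNP escape status is then called per cluster from
the mean reference ratio across cells, using the 0.1-0.9 escape window.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CellAllelicProfile",
    "ClusterAssignment",
    "SnpEscapeCall",
    "AnchorSnp",
    "ANCHOR_GENE_PRESET",
    "qc_filter_cells",
    "assign_by_xist",
    "find_anchor_genes",
    "propagate_clusters",
    "call_snp_escape",
    "xi_read_histogram",
    "xi_alleles_from_phases",
    "infer_xi_alleles",
]

# Inactive genes used in the original Smart-seq2 design to propagate the
# XIST-seeded clustering; shipped as a named preset for real-data runs.
ANCHOR_GENE_PRESET = ("ATRX", "BEX4", "ITM2A", "LAMP2", "MORF4L2", "PIN4", "TMSB4X")


@dataclass
class CellAllelicProfile:
    """Per-cell allelic counts at heterozygous SNPs plus QC metrics.

    ``counts`` maps (gene_id, pos) to (rna_ref, rna_alt).
    """

    cell_id: str
    cell_type: str
    counts: dict[tuple[str, int], tuple[int, int]]
    total_reads: int
    mito_fraction: float
    ribo_fraction: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.mito_fraction <= 1.0 or not 0.0 <= self.ribo_fraction <= 1.0:
            raise ValueError(f"{self.cell_id}: QC fractions must be in [0, 1]")
        for (g, p), (r, a) in self.counts.items():
            if r < 0 or a < 0:
                raise ValueError(f"{self.cell_id}: negative count at {g}:{p}")

    def gene_counts(self, gene: str) -> tuple[int, int]:
        """Summed (ref, alt) over all SNPs of one gene."""
        ref = alt = 0
        for (g, _), (r, a) in self.counts.items():
            if g == gene:
                ref += r
                alt += a
        return ref, alt


@dataclass(frozen=True)
class ClusterAssignment:
    """A cell's inferred Xi cluster and the evidence it rests on.

    ``cluster`` is 1, 2 or None (unassigned); ``basis`` is "XIST",
    "anchor:<gene[,gene...]>", "conflict" or "none".
    """

    cell_id: str
    cluster: int | None
    basis: str


@dataclass(frozen=True)
class AnchorSnp:
    """A hetSNP with perfectly opposed monoallelic expression per cluster."""

    gene_id: str
    pos: int
    cluster1_allele: str  # "ref" | "alt"
    cluster2_allele: str


@dataclass
class SnpEscapeCall:
    """Per-cluster escape/inactive status of one hetSNP."""

    gene_id: str
    pos: int
    mean_rr: dict[int, float | None]
    n_cells: dict[int, int]
    status: dict[int, str]  # escape | inactive | no_call
    concordant: bool | None  # None = not_comparable


def qc_filter_cells(
    cells: Iterable[CellAllelicProfile],
    mito_max: float = 0.10,
    ribo_max: float = 0.20,
    reads_min: int = 125_000,
    reads_max: int = 1_000_000,
) -> list[CellAllelicProfile]:
    """Drop cells failing QC: mito > 10%, ribo > 20%, reads outside 125k-1M."""
    return [
        c
        for c in cells
        if c.mito_fraction <= mito_max
        and c.ribo_fraction <= ribo_max
        and reads_min <= c.total_reads <= reads_max
    ]


def assign_by_xist(
    cells: Sequence[CellAllelicProfile], xist_gene: str = "XIST"
) -> list[ClusterAssignment]:
    """Seed clusters from allelic XIST expression.

    Cells with only reference XIST reads go to cluster 1, only alternative
    reads to cluster 2. Cells with both alleles detected are left
    unassigned with basis ``conflict`` (doublet/index-hopping policy);
    cells without XIST reads are unassigned with basis ``none``.
    """
    out = []
    any_xist = False
    for c in cells:
        ref, alt = c.gene_counts(xist_gene)
        if ref + alt > 0:
            any_xist = True
        if ref > 0 and alt == 0:
            out.append(ClusterAssignment(c.cell_id, 1, "XIST"))
        elif alt > 0 and ref == 0:
            out.append(ClusterAssignment(c.cell_id, 2, "XIST"))
        elif ref > 0 and alt > 0:
            out.append(ClusterAssignment(c.cell_id, None, "conflict"))
        else:
            out.append(ClusterAssignment(c.cell_id, None, "none"))
    if not any_xist:
        warnings.warn("no XIST allelic reads found; all cells unassigned")
    return out


def _snp_alleles_by_cluster(
    cells: Sequence[CellAllelicProfile],
    clusters: Mapping[str, int],
    min_reads: int = 1,
) -> dict[tuple[str, int], dict[int, set[str]]]:
    """Observed allele sets per SNP per cluster (among clustered cells)."""
    seen: dict[tuple[str, int], dict[int, set[str]]] = {}
    for c in cells:
        cl = clusters.get(c.cell_id)
        if cl is None:
            continue
        for key, (r, a) in c.counts.items():
            d = seen.setdefault(key, {1: set(), 2: set()})
            if r >= min_reads:
                d[cl].add("ref")
            if a >= min_reads:
                d[cl].add("alt")
    return seen


def find_anchor_genes(
    cells: Sequence[CellAllelicProfile],
    assignments: Sequence[ClusterAssignment],
    candidate_genes: Sequence[str] | None = None,
    min_cells: int = 3,
    min_reads: int = 1,
    xist_gene: str = "XIST",
) -> list[AnchorSnp]:
    """Discover anchor SNPs among XIST-assigned cells.

    A SNP anchors the clustering iff, restricted to XIST-assigned cells
    expressing it, every cell within a cluster shows the same single
    allele, the two clusters show opposite alleles, and each cluster has
    at least ``min_cells`` expressing cells. ``candidate_genes`` restricts
    the search (e.g. to :data:`ANCHOR_GENE_PRESET` or to known inactive
    genes); XIST itself is never an anchor.
    """
    clusters = {a.cell_id: a.cluster for a in assignments if a.cluster is not None}
    per_snp: dict[tuple[str, int], dict[int, Counter]] = {}
    n_cells_expr: dict[tuple[str, int], Counter] = {}
    for c in cells:
        cl = clusters.get(c.cell_id)
        if cl is None:
            continue
        for (gene, pos), (r, a) in c.counts.items():
            if gene == xist_gene:
                continue
            if candidate_genes is not None and gene not in candidate_genes:
                continue
            if r < min_reads and a < min_reads:
                continue
            d = per_snp.setdefault((gene, pos), {1: Counter(), 2: Counter()})
            if r >= min_reads:
                d[cl]["ref"] += 1
            if a >= min_reads:
                d[cl]["alt"] += 1
            n_cells_expr.setdefault((gene, pos), Counter())[cl] += 1
    anchors = []
    for (gene, pos), d in sorted(per_snp.items()):
        nc = n_cells_expr[(gene, pos)]
        if nc[1] < min_cells or nc[2] < min_cells:
            continue
        alleles1 = {al for al, n in d[1].items() if n > 0}
        alleles2 = {al for al, n in d[2].items() if n > 0}
        if len(alleles1) != 1 or len(alleles2) != 1:
            continue  # biallelic within a cluster: not consistently monoallelic
        (al1,), (al2,) = alleles1, alleles2
        if al1 == al2:
            continue  # no discrimination between clusters
        anchors.append(AnchorSnp(gene, pos, al1, al2))
    return anchors


def propagate_clusters(
    cells: Sequence[CellAllelicProfile],
    assignments: Sequence[ClusterAssignment],
    anchors: Sequence[AnchorSnp],
    min_reads: int = 1,
) -> list[ClusterAssignment]:
    """Assign XIST-negative cells by majority vote over expressed anchors.

    Each anchor SNP a cell expresses votes for the cluster whose allele
    the cell shows (a biallelic anchor observation votes for both, i.e.
    cancels). Ties or zero votes leave the cell unassigned; the basis
    records the deciding anchor genes.
    """
    anchor_map = {(a.gene_id, a.pos): a for a in anchors}
    by_id = {a.cell_id: a for a in assignments}
    out = []
    for c in cells:
        a0 = by_id.get(c.cell_id, ClusterAssignment(c.cell_id, None, "none"))
        if a0.cluster is not None:
            out.append(a0)
            continue
        votes: Counter = Counter()
        voters: dict[int, list[str]] = {1: [], 2: []}
        for key, (r, alt) in c.counts.items():
            anc = anchor_map.get(key)
            if anc is None:
                continue
            for allele, n in (("ref", r), ("alt", alt)):
                if n >= min_reads:
                    cl = 1 if anc.cluster1_allele == allele else 2
                    votes[cl] += 1
                    voters[cl].append(anc.gene_id)
        if votes[1] > votes[2]:
            out.append(
                ClusterAssignment(c.cell_id, 1, "anchor:" + ",".join(sorted(set(voters[1]))))
            )
        elif votes[2] > votes[1]:
            out.append(
                ClusterAssignment(c.cell_id, 2, "anchor:" + ",".join(sorted(set(voters[2]))))
            )
        elif votes[1] == votes[2] and votes[1] > 0:
            out.append(ClusterAssignment(c.cell_id, None, "conflict"))
        else:
            out.append(ClusterAssignment(c.cell_id, None, "none"))
    return out


def call_snp_escape(
    cells: Sequence[CellAllelicProfile],
    assignments: Sequence[ClusterAssignment],
    rr_low: float = 0.1,
    rr_high: float = 0.9,
    min_cells: int = 2,
    xist_gene: str | None = "XIST",
) -> list[SnpEscapeCall]:
    """Per-SNP, per-cluster escape calls from mean reference ratios.

    The mean is unweighted over cells with at least one read at the SNP.
    A SNP detected in fewer than ``min_cells`` cells in a cluster is
    ``no_call`` there ("detected in more than one cell"). Escape iff
    ``rr_low <= mean RR <= rr_high``: both within-cell biallelism and
    opposite monoallelic cells within a cluster can produce it.
    ``concordant`` compares the two clusters and is None (not comparable)
    if either side is no_call. XIST is excluded by default.
    """
    clusters = {a.cell_id: a.cluster for a in assignments if a.cluster is not None}
    rrs: dict[tuple[str, int], dict[int, list[float]]] = {}
    for c in cells:
        cl = clusters.get(c.cell_id)
        if cl is None:
            continue
        for (gene, pos), (r, a) in c.counts.items():
            if xist_gene is not None and gene == xist_gene:
                continue
            if r + a == 0:
                continue
            rrs.setdefault((gene, pos), {1: [], 2: []})[cl].append(r / (r + a))
    calls = []
    for (gene, pos), d in sorted(rrs.items()):
        mean_rr: dict[int, float | None] = {}
        n_cells: dict[int, int] = {}
        status: dict[int, str] = {}
        for cl in (1, 2):
            vals = d[cl]
            n_cells[cl] = len(vals)
            if len(vals) < min_cells:
                mean_rr[cl] = float(np.mean(vals)) if vals else None
                status[cl] = "no_call"
            else:
                m = float(np.mean(vals))
                mean_rr[cl] = m
                status[cl] = "escape" if rr_low <= m <= rr_high else "inactive"
        if "no_call" in status.values():
            concordant = None
        else:
            concordant = status[1] == status[2]
        calls.append(SnpEscapeCall(gene, pos, mean_rr, n_cells, status, concordant))
    return calls


def xi_alleles_from_phases(
    phases: Mapping[tuple[str, int], bool],
    xist_ref_on_a: bool,
) -> dict[tuple[str, int], dict[int, str]]:
    """Xi allele per SNP per cluster from known haplotype phases.

    ``phases`` maps (gene, pos) -> reference allele on haplotype A.
    Cluster 1 is defined by XIST reference reads; XIST comes from Xi, so
    cluster-1 cells carry the XIST reference allele on their Xi. That
    fixes which parental haplotype is Xi per cluster, and the phase of
    every other SNP then gives its Xi allele.
    """
    # cluster 1: Xi carries XIST ref => Xi haplotype is A iff xist_ref_on_a
    xi_hap = {1: "A" if xist_ref_on_a else "B"}
    xi_hap[2] = "B" if xi_hap[1] == "A" else "A"
    out = {}
    for key, ref_on_a in phases.items():
        out[key] = {
            cl: ("ref" if (hap == "A") == bool(ref_on_a) else "alt")
            for cl, hap in xi_hap.items()
        }
    return out


def infer_xi_alleles(anchors: Sequence[AnchorSnp]) -> dict[tuple[str, int], dict[int, str]]:
    """Xi allele per anchor SNP per cluster, inferred from the anchors alone.

    Anchor SNPs are monoallelic from the active X, so the allele a cluster
    expresses is its Xa allele and the opposite allele is its Xi allele.
    """
    out = {}
    for a in anchors:
        out[(a.gene_id, a.pos)] = {
            1: "alt" if a.cluster1_allele == "ref" else "ref",
            2: "alt" if a.cluster2_allele == "ref" else "ref",
        }
    return out


@dataclass
class XiReadHistogram:
    """Cells bucketed by how many reads they show from the inactive X."""

    counts: dict[str, int]  # keys "0", "1", "2+"
    n_unassigned_excluded: int


def xi_read_histogram(
    cells: Sequence[CellAllelicProfile],
    assignments: Sequence[ClusterAssignment],
    xi_alleles: Mapping[tuple[str, int], Mapping[int, str]],
    gene_set: Sequence[str] | None = None,
) -> XiReadHistogram:
    """Count cells with 0, 1 or >=2 reads from the Xi allele of inactive
    genes. Unassigned cells are excluded and their count reported.
    """
    clusters = {a.cell_id: a.cluster for a in assignments if a.cluster is not None}
    counts = {"0": 0, "1": 0, "2+": 0}
    excluded = 0
    for c in cells:
        cl = clusters.get(c.cell_id)
        if cl is None:
            excluded += 1
            continue
        xi_reads = 0
        for key, (r, a) in c.counts.items():
            if gene_set is not None and key[0] not in gene_set:
                continue
            spec = xi_alleles.get(key)
            if spec is None:
                continue
            xi_reads += r if spec[cl] == "ref" else a
        bucket = "0" if xi_reads == 0 else ("1" if xi_reads == 1 else "2+")
        counts[bucket] += 1
    return XiReadHistogram(counts, excluded)
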