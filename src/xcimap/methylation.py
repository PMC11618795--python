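"""Promoter methylation summaries and low/intermediate/high categories.

Promoter methylation of X-linked genes in females separates XCI states:
escape-gene promoters are unmethylated on both alleles (low beta), while
promoters subject to XCI are methylated on the inactive allele only,
giving intermediate beta. Probes are summarized over a strand-aware
window upstream of the TSS (default 500 bp upstream to the TSS itself).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable

import pandas as pd

from .io_formats import GeneAnnotation, MethylationTable, ValidationError

__all__ = [
    "PromoterMethylation",
    "promoter_mean_beta",
    "categorize_beta",
    "top_variable_probes",
]

LOW_BOUNDARY = 0.25
HIGH_BOUNDARY = 0.75


@dataclass
class PromoterMethylation:
    """Mean promoter beta of one gene, per cell type and overall."""

    gene_id: str
    per_cell_type: dict[str, float] = field(default_factory=dict)
    mean_beta: float | None = None
    category: str = "no_probe"
    n_probes: int = 0


def categorize_beta(
    mean_beta: float,
    low_boundary: float = LOW_BOUNDARY,
    high_boundary: float = HIGH_BOUNDARY,
    low_inclusive: bool = False,
) -> str:
    """Map a mean beta in [0, 1] to low / intermediate / high.

    Default boundaries: low iff beta < 0.25, high iff beta > 0.75,
    intermediate otherwise. ``low_inclusive=True`` switches the low
    boundary to beta <= 0.25 (an alternative published convention).
    """
    if not 0.0 <= mean_beta <= 1.0:
        raise ValidationError(f"beta value {mean_beta} outside [0, 1]")
    is_low = mean_beta <= low_boundary if low_inclusive else mean_beta < low_boundary
    if is_low:
        return "low"
    if mean_beta > high_boundary:
        return "high"
    return "intermediate"


def _promoter_window(tss: int, strand: str, upstream: int, downstream: int) -> tuple[int, int]:
    """Genomic [start, end] (1-based inclusive) of the promoter window,
    reflected for minus-strand genes."""
    if strand == "+":
        return tss - upstream, tss + downstream
    return tss - downstream, tss + upstream


def promoter_mean_beta(
    meth: MethylationTable,
    annotation: Iterable[GeneAnnotation],
    upstream_bp: int = 500,
    downstream_bp: int = 0,
    low_inclusive: bool = False,
) -> list[PromoterMethylation]:
    """Mean beta of probes in each gene's promoter window.

    The window is [TSS - upstream, TSS + downstream] on the transcribed
    strand; for minus-strand genes it is reflected in genome coordinates.
    Probes are averaged per sample, then across samples; per-cell-type
    means are reported when the table carries sample metadata. Genes with
    no probe in the window get category ``no_probe``.
    """
    out = []
    probes = meth.probes
    for g in annotation:
        start, end = _promoter_window(g.tss, g.strand, upstream_bp, downstream_bp)
        in_window = probes.index[
            (probes["chrom"] == g.chrom)
            & (probes["pos"] >= start)
            & (probes["pos"] <= end)
        ]
        pm = PromoterMethylation(gene_id=g.gene_id, n_probes=len(in_window))
        if len(in_window) == 0:
            out.append(pm)
            continue
        per_sample = meth.beta.loc[in_window].mean(axis=0)
        pm.mean_beta = float(per_sample.mean())
        if meth.samples is not None and "cell_type" in meth.samples.columns:
            cts = meth.samples.loc[per_sample.index, "cell_type"]
            pm.per_cell_type = {
                str(ct): float(v) for ct, v in per_sample.groupby(cts).mean().items()
            }
        pm.category = categorize_beta(pm.mean_beta, low_inclusive=low_inclusive)
        out.append(pm)
    return out


def top_variable_probes(meth: MethylationTable, n: int = 1000) -> MethylationTable:
    """The ``n`` probes with the highest cross-sample variance.

    Ranking is by variance (ddof=1) descending with a deterministic
    tie-break by genomic coordinate then probe id. Asking for more probes
    than exist returns everything with a warning.
    """
    variances = meth.beta.var(axis=1, ddof=1)
    if n > len(variances):
        warnings.warn(
            f"requested {n} probes but only {len(variances)} available; returning all"
        )
        n = len(variances)
    order = pd.DataFrame(
        {
            "var": variances,
            "chrom": meth.probes.loc[variances.index, "chrom"],
            "pos": meth.probes.loc[variances.index, "pos"],
        }
    ).sort_values(["var", "chrom", "pos"], ascending=[False, True, True], kind="mergesort")
    chosen = order.index[:n]
    return MethylationTable(
        meth.beta.loc[chosen], meth.probes.loc[chosen], meth.samples
    )
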