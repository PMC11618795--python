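"""Final per-gene XCI status from ASE, promoter methylation and sex bias.

Decision rule (ASE evidence, when present, is decisive):

* mean ASE deviation <= 0.4           -> escape_ASE
* mean ASE deviation  > 0.4           -> inactive_ASE

Without ASE coverage, promoter methylation and female/male log2FC decide:

* low methylation,  FC > 0.2          -> escape_high  (high confidence)
* low methylation,  0 < FC <= 0.2     -> escape_low   (low confidence)
* methylation >= 0.25, FC < 0.2       -> inactive
* low methylation,  FC <= 0           -> unclassified
* methylation >= 0.25, FC >= 0.2      -> unclassified

The table is exhaustive and mutually exclusive over every input tuple.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import math

import pandas as pd

from .ase import GeneAseCall
from .io_formats import GeneAnnotation
from .methylation import PromoterMethylation
from .sexbias import SexBiasResult

__all__ = [
    "ClassifierThresholds",
    "XciStatusCall",
    "classify_gene",
    "classify_all",
    "compare_with_reference",
    "AgreementReport",
    "STATUS_TO_BINARY",
]

STATUSES = ("escape_ASE", "inactive_ASE", "escape_high", "escape_low", "inactive", "unclassified")
STATUS_TO_BINARY = {
    "escape_ASE": "escape",
    "escape_high": "escape",
    "escape_low": "escape",
    "inactive_ASE": "inactive",
    "inactive": "inactive",
}


@dataclass(frozen=True)
class ClassifierThresholds:
    """Tunable decision boundaries (defaults follow the rule above).

    ``require_significance`` gates the fold-change criterion on the
    sex-bias test p-value: when on, a non-significant FC is treated as 0
    (no evidence of female bias). Off by default — only the FC value
    enters the published rule.
    """

    ase_cut: float = 0.4
    meth_low_cut: float = 0.25
    fc_cut: float = 0.2
    require_significance: bool = False
    p_cut: float = 1e-5

    def as_dict(self) -> dict[str, float]:
        return {
            "ase_cut": self.ase_cut,
            "meth_low_cut": self.meth_low_cut,
            "fc_cut": self.fc_cut,
        }


@dataclass
class XciStatusCall:
    """One gene's final XCI status with its evidence trail."""

    gene_id: str
    status: str
    ase_mean_deviation: float | None = None
    meth_category: str | None = None
    mean_beta: float | None = None
    log2fc: float | None = None
    thresholds: dict[str, float] = field(default_factory=dict)
    reason: str | None = None


def classify_gene(
    ase: GeneAseCall | None,
    meth: PromoterMethylation | None,
    bias: SexBiasResult | None,
    thresholds: ClassifierThresholds = ClassifierThresholds(),
) -> XciStatusCall:
    """Classify one gene; see the module docstring for the decision table."""
    th = thresholds
    call = XciStatusCall(
        gene_id=_gene_id(ase, meth, bias),
        status="unclassified",
        thresholds=th.as_dict(),
    )
    if ase is not None and ase.ase_status != "no_call":
        call.ase_mean_deviation = ase.mean_deviation
        _attach_secondary(call, meth, bias)
        call.status = (
            "escape_ASE" if ase.mean_deviation <= th.ase_cut else "inactive_ASE"
        )
        return call
    has_meth = meth is not None and meth.category != "no_probe"
    if not has_meth:
        _attach_secondary(call, meth, bias)
        call.reason = "no evidence"
        return call
    _attach_secondary(call, meth, bias)
    fc = None if bias is None else bias.log2fc
    if fc is None or (isinstance(fc, float) and math.isnan(fc)):
        call.reason = "no sex-bias estimate"
        return call
    if th.require_significance and bias is not None:
        significant = (not math.isnan(bias.p_value)) and bias.p_value < th.p_cut
        if not significant:
            fc = 0.0
    low_meth = meth.mean_beta < th.meth_low_cut
    if low_meth:
        if fc > th.fc_cut:
            call.status = "escape_high"
        elif fc > 0:
            call.status = "escape_low"
        else:
            call.reason = "low methylation but no female bias"
    else:
        if fc < th.fc_cut:
            call.status = "inactive"
        else:
            call.reason = "methylated but female-biased"
    return call


def classify_all(
    ase_calls: Iterable[GeneAseCall],
    meths: Iterable[PromoterMethylation],
    biases: Iterable[SexBiasResult],
    thresholds: ClassifierThresholds = ClassifierThresholds(),
    genes: Sequence[str] | None = None,
) -> list[XciStatusCall]:
    """Classify every gene appearing in any evidence stream.

    ``genes`` restricts (and orders) the output; by default the union of
    gene ids across the three inputs is classified in sorted order.
    """
    ase_by = {c.gene_id: c for c in ase_calls}
    meth_by = {m.gene_id: m for m in meths}
    bias_by = {b.gene_id: b for b in biases}
    if genes is None:
        genes = sorted(set(ase_by) | set(meth_by) | set(bias_by))
    return [
        classify_gene(ase_by.get(g), meth_by.get(g), bias_by.get(g), thresholds)
        for g in genes
    ]


@dataclass
class AgreementReport:
    """Agreement of binary escape/inactive calls with a prior annotation."""

    confusion: pd.DataFrame  # rows: called, cols: prior
    agreement: float | None  # None when no comparable genes
    n_comparable: int
    n_excluded_unclassified: int
    n_excluded_prior: int  # unknown or variable prior
    reclassified: list[str]


def compare_with_reference(
    calls: Sequence[XciStatusCall], annotation: Iterable[GeneAnnotation]
) -> AgreementReport:
    """Compare binary escape/inactive calls against prior statuses.

    Calls collapse to escape (ASE/high/low confidence merged) or inactive;
    unclassified calls and genes whose prior is unknown or variable are
    excluded from the comparable set. The report lists genes whose call
    contradicts the prior (re-classified genes).
    """
    prior = {g.gene_id: g.prior_status for g in annotation}
    labels = ("escape", "inactive")
    confusion = pd.DataFrame(0, index=labels, columns=labels)
    n_uncls = n_prior_excl = 0
    reclassified = []
    for c in calls:
        binary = STATUS_TO_BINARY.get(c.status)
        if binary is None:
            n_uncls += 1
            continue
        p = prior.get(c.gene_id, "unknown")
        if p not in labels:
            n_prior_excl += 1
            continue
        confusion.loc[binary, p] += 1
        if binary != p:
            reclassified.append(c.gene_id)
    n_comp = int(confusion.to_numpy().sum())
    agreement = None if n_comp == 0 else float(
        (confusion.loc["escape", "escape"] + confusion.loc["inactive", "inactive"]) / n_comp
    )
    return AgreementReport(
        confusion=confusion,
        agreement=agreement,
        n_comparable=n_comp,
        n_excluded_unclassified=n_uncls,
        n_excluded_prior=n_prior_excl,
        reclassified=reclassified,
    )


def _gene_id(*evidence) -> str:
    for e in evidence:
        if e is not None:
            return e.gene_id
    raise ValueError("classify_gene needs at least one evidence object")


def _attach_secondary(
    call: XciStatusCall, meth: PromoterMethylation | None, bias: SexBiasResult | None
) -> None:
    if meth is not None:
        call.meth_category = meth.category
        call.mean_beta = meth.mean_beta
    if bias is not None and not (
        isinstance(bias.log2fc, float) and math.isnan(bias.log2fc)
    ):
        call.log2fc = bias.log2fc
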