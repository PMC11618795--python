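"""Female-vs-male expression bias from a TPM matrix.

Expression is compared on log2(TPM + 0.5); the fold change is
log2((mean_F + eps) / (mean_M + eps)) with eps = 0.5 by default, and
significance comes from a Welch two-sample t-test per gene with
Benjamini-Hochberg correction across tested genes. A gene is flagged
sex-biased when p < 1e-5 and |log2FC| > 0.2 (both configurable).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import ExpressionTable, GeneAnnotation

__all__ = [
    "SexBiasResult",
    "tpm_filter",
    "log2_fold_change",
    "sex_bias_test",
    "group_bias_summary",
]

DEFAULT_EPS = 0.5
DEFAULT_P_CUT = 1e-5
DEFAULT_FC_CUT = 0.2


@dataclass
class SexBiasResult:
    gene_id: str
    log2fc: float
    p_value: float  # NaN when untestable
    q_value: float
    biased: bool
    mean_tpm_f: float
    mean_tpm_m: float


def tpm_filter(table: ExpressionTable, min_mean: float = 1.0) -> ExpressionTable:
    """Drop genes whose mean TPM across all samples is below ``min_mean``
    (strictly: mean < min_mean removed, mean == min_mean kept)."""
    means = table.tpm.mean(axis=1)
    keep = means >= min_mean
    return ExpressionTable(table.tpm.loc[keep], table.samples)


def _sex_columns(
    table: ExpressionTable, normal_karyotype_only: bool = True
) -> tuple[list[str], list[str]]:
    # the female/male contrast is defined on karyotypically normal samples;
    # aneuploid donors (X0) have their own dosage and are excluded by default
    meta = table.samples.loc[list(table.tpm.columns)]
    allowed = {"XX", "XY"} if normal_karyotype_only else None
    cols = [
        s
        for s in table.tpm.columns
        if allowed is None or meta.loc[s, "karyotype"] in allowed
    ]
    f = [s for s in cols if meta.loc[s, "sex"] == "F"]
    m = [s for s in cols if meta.loc[s, "sex"] == "M"]
    return f, m


def log2_fold_change(table: ExpressionTable, gene: str, eps: float = DEFAULT_EPS) -> float:
    """log2((mean female TPM + eps) / (mean male TPM + eps)) for one gene."""
    f_cols, m_cols = _sex_columns(table)
    for sex, cols in (("female", f_cols), ("male", m_cols)):
        if not cols:
            raise ValueError(f"no {sex} samples in the table")
    mean_f = float(table.tpm.loc[gene, f_cols].mean())
    mean_m = float(table.tpm.loc[gene, m_cols].mean())
    return float(np.log2((mean_f + eps) / (mean_m + eps)))


def sex_bias_test(
    table: ExpressionTable,
    eps: float = DEFAULT_EPS,
    p_cut: float = DEFAULT_P_CUT,
    fc_cut: float = DEFAULT_FC_CUT,
) -> list[SexBiasResult]:
    """Per-gene Welch t-test of log2(TPM + eps) between sexes, BH-corrected.

    With fewer than two samples in a sex the p-value is NaN, the gene is
    never flagged biased, and a warning is emitted; fold changes are still
    reported where both sexes have at least one sample.
    """
    f_cols, m_cols = _sex_columns(table)
    for sex, cols in (("female", f_cols), ("male", m_cols)):
        if not cols:
            raise ValueError(f"no {sex} samples in the table")
    fv = np.log2(table.tpm[f_cols].to_numpy() + eps)
    mv = np.log2(table.tpm[m_cols].to_numpy() + eps)
    mean_f = table.tpm[f_cols].mean(axis=1).to_numpy()
    mean_m = table.tpm[m_cols].mean(axis=1).to_numpy()
    log2fc = np.log2((mean_f + eps) / (mean_m + eps))
    testable = len(f_cols) >= 2 and len(m_cols) >= 2
    if testable:
        with np.errstate(divide="ignore", invalid="ignore"):
            t, p = stats.ttest_ind(fv, mv, axis=1, equal_var=False)
        p = np.where(np.isnan(p), 1.0, p)  # zero-variance identical groups
        _, q, _, _ = multipletests(p, method="fdr_bh")
    else:
        warnings.warn("fewer than 2 samples in a sex; p-values unavailable")
        p = np.full(len(log2fc), np.nan)
        q = np.full(len(log2fc), np.nan)
    results = []
    for i, gene in enumerate(table.tpm.index):
        biased = bool(
            testable and p[i] < p_cut and abs(log2fc[i]) > fc_cut
        )
        results.append(
            SexBiasResult(
                gene_id=str(gene),
                log2fc=float(log2fc[i]),
                p_value=float(p[i]),
                q_value=float(q[i]),
                biased=biased,
                mean_tpm_f=float(mean_f[i]),
                mean_tpm_m=float(mean_m[i]),
            )
        )
    return results


def group_bias_summary(
    results: Sequence[SexBiasResult],
    annotation: Iterable[GeneAnnotation],
    cap: float | None = None,
) -> pd.DataFrame:
    """Median and IQR of log2FC per XCI class (PAR / escape / inactive).

    Classes come from the annotation's prior status; PAR membership from
    the region field. ``cap`` truncates reported per-gene values to
    +/- cap for display — statistics are always computed on raw values,
    and capped genes are counted in ``n_capped``.
    """
    ann = {g.gene_id: g for g in annotation}
    rows = []
    for r in results:
        g = ann.get(r.gene_id)
        if g is None:
            continue
        if g.region in ("PAR1", "PAR2"):
            cls = "PAR"
        elif g.prior_status in ("escape", "inactive"):
            cls = g.prior_status
        else:
            continue
        rows.append((cls, r.log2fc))
    df = pd.DataFrame(rows, columns=["xci_class", "log2fc"])
    out = []
    for cls in ("PAR", "escape", "inactive"):
        vals = df.loc[df["xci_class"] == cls, "log2fc"]
        if vals.empty:
            warnings.warn(f"no genes in class {cls}; omitted from summary")
            continue
        q1, med, q3 = vals.quantile([0.25, 0.5, 0.75])
        n_capped = int((vals.abs() > cap).sum()) if cap is not None else 0
        out.append(
            {
                "xci_class": cls,
                "n_genes": len(vals),
                "median_log2fc": float(med),
                "iqr_log2fc": float(q3 - q1),
                "n_capped": n_capped,
            }
        )
    return pd.DataFrame(out).set_index("xci_class")
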