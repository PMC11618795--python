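"""Readers and writers for the plain-TSV tables the pipeline exchanges.

Every table is a diff-able, headered TSV. Genomic coordinates are 1-based
(VCF convention) throughout; BED-style 0-based half-open intervals are
converted on read where they occur (PAR interval configs). Readers validate
strictly and report offending rows by line number rather than silently
dropping them.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "SchemaError",
    "ValidationError",
    "GeneAnnotation",
    "AllelicSite",
    "ExpressionTable",
    "MethylationTable",
    "HG38_PAR1",
    "HG38_PAR2",
    "read_allelic_counts",
    "write_allelic_counts",
    "read_gene_annotation",
    "write_gene_annotation",
    "read_expression",
    "write_expression",
    "read_methylation",
    "write_methylation",
    "read_status_table",
    "write_status_table",
]


class SchemaError(ValueError):
    """A table is missing a required column or has an unknown schema."""


class ValidationError(ValueError):
    """A row violates a domain invariant (reported with its line number)."""


# hg38 pseudoautosomal regions, 1-based inclusive.
HG38_PAR1 = ("chrX", 10_001, 2_781_479)
HG38_PAR2 = ("chrX", 155_701_383, 156_030_895)

REGIONS = ("PAR1", "PAR2", "nonPAR", "autosome")
PRIOR_STATUSES = ("escape", "inactive", "variable", "unknown")


@dataclass(frozen=True)
class GeneAnnotation:
    """Per-gene annotation: position, X-region, prior XCI status.

    ``region`` is one of PAR1/PAR2/nonPAR for chrX genes and ``autosome``
    otherwise. ``prior_status`` is an external (literature) escape/inactive
    assessment used only for comparison, never as classifier input.
    ``immune_flag`` marks membership in the curated immune-gene set.
    """

    gene_id: str
    chrom: str
    tss: int
    strand: str
    region: str = "nonPAR"
    prior_status: str = "unknown"
    immune_flag: bool = False

    def __post_init__(self) -> None:
        if self.tss < 1:
            raise ValidationError(f"{self.gene_id}: tss must be >= 1, got {self.tss}")
        if self.strand not in ("+", "-"):
            raise ValidationError(f"{self.gene_id}: unknown strand {self.strand!r}")
        if self.region not in REGIONS:
            raise ValidationError(f"{self.gene_id}: unknown region {self.region!r}")
        if self.region in ("PAR1", "PAR2") and self.chrom != "chrX":
            raise ValidationError(
                f"{self.gene_id}: region {self.region} only allowed on chrX"
            )
        if self.prior_status not in PRIOR_STATUSES:
            raise ValidationError(
                f"{self.gene_id}: unknown prior_status {self.prior_status!r}"
            )


@dataclass(frozen=True)
class AllelicSite:
    """One heterozygous SNP's RNA and DNA allele counts in one sample.

    For single-cell data ``sample_id`` holds the cell barcode and the DNA
    counts are zero (genotypes come from bulk WES).
    """

    sample_id: str
    cell_type: str
    gene_id: str
    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    rna_ref: int
    rna_alt: int
    dna_ref: int = 0
    dna_alt: int = 0

    def __post_init__(self) -> None:
        for name in ("rna_ref", "rna_alt", "dna_ref", "dna_alt"):
            if getattr(self, name) < 0:
                raise ValidationError(
                    f"{self.gene_id}@{self.chrom}:{self.pos}: negative {name}"
                )
        if self.ref_allele == self.alt_allele:
            raise ValidationError(
                f"{self.gene_id}@{self.chrom}:{self.pos}: ref and alt allele identical"
            )

    @property
    def rna_total(self) -> int:
        return self.rna_ref + self.rna_alt

    @property
    def dna_total(self) -> int:
        return self.dna_ref + self.dna_alt

    @property
    def ref_ratio(self) -> float:
        """Reference ratio RR = rna_ref / (rna_ref + rna_alt)."""
        if self.rna_total == 0:
            raise ValueError("ref_ratio undefined with zero RNA reads")
        return self.rna_ref / self.rna_total

    @property
    def deviation(self) -> float:
        """Allelic deviation D = |RR - 0.5|; 0 = balanced, 0.5 = monoallelic."""
        return abs(self.ref_ratio - 0.5)

    @property
    def rna_minor(self) -> int:
        return min(self.rna_ref, self.rna_alt)


@dataclass
class ExpressionTable:
    """Gene x sample TPM matrix with per-sample metadata.

    ``tpm`` is indexed by gene_id with one column per sample; ``samples``
    is indexed by sample_id and must carry sex ({F,M}), karyotype
    ({XX,XY,X0}), cell_type and individual for every sample.
    """

    tpm: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"sex", "karyotype", "cell_type", "individual"}
        missing = required - set(self.samples.columns)
        if missing:
            raise SchemaError(f"sample metadata missing columns: {sorted(missing)}")
        unmatched = set(self.tpm.columns) - set(self.samples.index)
        if unmatched:
            raise ValidationError(
                f"samples without metadata: {sorted(unmatched)[:5]}"
            )
        if (self.tpm.to_numpy() < 0).any():
            raise ValidationError("TPM values must be non-negative")
        if not self.samples.loc[list(self.tpm.columns), "sex"].isin(["F", "M"]).all():
            raise ValidationError("sex must be F or M")

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionTable":
        return ExpressionTable(
            self.tpm[list(sample_ids)], self.samples.loc[list(sample_ids)]
        )


@dataclass
class MethylationTable:
    """Probe x sample beta-value matrix with probe genomic coordinates.

    ``beta`` is indexed by probe_id; ``probes`` is indexed by probe_id with
    ``chrom`` and 1-based ``pos`` columns. Optional ``samples`` metadata
    (same layout as :class:`ExpressionTable`) enables per-cell-type
    summaries.
    """

    beta: pd.DataFrame
    probes: pd.DataFrame
    samples: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        for col in ("chrom", "pos"):
            if col not in self.probes.columns:
                raise SchemaError(f"probe table missing column: {col}")
        if not self.beta.index.equals(self.probes.index):
            # allow any order, but every beta probe needs coordinates
            missing = set(self.beta.index) - set(self.probes.index)
            if missing:
                raise ValidationError(
                    f"probes without coordinates: {sorted(missing)[:5]}"
                )
        vals = self.beta.to_numpy()
        if ((vals < 0) | (vals > 1)).any():
            raise ValidationError("beta values must lie in [0, 1]")


# ---------------------------------------------------------------------------
# allelic count tables

_BULK_COLUMNS = [
    "sample_id",
    "cell_type",
    "gene_id",
    "chrom",
    "pos",
    "ref_allele",
    "alt_allele",
    "rna_ref",
    "rna_alt",
    "dna_ref",
    "dna_alt",
]
_SC_COLUMNS = [
    "cell_id",
    "cell_type",
    "gene_id",
    "chrom",
    "pos",
    "ref_allele",
    "alt_allele",
    "rna_ref",
    "rna_alt",
]


def read_allelic_counts(path: str | Path, schema: str = "bulk") -> list[AllelicSite]:
    """Read an allelic count TSV into :class:`AllelicSite` records.

    ``schema="bulk"`` expects RNA and DNA (WES) counts per sample;
    ``schema="singlecell"`` expects per-cell RNA counts only (the cell
    barcode column is ``cell_id``). Positions are parsed as 1-based
    integers. Rows violating invariants raise :class:`ValidationError`
    naming the offending line.
    """
    if schema not in ("bulk", "singlecell"):
        raise SchemaError(f"unknown allelic count schema {schema!r}")
    required = _BULK_COLUMNS if schema == "bulk" else _SC_COLUMNS
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
    id_col = "sample_id" if schema == "bulk" else "cell_id"
    sites: list[AllelicSite] = []
    count_cols = ["rna_ref", "rna_alt"] + (
        ["dna_ref", "dna_alt"] if schema == "bulk" else []
    )
    for i, row in enumerate(df.itertuples(index=False), start=2):  # line 1 = header
        rec = dict(zip(df.columns, row))
        try:
            counts = {c: int(rec[c]) for c in count_cols}
            for c, v in counts.items():
                if v < 0:
                    raise ValidationError(f"negative {c}")
            sites.append(
                AllelicSite(
                    sample_id=str(rec[id_col]),
                    cell_type=str(rec["cell_type"]),
                    gene_id=str(rec["gene_id"]),
                    chrom=str(rec["chrom"]),
                    pos=int(rec["pos"]),
                    ref_allele=str(rec["ref_allele"]),
                    alt_allele=str(rec["alt_allele"]),
                    rna_ref=counts["rna_ref"],
                    rna_alt=counts["rna_alt"],
                    dna_ref=counts.get("dna_ref", 0),
                    dna_alt=counts.get("dna_alt", 0),
                )
            )
        except (ValueError, ValidationError) as exc:
            raise ValidationError(f"{path}: line {i}: {exc}") from exc
    return sites


def write_allelic_counts(
    sites: Iterable[AllelicSite], path: str | Path, schema: str = "bulk"
) -> None:
    """Write allelic sites back to TSV; inverse of :func:`read_allelic_counts`."""
    if schema not in ("bulk", "singlecell"):
        raise SchemaError(f"unknown allelic count schema {schema!r}")
    cols = _BULK_COLUMNS if schema == "bulk" else _SC_COLUMNS
    rows = []
    for s in sites:
        rec = dataclasses.asdict(s)
        if schema == "singlecell":
            rec["cell_id"] = rec.pop("sample_id")
        rows.append({c: rec[c] for c in cols})
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def sites_to_frame(sites: Iterable[AllelicSite]) -> pd.DataFrame:
    """Convenience view of a site list as a DataFrame (column order fixed)."""
    return pd.DataFrame([dataclasses.asdict(s) for s in sites], columns=_BULK_COLUMNS)


# ---------------------------------------------------------------------------
# gene annotation

_ANNOT_COLUMNS = ["gene_id", "chrom", "tss", "strand", "region", "prior_status", "immune_flag"]


def classify_region(
    chrom: str,
    pos: int,
    par1: tuple[str, int, int] = HG38_PAR1,
    par2: tuple[str, int, int] = HG38_PAR2,
) -> str:
    """Region label for a position: PAR1/PAR2/nonPAR on chrX, else autosome."""
    if chrom != "chrX":
        return "autosome"
    for label, (c, start, end) in (("PAR1", par1), ("PAR2", par2)):
        if c == chrom and start <= pos <= end:
            return label
    return "nonPAR"


def read_gene_annotation(
    path: str | Path,
    par1: tuple[str, int, int] = HG38_PAR1,
    par2: tuple[str, int, int] = HG38_PAR2,
) -> list[GeneAnnotation]:
    """Read a BED-like gene annotation TSV.

    Required columns: gene_id, chrom, tss (1-based), strand. Optional:
    region (derived from the configured PAR intervals when absent or
    empty), prior_status (default ``unknown``) and immune_flag (0/1).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("gene_id", "chrom", "tss", "strand"):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
    genes: list[GeneAnnotation] = []
    for i, rec in enumerate(df.to_dict("records"), start=2):
        try:
            tss = int(rec["tss"])
            region = rec.get("region")
            if region is None or pd.isna(region) or region == "":
                region = classify_region(str(rec["chrom"]), tss, par1, par2)
            prior = rec.get("prior_status")
            if prior is None or pd.isna(prior) or prior == "":
                prior = "unknown"
            immune = rec.get("immune_flag", "0")
            if immune is None or pd.isna(immune) or immune == "":
                immune = "0"
            genes.append(
                GeneAnnotation(
                    gene_id=str(rec["gene_id"]),
                    chrom=str(rec["chrom"]),
                    tss=tss,
                    strand=str(rec["strand"]),
                    region=str(region),
                    prior_status=str(prior),
                    immune_flag=str(immune) in ("1", "True", "true"),
                )
            )
        except (ValueError, ValidationError) as exc:
            raise ValidationError(f"{path}: line {i}: {exc}") from exc
    return genes


def write_gene_annotation(genes: Iterable[GeneAnnotation], path: str | Path) -> None:
    rows = [
        {
            "gene_id": g.gene_id,
            "chrom": g.chrom,
            "tss": g.tss,
            "strand": g.strand,
            "region": g.region,
            "prior_status": g.prior_status,
            "immune_flag": int(g.immune_flag),
        }
        for g in genes
    ]
    pd.DataFrame(rows, columns=_ANNOT_COLUMNS).to_csv(path, sep="\t", index=False)


def annotation_index(genes: Iterable[GeneAnnotation]) -> dict[str, GeneAnnotation]:
    return {g.gene_id: g for g in genes}


# ---------------------------------------------------------------------------
# expression & methylation matrices

_META_COLUMNS = ["sample_id", "individual", "sex", "karyotype", "cell_type"]


def read_expression(tpm_path: str | Path, meta_path: str | Path) -> ExpressionTable:
    tpm = pd.read_csv(tpm_path, sep="\t", index_col="gene_id")
    meta = pd.read_csv(meta_path, sep="\t", dtype=str)
    for col in _META_COLUMNS:
        if col not in meta.columns:
            raise SchemaError(f"{meta_path}: missing required column {col!r}")
    meta = meta.set_index("sample_id")
    return ExpressionTable(tpm, meta)


def write_expression(table: ExpressionTable, tpm_path: str | Path, meta_path: str | Path) -> None:
    table.tpm.to_csv(tpm_path, sep="\t", index_label="gene_id")
    table.samples.to_csv(meta_path, sep="\t", index_label="sample_id")


def read_methylation(
    beta_path: str | Path, meta_path: str | Path | None = None
) -> MethylationTable:
    """Read a beta-value TSV: probe_id, chrom, pos, then one column per sample."""
    df = pd.read_csv(beta_path, sep="\t")
    for col in ("probe_id", "chrom", "pos"):
        if col not in df.columns:
            raise SchemaError(f"{beta_path}: missing required column {col!r}")
    df = df.set_index("probe_id")
    probes = df[["chrom", "pos"]].copy()
    probes["pos"] = probes["pos"].astype(int)
    beta = df.drop(columns=["chrom", "pos"]).astype(float)
    samples = None
    if meta_path is not None:
        samples = pd.read_csv(meta_path, sep="\t", dtype=str).set_index("sample_id")
    return MethylationTable(beta, probes, samples)


def write_methylation(
    meth: MethylationTable, beta_path: str | Path, meta_path: str | Path | None = None
) -> None:
    out = pd.concat([meth.probes[["chrom", "pos"]], meth.beta], axis=1)
    out.to_csv(beta_path, sep="\t", index_label="probe_id")
    if meta_path is not None and meth.samples is not None:
        meth.samples.to_csv(meta_path, sep="\t", index_label="sample_id")


# ---------------------------------------------------------------------------
# final status table

_STATUS_COLUMNS = [
    "gene_id",
    "status",
    "ase_mean_deviation",
    "meth_category",
    "mean_beta",
    "log2fc",
    "ase_cut",
    "meth_low_cut",
    "fc_cut",
    "reason",
]


def write_status_table(calls: Sequence, path: str | Path) -> None:
    """Write XCI status calls with their evidence trail to TSV.

    Missing optional evidence is written as an empty cell, never ``0``.
    Round-trips losslessly through :func:`read_status_table`.
    """
    if not calls:
        raise ValidationError("refusing to write an empty status table")
    rows = []
    for c in calls:
        rows.append(
            {
                "gene_id": c.gene_id,
                "status": c.status,
                "ase_mean_deviation": _fmt(c.ase_mean_deviation),
                "meth_category": c.meth_category if c.meth_category is not None else "",
                "mean_beta": _fmt(c.mean_beta),
                "log2fc": _fmt(c.log2fc),
                "ase_cut": _fmt(c.thresholds.get("ase_cut")),
                "meth_low_cut": _fmt(c.thresholds.get("meth_low_cut")),
                "fc_cut": _fmt(c.thresholds.get("fc_cut")),
                "reason": c.reason or "",
            }
        )
    pd.DataFrame(rows, columns=_STATUS_COLUMNS).to_csv(path, sep="\t", index=False)


def read_status_table(path: str | Path) -> list:
    from .classifier import XciStatusCall  # local import to avoid a cycle

    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in _STATUS_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
    calls = []
    for rec in df.to_dict("records"):
        thresholds = {
            k: float(rec[k]) for k in ("ase_cut", "meth_low_cut", "fc_cut") if rec[k] != ""
        }
        calls.append(
            XciStatusCall(
                gene_id=rec["gene_id"],
                status=rec["status"],
                ase_mean_deviation=_parse_float(rec["ase_mean_deviation"]),
                meth_category=rec["meth_category"] or None,
                mean_beta=_parse_float(rec["mean_beta"]),
                log2fc=_parse_float(rec["log2fc"]),
                thresholds=thresholds,
                reason=rec["reason"] or None,
            )
        )
    return calls


def _fmt(x) -> str:
    return "" if x is None else repr(float(x))


def _parse_float(s: str) -> float | None:
    return None if s == "" else float(s)
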