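"""Synthetic bulk and single-cell cohorts with known XCI ground truth.

The generator emulates the data structure of a pediatric thymocyte study
design: a handful of XX, XY and X0 individuals profiled across six
developmental cell types with bulk RNA allelic counts at heterozygous
SNPs, matched WES (DNA) allelic counts, a TPM expression matrix, promoter
methylation beta values, and Smart-seq2-style single-cell allelic counts
for one non-skewed female.

Generative model (per female, per gene with Xi/Xa expression ratio rho_g):
a fraction pi of cells share the same active parental haplotype A, so for
a hetSNP whose reference allele sits on A the expected RNA reference
fraction is (pi + (1 - pi) * rho_g) / (1 + rho_g). Inactive genes have
rho_g = leak_fraction * leak_ratio (the bulk expectation of sporadic
reactivation), escape genes rho_g = xi_ratio, PAR and autosomal genes are
balanced at 0.5. DNA counts are Binomial(dna_depth, 0.5); RNA counts are
beta-binomial around the expected fraction. XIST is expressed from Xi
only. XY and X0 samples carry no heterozygous nonPAR chrX sites; X0
additionally loses PAR heterozygosity (single X).

All randomness flows through named substreams spawned from one master
seed (``SeedSequence`` spawn keys), so the same config and seed always
produce byte-identical tables regardless of which outputs are requested.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .io_formats import (
    AllelicSite,
    ExpressionTable,
    GeneAnnotation,
    MethylationTable,
    classify_region,
)
from .singlecell import CellAllelicProfile

__all__ = [
    "ConfigError",
    "IndividualSpec",
    "SimConfig",
    "SimTruth",
    "SimResult",
    "simulate_cohort",
    "simulate_single_cells",
    "simulate_null_expression",
]

CELL_TYPES = ("ETP", "T-C", "DPearly", "DPlate", "CD4SP", "CD8SP")


class ConfigError(ValueError):
    """Invalid simulation configuration (raised before any sampling)."""


@dataclass(frozen=True)
class IndividualSpec:
    """One simulated donor: id, karyotype, and XCI skewing pi.

    ``skewing`` is the fraction of cells whose active X is parental
    haplotype A; 1.0 models complete skewing (cXCI), 0.5 a random mosaic.
    Ignored for XY and X0 karyotypes.
    """

    individual: str
    karyotype: str  # XX | XY | X0
    skewing: float = 0.5


# Default roster mirrors the study design: four XX females (one of them
# completely skewed, one unskewed and used for single cells), three XY
# males and one X0 (Turner syndrome) donor.
DEFAULT_INDIVIDUALS = (
    IndividualSpec("F1", "XX", 0.75),
    IndividualSpec("F2", "XX", 0.60),
    IndividualSpec("F3", "XX", 1.00),
    IndividualSpec("F4", "XX", 0.50),
    IndividualSpec("M1", "XY", 0.5),
    IndividualSpec("M2", "XY", 0.5),
    IndividualSpec("M3", "XY", 0.5),
    IndividualSpec("TS", "X0", 0.5),
)


@dataclass
class SimConfig:
    """All knobs of the synthetic cohort; the defaults ARE the study
    conditions the generator emulates.

    Gene-class sizes put escape genes at ~19% of X-linked genes, the
    accepted 15-20% range. ``xi_ratio`` (Xi/Xa expression of escape genes)
    defaults to 0.4, the midpoint of the 0.22-0.59x female-excess range
    reported for female-biased escape genes, so escape genes emerge with a
    positive female log2FC without it being hard-coded. ``leak_fraction``
    defaults to 0 (high-fidelity XCI); set it to 0.02-0.05 to emulate the
    hypothetical loss-of-XCI subpopulation.
    """

    n_par: int = 8
    n_escape: int = 30
    n_inactive: int = 120
    n_autosome: int = 50

    individuals: tuple[IndividualSpec, ...] = DEFAULT_INDIVIDUALS
    cell_types: tuple[str, ...] = CELL_TYPES

    xi_ratio: float = 0.4
    leak_fraction: float = 0.0
    leak_ratio: float = 1.0

    rna_depth: float = 100.0  # mean RNA reads per site
    dna_depth: int = 60  # WES reads per site (Binomial n)
    overdispersion: float = 0.02  # beta-binomial intra-class correlation
    het_rate: float = 1.5  # mean hetSNPs per gene per XX individual
    het_sites_per_gene: int | None = None  # fixed override of the Poisson draw

    expr_base_log_mean: float = 3.4  # ln-scale baseline TPM (~30)
    expr_base_log_sd: float = 1.0
    expr_noise_log2_sd: float = 0.2  # per-sample multiplicative noise

    # per-class Beta(a, b) for promoter probe beta values
    meth_params: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "escape": (4.0, 36.0),
            "PAR": (4.0, 36.0),
            "inactive": (30.0, 30.0),
            "autosome": (4.0, 36.0),
            "xist": (30.0, 30.0),
        }
    )

    # single-cell block
    sc_individual: str = "F4"
    n_cells_per_type: int = 75
    sc_detect_prob: float = 0.35  # per-cell chance a hetSNP gene is captured
    sc_reads_mean: float = 3.0  # mean reads per detected SNP (>=1)
    xist_detect_prob: float = 0.30
    qc_fail_fraction: float = 0.10

    seed: int = 0

    def validate(self) -> None:
        if min(self.n_par, self.n_escape, self.n_inactive, self.n_autosome) < 0:
            raise ConfigError("gene-class counts must be non-negative")
        ids = [i.individual for i in self.individuals]
        if len(set(ids)) != len(ids):
            raise ConfigError("duplicate individual ids")
        for ind in self.individuals:
            if ind.karyotype not in ("XX", "XY", "X0"):
                raise ConfigError(f"{ind.individual}: unknown karyotype {ind.karyotype}")
            if not 0.5 <= ind.skewing <= 1.0:
                raise ConfigError(f"{ind.individual}: skewing must be in [0.5, 1]")
        if self.xi_ratio < 0 or self.leak_ratio < 0:
            raise ConfigError("xi_ratio and leak_ratio must be >= 0")
        if not 0.0 <= self.leak_fraction <= 1.0:
            raise ConfigError("leak_fraction must be in [0, 1]")
        if self.rna_depth <= 0 or self.dna_depth <= 0:
            raise ConfigError("depths must be positive")
        if self.overdispersion < 0:
            raise ConfigError("overdispersion must be >= 0")
        for p in (self.sc_detect_prob, self.xist_detect_prob, self.qc_fail_fraction):
            if not 0.0 <= p <= 1.0:
                raise ConfigError("probabilities must be in [0, 1]")
        for cls, (a, b) in self.meth_params.items():
            if a <= 0 or b <= 0:
                raise ConfigError(f"meth_params[{cls}]: Beta parameters must be > 0")


@dataclass
class SimTruth:
    """Ground truth behind a synthetic cohort.

    genes: gene_id -> true class (PAR/escape/inactive/autosome/xist) etc.
    sites: every simulated hetSNP with its phase (``ref_on_A``).
    individuals: karyotype and true skewing pi per donor.
    cells: filled by :func:`simulate_single_cells` (true Xi haplotype,
    injected QC failure flag).
    """

    genes: pd.DataFrame
    sites: pd.DataFrame
    individuals: pd.DataFrame
    cells: pd.DataFrame | None = None
    leak_events: set[tuple[str, str]] = field(default_factory=set)  # (cell_id, gene_id)

    def phase_map(self, individual: str) -> dict[tuple[str, int], bool]:
        """(gene_id, pos) -> ref allele on haplotype A, for one donor."""
        sub = self.sites[self.sites["individual"] == individual]
        return {
            (g, int(p)): bool(r)
            for g, p, r in zip(sub["gene_id"], sub["pos"], sub["ref_on_A"])
        }


@dataclass
class SimResult:
    """Bundle returned by :func:`simulate_cohort`."""

    expression: ExpressionTable
    allelic_sites: list[AllelicSite]
    methylation: MethylationTable
    annotation: list[GeneAnnotation]
    truth: SimTruth
    config: SimConfig


def _rng(seed: int, key: int) -> np.random.Generator:
    # named substream: immune to call-order changes elsewhere
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(key,)))


_K_GENES, _K_PHASE, _K_EXPR, _K_RNA, _K_DNA, _K_METH, _K_CELLS = range(1, 8)


def _betabinom(rng: np.random.Generator, n: int, p: float, icc: float) -> int:
    """Beta-binomial draw with intra-class correlation ``icc`` (0 = binomial)."""
    if n == 0:
        return 0
    p = min(max(p, 0.0), 1.0)
    if icc <= 0 or p in (0.0, 1.0):
        return int(rng.binomial(n, p))
    c = (1.0 - icc) / icc
    q = rng.beta(p * c, (1.0 - p) * c)
    return int(rng.binomial(n, q))


def _expected_ref_fraction(pi_a: float, rho: float, ref_on_a: bool) -> float:
    p_a = (pi_a + (1.0 - pi_a) * rho) / (1.0 + rho)
    return p_a if ref_on_a else 1.0 - p_a


def _build_genes(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    # PAR1 genes inside the hg38 PAR1 interval, nonPAR genes spread along
    # the rest of chrX, autosomes on chr1.
    par_pos = np.linspace(100_000, 2_700_000, max(config.n_par, 1), dtype=int)
    for i in range(config.n_par):
        rows.append(("PARG%03d" % (i + 1), "chrX", int(par_pos[i]), "PAR"))
    nonpar = config.n_escape + config.n_inactive + 1  # +1 for XIST
    nonpar_pos = np.linspace(3_500_000, 154_000_000, nonpar, dtype=int)
    k = 0
    for i in range(config.n_escape):
        rows.append(("ESCG%03d" % (i + 1), "chrX", int(nonpar_pos[k]), "escape"))
        k += 1
    for i in range(config.n_inactive):
        rows.append(("INAG%03d" % (i + 1), "chrX", int(nonpar_pos[k]), "inactive"))
        k += 1
    rows.append(("XIST", "chrX", int(nonpar_pos[k]), "xist"))
    auto_pos = np.linspace(1_000_000, 240_000_000, max(config.n_autosome, 1), dtype=int)
    for i in range(config.n_autosome):
        rows.append(("AUTG%03d" % (i + 1), "chr1", int(auto_pos[i]), "autosome"))
    df = pd.DataFrame(rows, columns=["gene_id", "chrom", "tss", "true_class"])
    df["strand"] = np.where(np.arange(len(df)) % 2 == 0, "+", "-")
    df["region"] = [classify_region(c, t) for c, t in zip(df["chrom"], df["tss"])]
    # baseline expression per gene
    df["base_tpm"] = np.exp(
        rng.normal(config.expr_base_log_mean, config.expr_base_log_sd, len(df))
    )
    # a subset of inactive genes double as immune genes so immune-set
    # summaries have members
    immune = np.zeros(len(df), dtype=bool)
    ina_idx = df.index[df["true_class"] == "inactive"]
    immune[ina_idx[: max(len(ina_idx) // 6, 0)]] = True
    df["immune_flag"] = immune
    return df


def _rho_for_class(cls: str, config: SimConfig) -> float | None:
    """Xi/Xa expression ratio entering the allelic model; None = balanced."""
    if cls == "escape":
        return config.xi_ratio
    if cls == "inactive":
        return config.leak_fraction * config.leak_ratio
    if cls == "xist":
        return None  # handled specially: expressed from Xi only
    return None  # PAR / autosome: balanced


def _simulate_sites(
    config: SimConfig, genes: pd.DataFrame, rng_phase: np.random.Generator,
    rng_rna: np.random.Generator, rng_dna: np.random.Generator,
) -> tuple[list[AllelicSite], pd.DataFrame]:
    alleles = ("A", "C", "G", "T")
    site_rows = []
    sites: list[AllelicSite] = []
    for ind in config.individuals:
        pi_a = ind.skewing
        for g in genes.itertuples(index=False):
            cls = g.true_class
            # heterozygosity by karyotype
            if ind.karyotype == "X0" and g.chrom == "chrX":
                continue  # single X: hemizygous everywhere, PAR included
            if ind.karyotype == "XY" and g.chrom == "chrX" and g.region == "nonPAR":
                continue  # hemizygous nonPAR X in males
            if cls == "xist":
                # exactly one XIST hetSNP per female: the cluster-seeding
                # convention (cluster 1 = XIST reference allele) is defined
                # relative to a single marker SNP
                n_sites = 1 if ind.karyotype == "XX" else 0
            elif config.het_sites_per_gene is not None:
                n_sites = config.het_sites_per_gene
            else:
                n_sites = int(rng_phase.poisson(config.het_rate))
            for s in range(n_sites):
                pos = int(g.tss) + 200 + 150 * s
                ref_on_a = bool(rng_phase.random() < 0.5)
                a_i = int(rng_phase.integers(0, 4))
                ref, alt = alleles[a_i], alleles[(a_i + 1) % 4]
                site_rows.append(
                    (ind.individual, g.gene_id, g.chrom, pos, cls, ref_on_a)
                )
                if cls == "xist":
                    # XIST transcribed from Xi only: reference fraction is
                    # the fraction of cells whose Xi carries the ref allele
                    p_ref = (1.0 - pi_a) if ref_on_a else pi_a
                elif g.chrom != "chrX" or g.region in ("PAR1", "PAR2"):
                    p_ref = 0.5
                else:
                    rho = _rho_for_class(cls, config)
                    p_ref = _expected_ref_fraction(pi_a, rho or 0.0, ref_on_a)
                for ct in config.cell_types:
                    n_rna = int(rng_rna.poisson(config.rna_depth))
                    rna_ref = _betabinom(rng_rna, n_rna, p_ref, config.overdispersion)
                    dna_ref = int(rng_dna.binomial(config.dna_depth, 0.5))
                    sites.append(
                        AllelicSite(
                            sample_id=f"{ind.individual}_{ct}",
                            cell_type=ct,
                            gene_id=g.gene_id,
                            chrom=g.chrom,
                            pos=pos,
                            ref_allele=ref,
                            alt_allele=alt,
                            rna_ref=rna_ref,
                            rna_alt=n_rna - rna_ref,
                            dna_ref=dna_ref,
                            dna_alt=config.dna_depth - dna_ref,
                        )
                    )
    site_df = pd.DataFrame(
        site_rows,
        columns=["individual", "gene_id", "chrom", "pos", "true_class", "ref_on_A"],
    )
    return sites, site_df


def _copy_factor(cls: str, karyotype: str, config: SimConfig) -> float:
    """Relative expression dosage by gene class and karyotype (Xa of XX = 1)."""
    if cls == "autosome":
        return 2.0
    if cls == "xist":
        return 1.0 if karyotype == "XX" else 0.02  # silent without an Xi
    if cls == "PAR":
        return {"XX": 2.0, "XY": 2.0, "X0": 1.0}[karyotype]
    if karyotype in ("XY", "X0"):
        return 1.0
    if cls == "escape":
        return 1.0 + config.xi_ratio
    return 1.0 + config.leak_fraction * config.leak_ratio  # inactive


def _simulate_expression(
    config: SimConfig, genes: pd.DataFrame, rng: np.random.Generator
) -> ExpressionTable:
    sample_ids, meta_rows = [], []
    for ind in config.individuals:
        sex = "F" if ind.karyotype in ("XX", "X0") else "M"
        for ct in config.cell_types:
            sid = f"{ind.individual}_{ct}"
            sample_ids.append(sid)
            meta_rows.append((sid, ind.individual, sex, ind.karyotype, ct))
    tpm = np.empty((len(genes), len(sample_ids)))
    karyos = [m[3] for m in meta_rows]
    for j, karyo in enumerate(karyos):
        copy = np.array(
            [_copy_factor(c, karyo, config) for c in genes["true_class"]]
        )
        noise = np.exp2(rng.normal(0.0, config.expr_noise_log2_sd, len(genes)))
        tpm[:, j] = genes["base_tpm"].to_numpy() * copy / 2.0 * noise
    tpm_df = pd.DataFrame(tpm, index=genes["gene_id"].to_numpy(), columns=sample_ids)
    tpm_df.index.name = "gene_id"
    meta = pd.DataFrame(
        meta_rows, columns=["sample_id", "individual", "sex", "karyotype", "cell_type"]
    ).set_index("sample_id")
    return ExpressionTable(tpm_df, meta)


def _simulate_methylation(
    config: SimConfig, genes: pd.DataFrame, rng: np.random.Generator
) -> MethylationTable:
    # methylation is profiled on female (XX) donors only, as in the study
    females = [i for i in config.individuals if i.karyotype == "XX"]
    sample_ids, meta_rows = [], []
    for ind in females:
        for ct in config.cell_types:
            sid = f"{ind.individual}_{ct}"
            sample_ids.append(sid)
            meta_rows.append((sid, ind.individual, "F", "XX", ct))
    probe_rows, beta_rows = [], []
    probe_n = 0
    for g in genes.itertuples(index=False):
        a, b = config.meth_params[g.true_class if g.true_class != "PAR" else "PAR"]
        n_prom = 1 + int(rng.poisson(1.0))
        offsets = rng.integers(-450, -40, n_prom)  # inside the -500 TSS window
        # one distal gene-body probe outside the promoter window, drawn
        # from an intermediate Beta regardless of class
        for off, dist in [(int(o), False) for o in offsets] + [(1500, True)]:
            probe_n += 1
            pid = "cg%07d" % probe_n
            if g.strand == "+":
                pos = int(g.tss) + off
            else:
                pos = int(g.tss) - off
            aa, bb = (10.0, 10.0) if dist else (a, b)
            beta = rng.beta(aa, bb, len(sample_ids))
            probe_rows.append((pid, g.chrom, max(pos, 1)))
            beta_rows.append(beta)
    probes = pd.DataFrame(probe_rows, columns=["probe_id", "chrom", "pos"]).set_index(
        "probe_id"
    )
    beta = pd.DataFrame(
        np.vstack(beta_rows), index=probes.index, columns=sample_ids
    )
    meta = pd.DataFrame(
        meta_rows, columns=["sample_id", "individual", "sex", "karyotype", "cell_type"]
    ).set_index("sample_id")
    return MethylationTable(beta, probes, meta)


def simulate_cohort(config: SimConfig | None = None) -> SimResult:
    """Generate a full bulk cohort (expression, allelic counts, methylation,
    annotation) plus its ground truth.

    Identical config (including ``seed``) always yields identical output.
    """
    config = config or SimConfig()
    config.validate()
    seed = config.seed
    genes = _build_genes(config, _rng(seed, _K_GENES))
    sites, site_df = _simulate_sites(
        config, genes, _rng(seed, _K_PHASE), _rng(seed, _K_RNA), _rng(seed, _K_DNA)
    )
    expression = _simulate_expression(config, genes, _rng(seed, _K_EXPR))
    methylation = _simulate_methylation(config, genes, _rng(seed, _K_METH))
    prior_map = {"PAR": "escape", "escape": "escape", "inactive": "inactive",
                 "autosome": "unknown", "xist": "unknown"}
    annotation = [
        GeneAnnotation(
            gene_id=g.gene_id,
            chrom=g.chrom,
            tss=int(g.tss),
            strand=g.strand,
            region=g.region,
            prior_status=prior_map[g.true_class],
            immune_flag=bool(g.immune_flag),
        )
        for g in genes.itertuples(index=False)
    ]
    individuals = pd.DataFrame(
        [(i.individual, i.karyotype, i.skewing) for i in config.individuals],
        columns=["individual", "karyotype", "pi"],
    )
    truth = SimTruth(genes=genes, sites=site_df, individuals=individuals)
    return SimResult(expression, sites, methylation, annotation, truth, config)


def simulate_single_cells(
    config: SimConfig, truth: SimTruth
) -> list[CellAllelicProfile]:
    """Simulate Smart-seq2-style per-cell allelic counts for the configured
    single-cell donor, using the bulk truth's phases.

    Each cell draws a true Xi haplotype (B with probability pi, A with
    1 - pi). Reads at inactive genes come only from the active haplotype
    unless the (cell, gene) pair is a leak event; XIST reads come only
    from the Xi haplotype; escape genes emit Xi reads at rate
    xi_ratio / (1 + xi_ratio) per read. A ``qc_fail_fraction`` of cells is
    injected with out-of-range QC metrics so that QC filtering has true
    positives. Updates ``truth.cells`` and ``truth.leak_events`` in place.
    """
    config.validate()
    rng = _rng(config.seed, _K_CELLS)
    ind = next(
        (i for i in config.individuals if i.individual == config.sc_individual), None
    )
    if ind is None or ind.karyotype != "XX":
        raise ConfigError("sc_individual must name an XX donor in the roster")
    pi_a = ind.skewing
    sub = truth.sites[truth.sites["individual"] == ind.individual]
    snps = list(
        sub[["gene_id", "pos", "true_class", "ref_on_A"]].itertuples(index=False)
    )
    cells: list[CellAllelicProfile] = []
    cell_rows = []
    leak_events: set[tuple[str, str]] = set()
    for ct in config.cell_types:
        for i in range(config.n_cells_per_type):
            cell_id = f"{ct}_c{i + 1:03d}"
            active = "A" if rng.random() < pi_a else "B"
            xi = "B" if active == "A" else "A"
            counts: dict[tuple[str, int], tuple[int, int]] = {}
            leaked_genes: set[str] = set()
            for snp in snps:
                gene, pos, cls, ref_on_a = (
                    snp.gene_id, int(snp.pos), snp.true_class, bool(snp.ref_on_A),
                )
                if cls == "xist":
                    if rng.random() >= config.xist_detect_prob:
                        continue
                    k = 1 + int(rng.poisson(config.sc_reads_mean - 1))
                    from_xi = k  # XIST: Xi only
                elif cls == "autosome":
                    continue  # single-cell panel is X-focused
                else:
                    if rng.random() >= config.sc_detect_prob:
                        continue
                    k = 1 + int(rng.poisson(config.sc_reads_mean - 1))
                    if cls == "escape":
                        p_xi = config.xi_ratio / (1.0 + config.xi_ratio)
                        from_xi = int(rng.binomial(k, p_xi))
                    elif cls == "inactive":
                        if config.leak_fraction > 0 and rng.random() < config.leak_fraction:
                            leaked_genes.add(gene)
                            p_xi = config.leak_ratio / (1.0 + config.leak_ratio)
                            from_xi = int(rng.binomial(k, p_xi))
                        else:
                            from_xi = 0
                    else:  # PAR: both copies active
                        from_xi = int(rng.binomial(k, 0.5))
                # map haplotype reads to ref/alt via phase
                xi_is_ref = (xi == "A") == ref_on_a
                ref = from_xi if xi_is_ref else k - from_xi
                counts[(gene, pos)] = (ref, k - ref)
            qc_fail = bool(rng.random() < config.qc_fail_fraction)
            if qc_fail:
                mode = int(rng.integers(0, 3))
                if mode == 0:
                    total_reads = int(rng.integers(20_000, 124_000))
                    mito, ribo = 0.05, 0.10
                elif mode == 1:
                    total_reads = int(rng.integers(300_000, 800_000))
                    mito, ribo = float(rng.uniform(0.12, 0.5)), 0.10
                else:
                    total_reads = int(rng.integers(300_000, 800_000))
                    mito, ribo = 0.05, float(rng.uniform(0.22, 0.6))
            else:
                total_reads = int(rng.integers(150_000, 950_000))
                mito = float(rng.uniform(0.0, 0.09))
                ribo = float(rng.uniform(0.0, 0.18))
            cells.append(
                CellAllelicProfile(
                    cell_id=cell_id,
                    cell_type=ct,
                    counts=counts,
                    total_reads=total_reads,
                    mito_fraction=mito,
                    ribo_fraction=ribo,
                )
            )
            cell_rows.append((cell_id, ct, xi, qc_fail))
            leak_events.update((cell_id, g) for g in leaked_genes)
    truth.cells = pd.DataFrame(
        cell_rows, columns=["cell_id", "cell_type", "xi_haplotype", "qc_fail"]
    )
    truth.leak_events = leak_events
    return cells


def simulate_null_expression(
    n_genes: int = 2000,
    n_per_sex: int = 20,
    seed: int = 0,
    noise_log2_sd: float = 0.5,
) -> ExpressionTable:
    """Expression matrix with NO sex effect, for type-I error calibration.

    Every gene's TPM is lognormal noise around a shared baseline in both
    sexes; any sex-bias test should then reject at its nominal rate.
    """
    rng = _rng(seed, 99)
    base = np.exp(rng.normal(3.4, 1.0, n_genes))
    sample_ids, meta_rows = [], []
    for sex, karyo, prefix in (("F", "XX", "NF"), ("M", "XY", "NM")):
        for i in range(n_per_sex):
            sid = f"{prefix}{i + 1:02d}"
            sample_ids.append(sid)
            meta_rows.append((sid, sid, sex, karyo, "bulk"))
    noise = np.exp2(rng.normal(0.0, noise_log2_sd, (n_genes, len(sample_ids))))
    tpm = pd.DataFrame(
        base[:, None] * noise,
        index=[f"NULLG%05d" % (i + 1) for i in range(n_genes)],
        columns=sample_ids,
    )
    tpm.index.name = "gene_id"
    meta = pd.DataFrame(
        meta_rows, columns=["sample_id", "individual", "sex", "karyotype", "cell_type"]
    ).set_index("sample_id")
    return ExpressionTable(tpm, meta)
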