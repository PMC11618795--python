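import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from xcimap.ase import GeneAseCall
from xcimap.classifier import (
    AgreementReport,
    ClassifierThresholds,
    STATUS_TO_BINARY,
    XciStatusCall,
    classify_all,
    classify_gene,
    compare_with_reference,
)
from xcimap.io_formats import GeneAnnotation
from xcimap.methylation import PromoterMethylation, categorize_beta
from xcimap.sexbias import SexBiasResult


def _ase(gene="G", deviation=None):
    call = GeneAseCall(gene_id=gene)
    if deviation is not None:
        call.mean_deviation = deviation
        call.ase_status = "inactive" if deviation > 0.4 else "escape"
    return call


def _meth(gene="G", beta=None):
    pm = PromoterMethylation(gene_id=gene)
    if beta is not None:
        pm.mean_beta = beta
        pm.category = categorize_beta(beta)
        pm.n_probes = 2
    return pm


def _bias(gene="G", fc=0.0, p=1e-7):
    return SexBiasResult(gene, fc, p, p, abs(fc) > 0.2 and p < 1e-5, 1, 1)


def oracle_status(deviation, beta, fc):
    """Independent restatement of the published decision rules."""
    if deviation is not None:
        return "escape_ASE" if deviation <= 0.4 else "inactive_ASE"
    if beta is None or fc is None:
        return "unclassified"
    if beta < 0.25:
        if fc > 0.2:
            return "escape_high"
        if fc > 0:
            return "escape_low"
        return "unclassified"
    if fc < 0.2:
        return "inactive"
    return "unclassified"


class TestDecisionTable:
    def test_ase_overrides_methylation(self):
        call = classify_gene(_ase(deviation=0.2), _meth(beta=0.9), _bias(fc=-0.5))
        assert call.status == "escape_ASE"

    def test_meth_and_bias_escape_high(self):
        call = classify_gene(None, _meth(beta=0.10), _bias(fc=0.30))
        assert call.status == "escape_high"

    def test_low_meth_without_female_bias_unclassified(self):
        call = classify_gene(None, _meth(beta=0.10), _bias(fc=-0.10))
        assert call.status == "unclassified"

    def test_no_evidence_reason(self):
        call = classify_gene(None, _meth(beta=None), _bias(fc=0.5))
        assert call.status == "unclassified" and call.reason == "no evidence"

    def test_boundary_grid_matches_oracle(self):
        deviations = [None, 0.0, 0.2, 0.4, 0.41, 0.5]
        betas = [0.0, 0.1, 0.24, 0.25, 0.26, 0.5, 0.75, 0.76, 1.0]
        fcs = [-0.3, 0.0, 0.1, 0.2, 0.21, 0.5]
        for d in deviations:
            for b in betas:
                for fc in fcs:
                    call = classify_gene(_ase(deviation=d), _meth(beta=b), _bias(fc=fc))
                    assert call.status == oracle_status(d, b, fc), (d, b, fc)

    @settings(max_examples=200, derandomize=True)
    @given(
        st.one_of(st.none(), st.floats(0, 0.5)),
        st.floats(0, 1),
        st.floats(-1, 1),
    )
    def test_exhaustive_and_exclusive(self, d, b, fc):
        call = classify_gene(_ase(deviation=d), _meth(beta=b), _bias(fc=fc))
        assert call.status in (
            "escape_ASE", "inactive_ASE", "escape_high", "escape_low",
            "inactive", "unclassified",
        )
        assert call.status == oracle_status(d, b, fc)

    def test_significance_gate_config(self):
        th = ClassifierThresholds(require_significance=True)
        # non-significant female bias is treated as no bias
        call = classify_gene(None, _meth(beta=0.10), _bias(fc=0.5, p=0.5), th)
        assert call.status == "unclassified"
        call = classify_gene(None, _meth(beta=0.5), _bias(fc=0.5, p=0.5), th)
        assert call.status == "inactive"

    def test_reclassification_is_stable(self):
        """Re-running the classifier on evidence reconstructed from its own
        output reproduces the same statuses."""
        cases = [
            (_ase(deviation=0.1), _meth(beta=0.5), _bias(fc=0.0)),
            (None, _meth(beta=0.1), _bias(fc=0.3)),
            (None, _meth(beta=0.6), _bias(fc=0.05)),
            (None, _meth(beta=0.1), _bias(fc=-0.2)),
        ]
        for ase, meth, bias in cases:
            first = classify_gene(ase, meth, bias)
            ase2 = _ase(deviation=first.ase_mean_deviation)
            meth2 = _meth(beta=first.mean_beta)
            bias2 = _bias(fc=first.log2fc) if first.log2fc is not None else None
            second = classify_gene(ase2, meth2, bias2)
            assert second.status == first.status


class TestClassifyAll:
    def test_union_of_genes_covered(self):
        calls = classify_all(
            [_ase("A", 0.1)], [_meth("B", 0.5)], [_bias("C", 0.3)]
        )
        assert [c.gene_id for c in calls] == ["A", "B", "C"]
        by = {c.gene_id: c.status for c in calls}
        assert by["A"] == "escape_ASE"
        assert by["B"] == "unclassified"  # meth without bias estimate
        assert by["C"] == "unclassified"  # bias without meth


class TestCompareWithReference:
    def _annot(self, priors):
        return [
            GeneAnnotation(g, "chrX", 1_000_000 * (i + 3), "+", "nonPAR", p)
            for i, (g, p) in enumerate(priors.items())
        ]

    def _call(self, gene, status):
        return XciStatusCall(gene_id=gene, status=status)

    def test_perfect_agreement(self):
        annot = self._annot({"A": "escape", "B": "inactive"})
        calls = [self._call("A", "escape_high"), self._call("B", "inactive_ASE")]
        report = compare_with_reference(calls, annot)
        assert report.agreement == 1.0 and report.reclassified == []

    def test_partial_agreement_counts(self):
        annot = self._annot(
            {"A": "escape", "B": "inactive", "C": "inactive", "D": "escape"}
        )
        calls = [
            self._call("A", "escape_ASE"),
            self._call("B", "inactive"),
            self._call("C", "inactive_ASE"),
            self._call("D", "inactive"),  # disagrees
        ]
        report = compare_with_reference(calls, annot)
        assert report.agreement == pytest.approx(0.75)
        assert report.reclassified == ["D"]
        assert report.n_comparable == 4

    def test_all_unclassified_gives_undefined_agreement(self):
        annot = self._annot({"A": "escape"})
        report = compare_with_reference([self._call("A", "unclassified")], annot)
        assert report.agreement is None and report.n_comparable == 0

    def test_unknown_and_variable_priors_excluded(self):
        annot = self._annot({"A": "unknown", "B": "variable", "C": "escape"})
        calls = [
            self._call("A", "escape_low"),
            self._call("B", "inactive"),
            self._call("C", "escape_high"),
        ]
        report = compare_with_reference(calls, annot)
        assert report.n_comparable == 1 and report.n_excluded_prior == 2


class TestSyntheticRecovery:
    def test_cohort_classification_accuracy(self, cohort):
        """Combined classifier recovers simulated statuses: >=90% of
        ASE-covered genes, >=80% of genes seen only through methylation
        and sex bias (the weaker evidence channel)."""
        from xcimap.ase import run_ase
        from xcimap.methylation import promoter_mean_beta
        from xcimap.sexbias import sex_bias_test, tpm_filter

        f3 = [s for s in cohort.allelic_sites if s.sample_id.startswith("F3_")]
        ase_calls = run_ase(f3)
        proms = promoter_mean_beta(cohort.methylation, cohort.annotation)
        biases = sex_bias_test(tpm_filter(cohort.expression))
        xgenes = [
            g.gene_id for g in cohort.annotation
            if g.chrom == "chrX" and g.gene_id != "XIST"
        ]
        calls = classify_all(ase_calls, proms, biases, genes=xgenes)
        classes = dict(zip(cohort.truth.genes.gene_id, cohort.truth.genes.true_class))
        ase_genes = {c.gene_id for c in ase_calls if c.ase_status != "no_call"}
        acc = {"ase": [], "meth_bias": []}
        for c in calls:
            want = "inactive" if classes[c.gene_id] == "inactive" else "escape"
            got = STATUS_TO_BINARY.get(c.status)
            acc["ase" if c.gene_id in ase_genes else "meth_bias"].append(got == want)
        assert np.mean(acc["ase"]) >= 0.90
        assert np.mean(acc["meth_bias"]) >= 0.80
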