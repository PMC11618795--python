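import numpy as np
import pytest

from xcimap.singlecell import (
    AnchorSnp,
    CellAllelicProfile,
    ClusterAssignment,
    assign_by_xist,
    call_snp_escape,
    find_anchor_genes,
    infer_xi_alleles,
    propagate_clusters,
    qc_filter_cells,
    xi_alleles_from_phases,
    xi_read_histogram,
)


def _cell(cell_id, counts, reads=400_000, mito=0.05, ribo=0.10, ct="ETP"):
    return CellAllelicProfile(
        cell_id=cell_id, cell_type=ct, counts=counts,
        total_reads=reads, mito_fraction=mito, ribo_fraction=ribo,
    )


XIST = ("XIST", 1000)
G1 = ("GENE1", 2000)
G2 = ("GENE2", 3000)


class TestQcFilter:
    @pytest.mark.parametrize(
        "kwargs,kept",
        [
            (dict(mito=0.12), False),
            (dict(ribo=0.25), False),
            (dict(reads=100_000), False),
            (dict(reads=1_200_000), False),
            (dict(reads=125_000), True),  # boundary inclusive
            (dict(reads=1_000_000, mito=0.10, ribo=0.20), True),
            (dict(), True),
        ],
    )
    def test_thresholds(self, kwargs, kept):
        cells = [_cell("c1", {}, **kwargs)]
        assert (len(qc_filter_cells(cells)) == 1) is kept

    def test_matches_rule_on_synthetic(self, sc_setup):
        _, _, cells = sc_setup
        kept = {c.cell_id for c in qc_filter_cells(cells)}
        for c in cells:
            want = (
                c.mito_fraction <= 0.10
                and c.ribo_fraction <= 0.20
                and 125_000 <= c.total_reads <= 1_000_000
            )
            assert (c.cell_id in kept) is want


class TestAssignByXist:
    def test_allele_determines_cluster(self):
        cells = [
            _cell("c1", {XIST: (3, 0)}),
            _cell("c2", {XIST: (0, 2)}),
            _cell("c3", {XIST: (1, 1)}),
            _cell("c4", {G1: (2, 0)}),
        ]
        a = {x.cell_id: x for x in assign_by_xist(cells)}
        assert a["c1"].cluster == 1 and a["c1"].basis == "XIST"
        assert a["c2"].cluster == 2
        assert a["c3"].cluster is None and a["c3"].basis == "conflict"
        assert a["c4"].cluster is None and a["c4"].basis == "none"

    def test_no_xist_anywhere_warns(self):
        with pytest.warns(UserWarning):
            out = assign_by_xist([_cell("c1", {G1: (2, 0)})])
        assert all(x.cluster is None for x in out)


def _seeded_cells():
    """Six XIST-assigned cells, three per cluster, plus unassigned ones."""
    return [
        _cell("x1", {XIST: (2, 0), G1: (0, 3), G2: (1, 0)}),
        _cell("x2", {XIST: (1, 0), G1: (0, 2), G2: (2, 0)}),
        _cell("x3", {XIST: (4, 0), G1: (0, 1), G2: (1, 0)}),
        _cell("y1", {XIST: (0, 2), G1: (2, 0), G2: (1, 0)}),
        _cell("y2", {XIST: (0, 1), G1: (3, 0), G2: (2, 0)}),
        _cell("y3", {XIST: (0, 3), G1: (1, 0), G2: (3, 0)}),
        _cell("u1", {G1: (0, 2)}),
        _cell("u2", {G1: (4, 0)}),
        _cell("u3", {}),
    ]


class TestAnchors:
    def test_opposed_monoallelic_gene_is_anchor(self):
        cells = _seeded_cells()
        anchors = find_anchor_genes(cells, assign_by_xist(cells))
        assert [a.gene_id for a in anchors] == ["GENE1"]
        (a,) = anchors
        assert a.cluster1_allele == "alt" and a.cluster2_allele == "ref"

    def test_biallelic_cell_disqualifies(self):
        cells = _seeded_cells()
        cells[0].counts[G1] = (1, 3)  # cluster-1 cell shows both alleles
        anchors = find_anchor_genes(cells, assign_by_xist(cells))
        assert anchors == []

    def test_same_allele_in_both_clusters_not_discriminating(self):
        cells = _seeded_cells()
        anchors = find_anchor_genes(cells, assign_by_xist(cells))
        assert all(a.gene_id != "GENE2" for a in anchors)  # ref in both clusters

    def test_min_cells_respected(self):
        cells = _seeded_cells()[:5]  # cluster 2 has only two G1 cells
        anchors = find_anchor_genes(cells, assign_by_xist(cells), min_cells=3)
        assert anchors == []


class TestPropagation:
    def test_anchor_allele_assigns_cell(self):
        cells = _seeded_cells()
        assignments = assign_by_xist(cells)
        anchors = find_anchor_genes(cells, assignments)
        out = {x.cell_id: x for x in propagate_clusters(cells, assignments, anchors)}
        assert out["u1"].cluster == 1 and out["u1"].basis == "anchor:GENE1"
        assert out["u2"].cluster == 2
        assert out["u3"].cluster is None and out["u3"].basis == "none"

    def test_tied_votes_conflict(self):
        anchors = [
            AnchorSnp("GENE1", 2000, "alt", "ref"),
            AnchorSnp("GENE3", 4000, "ref", "alt"),
        ]
        cell = _cell("u", {G1: (0, 2), ("GENE3", 4000): (0, 2)})
        (out,) = propagate_clusters(
            [cell], [ClusterAssignment("u", None, "none")], anchors
        )
        assert out.cluster is None and out.basis == "conflict"


class TestSnpEscape:
    def _assignments(self, mapping):
        return [ClusterAssignment(c, cl, "XIST") for c, cl in mapping.items()]

    def test_mean_rr_window(self):
        cells = [
            _cell("c1", {G1: (5, 0)}),
            _cell("c2", {G1: (7, 0)}),
            _cell("c3", {G1: (3, 2)}),  # RR 0.6
        ]
        asg = self._assignments({"c1": 1, "c2": 1, "c3": 1})
        (call,) = call_snp_escape(cells, asg)
        assert call.mean_rr[1] == pytest.approx((1 + 1 + 0.6) / 3)
        assert call.status[1] == "escape"  # 0.867 within 0.1-0.9

    def test_single_cell_is_no_call(self):
        cells = [_cell("c1", {G1: (5, 0)})]
        (call,) = call_snp_escape(cells, self._assignments({"c1": 1}))
        assert call.status[1] == "no_call" and call.concordant is None

    def test_fully_monoallelic_inactive(self):
        cells = [_cell(f"c{i}", {G1: (4, 0)}) for i in range(3)]
        asg = self._assignments({f"c{i}": 1 for i in range(3)})
        (call,) = call_snp_escape(cells, asg)
        assert call.status[1] == "inactive"

    def test_cross_cell_biallelism_is_escape_route_b(self):
        # every cell monoallelic, but both alleles present within a cluster
        cells = [
            _cell("c1", {G1: (4, 0)}),
            _cell("c2", {G1: (0, 5)}),
        ]
        (call,) = call_snp_escape(cells, self._assignments({"c1": 1, "c2": 1}))
        assert call.mean_rr[1] == pytest.approx(0.5)
        assert call.status[1] == "escape"

    def test_cluster_relabeling_invariance(self, sc_setup):
        _, _, cells = sc_setup
        kept = qc_filter_cells(cells)
        asg = assign_by_xist(kept)
        anchors = find_anchor_genes(kept, asg)
        asg = propagate_clusters(kept, asg, anchors)
        flipped = [
            ClusterAssignment(a.cell_id, {1: 2, 2: 1}.get(a.cluster), a.basis)
            for a in asg
        ]
        calls = {(c.gene_id, c.pos): c for c in call_snp_escape(kept, asg)}
        calls_f = {(c.gene_id, c.pos): c for c in call_snp_escape(kept, flipped)}
        for key, c in calls.items():
            f = calls_f[key]
            assert c.status[1] == f.status[2] and c.status[2] == f.status[1]
            assert c.concordant == f.concordant


class TestXiHistogram:
    def test_buckets(self):
        phases = {G1: True, G2: False, XIST: True}
        xi = xi_alleles_from_phases(phases, xist_ref_on_a=True)
        # cluster 1: Xi = haplotype A -> Xi allele of G1 (ref on A) is ref
        assert xi[G1][1] == "ref" and xi[G2][1] == "alt"
        cells = [
            _cell("c0", {G1: (0, 5)}),           # zero Xi reads
            _cell("c1", {G1: (1, 4)}),           # one Xi read
            _cell("c2", {G1: (1, 0), G2: (0, 1)}),  # two Xi reads across SNPs
            _cell("cu", {G1: (9, 9)}),           # unassigned, excluded
        ]
        asg = [
            ClusterAssignment("c0", 1, "XIST"),
            ClusterAssignment("c1", 1, "XIST"),
            ClusterAssignment("c2", 1, "XIST"),
            ClusterAssignment("cu", None, "none"),
        ]
        hist = xi_read_histogram(cells, asg, xi, gene_set=["GENE1", "GENE2"])
        assert hist.counts == {"0": 1, "1": 1, "2+": 1}
        assert hist.n_unassigned_excluded == 1

    def test_leak_free_simulation_all_in_zero_bucket(self, sc_setup):
        cfg, result, cells = sc_setup
        kept = qc_filter_cells(cells)
        asg = assign_by_xist(kept)
        anchors = find_anchor_genes(kept, asg)
        asg = propagate_clusters(kept, asg, anchors)
        phases = result.truth.phase_map(cfg.sc_individual)
        xist_key = next(k for k in phases if k[0] == "XIST")
        xi = xi_alleles_from_phases(phases, phases[xist_key])
        inactive = set(
            result.truth.genes.loc[
                result.truth.genes.true_class == "inactive", "gene_id"
            ]
        )
        hist = xi_read_histogram(kept, asg, xi, gene_set=inactive)
        assert hist.counts["1"] == 0 and hist.counts["2+"] == 0

    def test_inferred_xi_alleles_oppose_anchor_alleles(self):
        anchors = [AnchorSnp("GENE1", 2000, "ref", "alt")]
        xi = infer_xi_alleles(anchors)
        assert xi[G1] == {1: "alt", 2: "ref"}
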