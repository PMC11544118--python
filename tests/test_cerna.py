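"""ceRNA screen tests: toy fixtures, planted recovery, network export."""

from types import SimpleNamespace

import networkx as nx
import pandas as pd
import pytest

from spongescreen.cerna import (CeRNATriplet, InteractionTable,
                                assemble_triplets, export_network,
                                intersect_gene_sets,
                                intersect_interaction_sources,
                                ligand_correlated_lncs, rank_hub_lnc)
from spongescreen.diffexpr import differential_expression, filter_de
from spongescreen.examples import synthetic_ligand_correlated_lists
from spongescreen.matrix import ExpressionMatrix
from spongescreen.rankstats import spearman


def _matrix(rows: dict, conditions=None):
    frame = pd.DataFrame(rows).T.astype(float)
    samples = [f"S{i}" for i in range(1, frame.shape[1] + 1)]
    frame.columns = samples
    conditions = conditions or ["tumor"] * len(samples)
    return ExpressionMatrix(values=frame,
                            condition=pd.Series(conditions, index=samples),
                            scale="log2cpm")


class TestLigandScreen:
    def test_monotone_copy_retained_antimonotone_excluded(self):
        expr = _matrix({
            "MR0001": [1, 2, 3, 4, 5, 6],
            "LNC0001": [2, 3, 4, 5, 6, 7],     # monotone copy, rho = 1
            "LNC0002": [6, 5, 4, 3, 2, 1],     # reversed, rho = -1
        })
        hits = ligand_correlated_lncs(expr, ["LNC0001", "LNC0002"], "MR0001")
        assert set(hits) == {"LNC0001"}
        assert hits["LNC0001"].rho == pytest.approx(1.0)

    def test_absent_ligand_raises(self):
        expr = _matrix({"LNC0001": [1, 2, 3]})
        with pytest.raises(KeyError, match="CD274"):
            ligand_correlated_lncs(expr, ["LNC0001"], "CD274")

    def test_planted_sponges_recovered(self, default_bundle):
        """Planted hub lncRNA passes the ligand screen for both ligands."""
        logcpm = default_bundle["logcpm"]
        truth = default_bundle["truth"]
        recs = differential_expression(logcpm, gene_class="lncRNA")
        up, down = filter_de(recs)
        for ligand in truth.ligands:
            hits = ligand_correlated_lncs(logcpm, sorted(up | down), ligand)
            assert truth.hub_lnc in hits


class TestGeneSetIntersection:
    def test_plain_intersection(self):
        assert intersect_gene_sets({"A", "B", "C"}, {"B", "C", "D"}) == ["B", "C"]

    def test_disjoint(self):
        assert intersect_gene_sets({"A"}, {"B"}) == []

    def test_id_normalisation(self):
        # version suffixes and case must not break the match
        assert intersect_gene_sets({"ENSG01.5", "linc00999"},
                                   {"ensg01", "LINC00999.2"}) == \
            ["ENSG01", "LINC00999"]

    def test_ligand_lists_worked_example(self):
        """29 PD-L1-tracking and 85 PD-L2-tracking lncRNAs share 22."""
        pd_l1, pd_l2 = synthetic_ligand_correlated_lists()
        assert (len(pd_l1), len(pd_l2)) == (29, 85)
        assert len(intersect_gene_sets(pd_l1, pd_l2)) == 22


class TestInteractionIntersection:
    def test_identical_tables_unchanged(self):
        t = InteractionTable({("LNC1", "MIR1")}, "lnc_mi", "a")
        out = intersect_interaction_sources([t, t])
        assert out.edges == t.edges

    def test_empty_table_empties_result(self):
        a = InteractionTable({("LNC1", "MIR1")}, "lnc_mi", "a")
        b = InteractionTable(set(), "lnc_mi", "b")
        assert intersect_interaction_sources([a, b]).edges == set()

    def test_mixed_edge_class_rejected(self):
        a = InteractionTable({("LNC1", "MIR1")}, "lnc_mi", "a")
        b = InteractionTable({("MIR1", "MR1")}, "mi_mrna", "b")
        with pytest.raises(ValueError, match="mixed"):
            intersect_interaction_sources([a, b])

    def test_decoys_removed_planted_survive(self, default_bundle,
                                            default_tables):
        truth = default_bundle["truth"]
        merged = intersect_interaction_sources(default_tables["lnc_mi"])
        planted = {(t[0], t[1]) for t in truth.planted_triplets}
        assert planted <= merged.edges
        n_decoys_in = len(default_tables["lnc_mi"][0].edges - planted)
        n_decoys_out = len(merged.edges - planted)
        assert n_decoys_out <= 0.01 * n_decoys_in + 5  # birthday collisions


class TestAssembleTriplets:
    def _toy_tables(self):
        lnc_mi = InteractionTable({("LNC0001", "MIR0001")}, "lnc_mi", "a")
        mi_mrna = InteractionTable({("MIR0001", "MR0001")}, "mi_mrna", "b")
        return lnc_mi, mi_mrna

    def test_perfect_ranks_give_one_triplet(self):
        expr = _matrix({"LNC0001": [1, 2, 3, 4, 5],
                        "MIR0001": [5, 4, 3, 2, 1],
                        "MR0001": [1, 2, 3, 4, 5]})
        lnc_mi, mi_mrna = self._toy_tables()
        out = assemble_triplets(expr, ["LNC0001"], lnc_mi, mi_mrna,
                                ["MR0001"], rho_pos_min=0.5, p_max=1.0,
                                neg_p_max=1.0)
        assert len(out) == 1
        assert out[0].key() == ("LNC0001", "MIR0001", "MR0001")

    def test_positively_correlated_mirna_blocks_triplet(self):
        expr = _matrix({"LNC0001": [1, 2, 3, 4, 5],
                        "MIR0001": [1, 2, 3, 4, 5],
                        "MR0001": [1, 2, 3, 4, 5]})
        lnc_mi, mi_mrna = self._toy_tables()
        out = assemble_triplets(expr, ["LNC0001"], lnc_mi, mi_mrna,
                                ["MR0001"], rho_pos_min=0.5, p_max=1.0,
                                neg_p_max=1.0)
        assert out == []

    def test_absent_target_skipped_with_warning(self):
        expr = _matrix({"LNC0001": [1, 2, 3, 4, 5],
                        "MIR0001": [5, 4, 3, 2, 1]})
        lnc_mi, mi_mrna = self._toy_tables()
        warnings: list = []
        out = assemble_triplets(expr, ["LNC0001"], lnc_mi, mi_mrna,
                                ["MR0001"], warnings_out=warnings)
        assert out == [] and any("MR0001" in w for w in warnings)

    def test_planted_triplets_recovered(self, default_bundle, default_tables):
        truth = default_bundle["truth"]
        logcpm = default_bundle["logcpm"]
        recs = differential_expression(logcpm, gene_class="lncRNA")
        up, down = filter_de(recs)
        lnc_mi = intersect_interaction_sources(default_tables["lnc_mi"])
        mi_mrna = intersect_interaction_sources(default_tables["mi_mrna"])
        targets = sorted({t for _, t in mi_mrna.edges})
        out = assemble_triplets(logcpm, sorted(up | down), lnc_mi, mi_mrna,
                                targets)
        found = {t.key() for t in out}
        planted = set(truth.planted_triplets)
        assert len(found & planted) >= 9
        assert len(found - planted) <= 1

    def test_emitted_triplets_revalidate_against_matrix(self, default_bundle,
                                                        default_tables):
        """Every emitted triplet independently satisfies the three rules."""
        logcpm = default_bundle["logcpm"]
        truth = default_bundle["truth"]
        lnc_mi = intersect_interaction_sources(default_tables["lnc_mi"])
        mi_mrna = intersect_interaction_sources(default_tables["mi_mrna"])
        targets = sorted({t for _, t in mi_mrna.edges})
        out = assemble_triplets(logcpm, [t[0] for t in truth.planted_triplets],
                                lnc_mi, mi_mrna, targets)
        tumor = logcpm.tumor_only()
        for t in out:
            c_lm = spearman(tumor.expression_of(t.lnc_id),
                            tumor.expression_of(t.mrna_id))
            c_li = spearman(tumor.expression_of(t.lnc_id),
                            tumor.expression_of(t.mi_id))
            c_im = spearman(tumor.expression_of(t.mi_id),
                            tumor.expression_of(t.mrna_id))
            assert c_lm.rho > 0.5 and c_lm.p < 0.001
            assert c_li.rho < 0 and c_li.p < 0.05
            assert c_im.rho < 0 and c_im.p < 0.05
            assert (t.lnc_id, t.mi_id) in lnc_mi.edges
            assert (t.mi_id, t.mrna_id) in mi_mrna.edges

    def test_threshold_monotonicity(self, default_bundle, default_tables):
        logcpm = default_bundle["logcpm"]
        truth = default_bundle["truth"]
        lnc_mi = intersect_interaction_sources(default_tables["lnc_mi"])
        mi_mrna = intersect_interaction_sources(default_tables["mi_mrna"])
        targets = sorted({t for _, t in mi_mrna.edges})
        cands = [t[0] for t in truth.planted_triplets]
        loose = assemble_triplets(logcpm, cands, lnc_mi, mi_mrna, targets,
                                  rho_pos_min=0.5)
        tight = assemble_triplets(logcpm, cands, lnc_mi, mi_mrna, targets,
                                  rho_pos_min=0.9)
        assert {t.key() for t in tight} <= {t.key() for t in loose}


class TestHubRanking:
    def _corr(self, rho):
        return SimpleNamespace(rho=rho)

    def test_reported_correlation_triple(self):
        """Candidate with ligand correlations (0.58, 0.51) outranks
        (0.34, 0.46) and (0.44, 0.51)."""
        corr = {"X": (self._corr(0.58), self._corr(0.51)),
                "Y": (self._corr(0.34), self._corr(0.46)),
                "Z": (self._corr(0.44), self._corr(0.51))}
        assert rank_hub_lnc(["X", "Y", "Z"], corr) == ["X", "Z", "Y"]

    def test_single_candidate(self):
        corr = {"A": (self._corr(0.2), self._corr(0.3))}
        assert rank_hub_lnc(["A"], corr) == ["A"]

    def test_input_order_irrelevant(self):
        corr = {k: (self._corr(r1), self._corr(r2))
                for k, r1, r2 in [("A", 0.5, 0.4), ("B", 0.3, 0.9),
                                  ("C", 0.45, 0.45)]}
        assert rank_hub_lnc(["A", "B", "C"], corr) == \
            rank_hub_lnc(["C", "A", "B"], corr)

    def test_missing_correlation_rejected(self):
        with pytest.raises(KeyError):
            rank_hub_lnc(["A"], {})


class TestNetworkExport:
    def _triplet(self):
        return CeRNATriplet("LNC0001", "MIR0001", "MR0001",
                            0.8, 1e-5, -0.4, 1e-3, -0.5, 1e-4)

    def test_single_triplet_shape(self, tmp_path):
        sif = tmp_path / "net.sif"
        graph = export_network([self._triplet()], sif_path=sif)
        assert graph.number_of_nodes() == 3
        lines = sif.read_text().strip().splitlines()
        assert len(lines) == 2
        assert "LNC0001\tsponges\tMIR0001" in lines

    def test_empty_network(self, tmp_path):
        sif = tmp_path / "net.sif"
        gml = tmp_path / "net.graphml"
        graph = export_network([], sif_path=sif, graphml_path=gml)
        assert graph.number_of_nodes() == 0
        assert sif.read_text() == ""
        assert nx.read_graphml(gml).number_of_nodes() == 0

    def test_graphml_round_trip(self, tmp_path):
        triplets = [self._triplet(),
                    CeRNATriplet("LNC0002", "MIR0002", "MR0002",
                                 0.7, 1e-4, -0.3, 0.01, -0.6, 1e-5)]
        gml = tmp_path / "net.graphml"
        graph = export_network(triplets, graphml_path=gml)
        back = nx.read_graphml(gml)
        assert set(back.edges()) == set(graph.edges())
        assert {d["gene_class"] for _, d in back.nodes(data=True)} == \
            {"lncRNA", "miRNA", "mRNA"}
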