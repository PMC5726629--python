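"""TF x pathway integration: search space, intersection, exports, overlap graph."""

import numpy as np
import pandas as pd
import pytest

from renin_gsx import (
    IntegrationThresholds,
    build_search_space,
    contingency_export,
    enrichment_map,
    export_graph,
    gene_detail_table,
    intersect,
    overlap_coefficient,
    top_connection_genes,
    validate_table,
)


def gsea_frame(rows):
    return pd.DataFrame(rows, columns=["set_name", "nes", "q_fdr"])


def de_frame(entries):
    return pd.DataFrame(entries, columns=["gene", "log2fc", "q_fdr"])


@pytest.fixture
def toy_space():
    tf = {
        "TF_A": ["G1", "G2", "G3", "G4", "G5"],
        "TF_B": ["G4", "G5", "G6"],
        "TF_C": ["G7", "G8"],
    }
    pw = {
        "PW_X": ["G1", "G2", "G4", "G9"],
        "PW_Y": ["G3", "G5", "G6"],
        "PW_Z": ["G7", "G10"],
    }
    de = de_frame(
        [
            ("G1", 1.0, 0.0001), ("G2", 2.0, 0.0002), ("G3", 1.5, 0.0005),
            ("G4", -1.0, 0.0001), ("G5", 0.8, 0.05), ("G6", 0.5, 0.0001),
            ("G7", -2.0, 0.0001), ("G8", -0.3, 0.5), ("G9", 1.1, 0.0001),
            ("G10", -0.9, 0.0008),
        ]
    )
    return tf, pw, de


class TestSearchSpace:
    def test_threshold_boundary_is_inclusive(self):
        tft = gsea_frame([("A", -2.0, 0.01), ("B", -2.0, 0.02), ("C", 1.5, 0.001)])
        cp = gsea_frame([("P", -1.8, 0.01)])
        tf, pw = build_search_space(tft, cp, IntegrationThresholds(), "down")
        assert tf == ["A"] and pw == ["P"]  # q = threshold kept, 0.02 excluded

    def test_sign_must_match_direction(self):
        tft = gsea_frame([("A", 2.0, 0.0001), ("B", -2.0, 0.0001)])
        cp = gsea_frame([("P", 2.0, 0.0001), ("Q", -2.0, 0.0001)])
        tf, pw = build_search_space(tft, cp, IntegrationThresholds(), "up")
        assert tf == ["A"] and pw == ["P"]

    def test_all_significant_toy_space_retained(self):
        tft = gsea_frame([("A", -2.0, 0.001), ("B", -1.9, 0.002)])
        cp = gsea_frame([("P", -1.8, 0.003), ("Q", -1.7, 0.004)])
        tf, pw = build_search_space(tft, cp, IntegrationThresholds(), "down")
        assert tf == ["A", "B"] and pw == ["P", "Q"]

    def test_empty_space_warns_but_returns(self):
        tft = gsea_frame([("A", 2.0, 0.5)])
        cp = gsea_frame([("P", 2.0, 0.5)])
        tf, pw = build_search_space(tft, cp, IntegrationThresholds(), "up")
        assert tf == [] and pw == []


class TestIntersect:
    def test_matches_exhaustive_double_loop_oracle(self, toy_space):
        tf, pw, de = toy_space
        thr = IntegrationThresholds(drop_single_pathway_tfs=False)
        table = intersect(tf, pw, de, thr, "up")
        # independent oracle: loop every pair and every gene
        fc = dict(zip(de["gene"], de["log2fc"]))
        q = dict(zip(de["gene"], de["q_fdr"]))
        expected = {}
        for t_name, t_members in tf.items():
            for p_name, p_members in pw.items():
                shared = [
                    g for g in sorted(set(t_members) & set(p_members))
                    if q[g] <= thr.fdr_gene_up and fc[g] > 0
                ]
                if shared:
                    expected[(t_name, p_name)] = shared
        assert table.connections == expected

    def test_empty_intersection_produces_no_connection(self, toy_space):
        tf, pw, de = toy_space
        table = intersect({"TF_C": tf["TF_C"]}, {"PW_X": pw["PW_X"]}, de,
                          IntegrationThresholds(), "up")
        assert table.connections == {}

    def test_small_up_connections_dropped_from_plot_only(self, toy_space):
        tf, pw, de = toy_space
        thr = IntegrationThresholds(min_connection_genes_up=4,
                                    drop_single_pathway_tfs=False)
        table = intersect(tf, pw, de, thr, "up")
        assert len(table.connections) > 0
        assert all(len(v) < 4 for v in table.connections.values())
        assert table.plot_connections == {}  # all below the plot threshold
        assert table.matrix.empty

    def test_single_pathway_tfs_dropped_from_plot(self, toy_space):
        tf, pw, de = toy_space
        thr = IntegrationThresholds(min_connection_genes_up=1,
                                    drop_single_pathway_tfs=True)
        table = intersect(tf, pw, de, thr, "up")
        plotted_tfs = {k[0] for k in table.plot_connections}
        full_tfs = {k[0] for k in table.connections}
        assert "TF_B" in full_tfs and "TF_B" not in plotted_tfs  # 1 pathway only
        assert "TF_A" in plotted_tfs  # 2 pathways

    def test_down_direction_uses_negative_fold_changes(self, toy_space):
        tf, pw, de = toy_space
        thr = IntegrationThresholds(drop_single_pathway_tfs=False)
        table = intersect(tf, pw, de, thr, "down")
        genes = {g for v in table.connections.values() for g in v}
        # G4 and G7 are the only significant down genes inside any TF/pathway
        # overlap (G10 is in no TF set; G8 is not significant)
        assert genes == {"G4", "G7"}

    def test_tightening_thresholds_never_adds_connections(self, toy_space):
        tf, pw, de = toy_space
        loose = intersect(
            tf, pw, de,
            IntegrationThresholds(fdr_gene_up=0.05, drop_single_pathway_tfs=False),
            "up",
        )
        tight = intersect(
            tf, pw, de,
            IntegrationThresholds(fdr_gene_up=0.0003, drop_single_pathway_tfs=False),
            "up",
        )
        assert set(tight.connections) <= set(loose.connections)
        for key, genes in tight.connections.items():
            assert set(genes) <= set(loose.connections[key])

    def test_validator_accepts_own_output(self, toy_space):
        tf, pw, de = toy_space
        table = intersect(tf, pw, de, IntegrationThresholds(), "up")
        validate_table(table, tf, pw, de)

    def test_matrix_cells_equal_gene_list_lengths(self, toy_space):
        tf, pw, de = toy_space
        thr = IntegrationThresholds(min_connection_genes_up=1,
                                    drop_single_pathway_tfs=False)
        table = intersect(tf, pw, de, thr, "up")
        mat = table.matrix
        for (t, p), genes in table.plot_connections.items():
            assert mat.loc[t, p] == len(genes)
        assert mat.to_numpy().sum() == sum(
            len(v) for v in table.plot_connections.values()
        )


class TestExports:
    def test_contingency_serialization(self, tmp_path, toy_space):
        tf, pw, de = toy_space
        thr = IntegrationThresholds(min_connection_genes_up=1,
                                    drop_single_pathway_tfs=False)
        table = intersect(tf, pw, de, thr, "up")
        path = tmp_path / "cont.tsv"
        contingency_export(table, path)
        lines = path.read_text().splitlines()
        header = lines[0].split("\t")
        mat = table.matrix
        assert header == ["tf_set", *mat.columns]
        body = {ln.split("\t")[0]: ln.split("\t")[1:] for ln in lines[1:]}
        for t in mat.index:
            assert body[t] == [str(int(v)) for v in mat.loc[t]]

    def test_empty_table_writes_header_only(self, tmp_path):
        from renin_gsx.integrate import IntersectionTable

        table = IntersectionTable("up", {})
        path = tmp_path / "empty.tsv"
        contingency_export(table, path)
        assert path.read_text() == "tf_set\n"

    def test_row_order_by_descending_row_sums(self):
        from renin_gsx.integrate import connection_matrix

        mat = connection_matrix(
            {("T1", "P1"): ["a"] * 4, ("T1", "P2"): ["b"] * 5,
             ("T2", "P2"): ["c"] * 6}
        )
        assert list(mat.index) == ["T1", "T2"]  # 9 vs 6
        assert list(mat.columns) == ["P2", "P1"]  # 11 vs 4
        assert mat.loc["T2", "P1"] == 0

    def test_gene_detail_and_top_genes(self, toy_space):
        tf, pw, de = toy_space
        thr = IntegrationThresholds(min_connection_genes_up=1,
                                    drop_single_pathway_tfs=False)
        table = intersect(tf, pw, de, thr, "up")
        detail = gene_detail_table(table, de)
        assert set(detail.columns) == {"tf_set", "pathway_set", "gene", "log2fc", "q_fdr"}
        top = top_connection_genes(table, de, n=2)
        assert len(top) == 2
        # best q first; ties on q broken by larger |log2fc|
        qs = de.set_index("gene")["q_fdr"]
        assert qs[top[0]] <= qs[top[1]]


class TestEnrichmentMap:
    def test_identical_sets_have_coefficient_one(self):
        a = frozenset({"G1", "G2"})
        assert overlap_coefficient(a, a) == 1.0

    def test_disjoint_sets_have_no_edge(self):
        enriched = pd.DataFrame(
            {"set_name": ["A", "B"], "nes": [2.0, -1.8], "q_fdr": [0.001, 0.002]}
        )
        g = enrichment_map(enriched, {"A": ["G1", "G2"], "B": ["G3", "G4"]})
        assert g.number_of_edges() == 0 and g.number_of_nodes() == 2

    def test_hand_computed_coefficient_and_default_cutoff(self):
        enriched = pd.DataFrame(
            {"set_name": ["A", "B"], "nes": [2.0, 1.9], "q_fdr": [0.001, 0.002]}
        )
        members = {"A": ["G1", "G2", "G3", "G4"],
                   "B": ["G3", "G4", "G5", "G6", "G7", "G8"]}
        g = enrichment_map(enriched, members, similarity_cutoff=0.5)
        assert g.has_edge("A", "B")
        assert np.isclose(g.edges["A", "B"]["weight"], 0.5)
        assert g.nodes["A"]["direction"] == 1 and g.nodes["A"]["size"] == 4

    def test_graph_export_round_trip(self, tmp_path):
        enriched = pd.DataFrame(
            {"set_name": ["A", "B"], "nes": [2.0, 1.9], "q_fdr": [0.001, 0.002]}
        )
        members = {"A": ["G1", "G2"], "B": ["G1", "G2", "G3"]}
        g = enrichment_map(enriched, members)
        export_graph(g, tmp_path / "n.tsv", tmp_path / "e.tsv")
        nodes = pd.read_csv(tmp_path / "n.tsv", sep="\t")
        edges = pd.read_csv(tmp_path / "e.tsv", sep="\t")
        assert set(nodes["set_name"]) == {"A", "B"}
        assert len(edges) == 1 and edges["weight"][0] == 1.0
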