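import networkx as nx
import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from phona.phenotype_selection import PhenotypeModel, empty_phenotype_model
from phona.phona_graph import (
    PHENOTYPE_NODE,
    attributes_from_counts,
    build_phona,
    detect_modules_sa,
    modularity,
    network_attributes,
    node_roles,
    otu_subgraph,
)

# printed per-network summary rows used as derived-metric fixtures:
# (nodes, edges, node_degree, density, negative, positive, neg/pos ratio)
SUMMARY_ROWS = [
    (60, 88, 1.5, 0.05, 8, 75, 0.11),
    (67, 101, 1.5, 0.05, 9, 86, 0.10),
    (75, 123, 1.6, 0.04, 8, 110, 0.07),
    (77, 136, 1.8, 0.05, 24, 108, 0.22),
    (113, 264, 2.3, 0.04, 62, 195, 0.32),
    (102, 252, 2.5, 0.05, 76, 175, 0.43),
    (136, 341, 2.5, 0.04, 62, 271, 0.23),
    (158, 721, 4.6, 0.06, 288, 425, 0.68),
]


def _model(signs: dict) -> PhenotypeModel:
    coefs = pd.Series({o: (1.0 if s == "positive" else -1.0)
                       for o, s in signs.items()})
    return PhenotypeModel(
        selected_otus=list(signs),
        coefficients=coefs,
        pvalues=pd.Series(0.01, index=list(signs)),
        signs=pd.Series(signs))


def _edges(pairs) -> pd.DataFrame:
    return pd.DataFrame(
        [{"source": a, "target": b, "weight": w,
          "sign": "positive" if w > 0 else "negative"} for a, b, w in pairs],
        columns=["source", "target", "weight", "sign"])


class TestBuildPhona:
    def test_empty_model_leaves_phenotype_isolated(self):
        g = build_phona(_edges([("o1", "o2", 0.8)]), empty_phenotype_model())
        assert g.degree(PHENOTYPE_NODE) == 0
        assert g.number_of_edges() == 1

    def test_isolated_predictive_otu_retained(self):
        g = build_phona(_edges([("o1", "o2", 0.8)]),
                        _model({"o1": "positive", "o9": "negative"}))
        assert g.degree(PHENOTYPE_NODE) == 2
        assert "o9" in g
        g2 = build_phona(_edges([("o1", "o2", 0.8)]),
                         _model({"o1": "positive", "o9": "negative"}),
                         retain_isolated_predictive=False)
        assert g2.degree(PHENOTYPE_NODE) == 1
        assert "o9" not in g2

    def test_phenotype_link_signs_follow_model(self):
        signs = {"o1": "positive", "o2": "negative", "o3": "positive"}
        g = build_phona(_edges([("o1", "o2", -0.7), ("o2", "o3", 0.6)]),
                        _model(signs))
        for otu, sign in signs.items():
            assert g.edges[PHENOTYPE_NODE, otu]["sign"] == sign
            assert g.edges[PHENOTYPE_NODE, otu]["edge_kind"] == "otu-phenotype"
        assert g.edges["o1", "o2"]["sign"] == "negative"


class TestNetworkAttributes:
    @pytest.mark.parametrize(
        "nodes,edges,degree,density,neg,pos,ratio", SUMMARY_ROWS)
    def test_summary_rows_reproduce_from_counts(self, nodes, edges, degree,
                                                density, neg, pos, ratio):
        att = attributes_from_counts(nodes, edges, neg, pos)
        assert round(att.node_degree, 1) == degree
        assert round(att.density, 2) == density
        assert round(att.neg_pos_ratio, 2) == ratio

    def test_complete_graph_density_one(self):
        g = nx.complete_graph(5)
        att = network_attributes(g)
        assert att.density == pytest.approx(1.0)
        assert att.rounded()["density"] == 1.0

    def test_phenotype_layer_excluded_and_signs_counted(self):
        g = build_phona(_edges([("o1", "o2", 0.8), ("o2", "o3", -0.5)]),
                        _model({"o1": "positive"}))
        att = network_attributes(g)
        assert (att.n_nodes, att.n_edges) == (3, 2)
        assert (att.n_negative, att.n_positive) == (1, 1)
        assert att.n_negative + att.n_positive == att.n_edges

    def test_zero_positive_edges_reports_na(self):
        att = attributes_from_counts(4, 2, 2, 0)
        assert att.neg_pos_ratio is None
        assert att.rounded()["neg_pos_ratio"] == "NA"


class TestDetectModulesSa:
    def test_two_disconnected_cliques(self):
        g = nx.disjoint_union(nx.complete_graph(5), nx.complete_graph(5))
        partition, q = detect_modules_sa(g, seed=0, n_steps=30_000)
        assert len(set(partition.values())) == 2
        assert q == pytest.approx(0.5, abs=1e-12)

    def test_single_edge_graph(self):
        g = nx.Graph([("a", "b")])
        partition, q = detect_modules_sa(g, seed=1, n_steps=1000)
        assert q >= 0.0
        assert q == pytest.approx(0.0, abs=1e-12)

    def test_zero_edge_graph_gives_singletons(self):
        g = nx.empty_graph(4)
        partition, q = detect_modules_sa(g, seed=2)
        assert q == 0.0
        assert len(set(partition.values())) == 4

    def test_planted_partition_recovered(self):
        rng = np.random.default_rng(7)
        blocks = [0] * 15 + [1] * 15
        g = nx.Graph()
        g.add_nodes_from(range(30))
        for i in range(30):
            for j in range(i + 1, 30):
                p = 0.5 if blocks[i] == blocks[j] else 0.02
                if rng.random() < p:
                    g.add_edge(i, j)
        partition, q = detect_modules_sa(g, seed=8, n_steps=150_000)
        labels = [partition[i] for i in range(30)]
        assert adjusted_rand_score(blocks, labels) >= 0.9

    def test_returned_q_matches_networkx_modularity(self):
        g = nx.karate_club_graph()
        partition, q = detect_modules_sa(g, seed=3, n_steps=100_000)
        assert q == pytest.approx(modularity(g, partition), abs=1e-12)
        assert q > 0.3  # karate club has clear community structure

    def test_beats_random_partitions(self):
        g = nx.disjoint_union(nx.complete_graph(6), nx.cycle_graph(6))
        _, q = detect_modules_sa(g, seed=4, n_steps=50_000)
        rng = np.random.default_rng(5)
        for _ in range(50):
            random_part = {n: int(rng.integers(3)) for n in g.nodes}
            assert q >= modularity(g, random_part) - 1e-12
        assert q >= 0.0

    def test_node_relabelling_invariance(self):
        g = nx.disjoint_union(nx.complete_graph(5), nx.complete_graph(5))
        mapping = {i: f"n{i+100}" for i in g.nodes}
        h = nx.relabel_nodes(g, mapping)
        _, q1 = detect_modules_sa(g, seed=6, n_steps=30_000)
        _, q2 = detect_modules_sa(h, seed=6, n_steps=30_000)
        assert q1 == pytest.approx(q2, abs=1e-12)

    def test_deterministic_given_seed(self):
        g = nx.gnm_random_graph(20, 40, seed=9)
        p1, q1 = detect_modules_sa(g, seed=10, n_steps=20_000)
        p2, q2 = detect_modules_sa(g, seed=10, n_steps=20_000)
        assert p1 == p2 and q1 == q2


class TestNodeRoles:
    def test_all_links_inside_module_gives_zero_participation(self):
        g = nx.complete_graph(4)
        roles = node_roles(g, {n: 0 for n in g.nodes})
        assert (roles["P"] == 0.0).all()

    def test_equal_split_participation(self):
        # degree-2 node bridging two modules: P = 1 - 2 (1/2)^2 = 0.5
        g = nx.Graph([("bridge", "a"), ("bridge", "b"), ("a", "a2"),
                      ("b", "b2")])
        part = {"bridge": 0, "a": 0, "a2": 0, "b": 1, "b2": 1}
        roles = node_roles(g, part)
        assert roles.loc["bridge", "P"] == pytest.approx(0.5)

    def test_isolated_node_is_peripheral(self):
        g = nx.Graph()
        g.add_nodes_from(["x", "y", "z"])
        g.add_edge("y", "z")
        roles = node_roles(g, {"x": 0, "y": 1, "z": 1})
        assert roles.loc["x", "role"] == "peripheral"
        assert roles.loc["x", "z"] == 0.0
        assert roles.loc["x", "P"] == 0.0

    def test_roles_are_exhaustive_and_exclusive(self):
        g = nx.gnm_random_graph(25, 60, seed=11)
        partition, _ = detect_modules_sa(g, seed=12, n_steps=30_000)
        roles = node_roles(g, partition)
        assert len(roles) == g.number_of_nodes()
        assert roles["role"].isin(
            ["peripheral", "connector", "module hub", "network hub"]).all()
        assert ((roles["P"] >= 0) & (roles["P"] <= 1)).all()

    def test_hub_thresholds_boundary_inclusive(self):
        # star center inside a module with enough members to push z >= 2.5
        g = nx.star_graph(12)  # node 0 is the hub
        part = {n: 0 for n in g.nodes}
        roles = node_roles(g, part)
        ks = np.array([g.degree(n) for n in g.nodes], dtype=float)
        z0 = (ks[0] - ks.mean()) / ks.std(ddof=1)
        assert roles.loc[0, "z"] == pytest.approx(z0)
        expected = "module hub" if z0 >= 2.5 else "peripheral"
        assert roles.loc[0, "role"] == expected

    def test_partition_must_cover_graph(self):
        g = nx.Graph([("a", "b")])
        with pytest.raises(Exception, match="cover"):
            node_roles(g, {"a": 0})


def test_otu_subgraph_strips_phenotype_layer():
    g = build_phona(_edges([("o1", "o2", 0.9)]), _model({"o1": "positive"}))
    sub = otu_subgraph(g)
    assert PHENOTYPE_NODE not in sub
    assert sub.number_of_edges() == 1
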