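"""Signed network: thresholding, mWMDz, participation coefficient, export."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from fosnet import (
    ModulePartition,
    RegionSet,
    SignedGraph,
    export_graph,
    mwmdz,
    node_metrics_table,
    participation_coefficient,
    threshold_edges,
)
from fosnet.coactivity import CorrelationMatrix


def _cm(R: np.ndarray, labels):
    df = pd.DataFrame(R, index=labels, columns=labels)
    return CorrelationMatrix(
        condition_name="c", regions=RegionSet(labels), R=df,
        n_used=pd.DataFrame(9, index=labels, columns=labels),
    )


# --- independent brute-force oracles over raw edge lists -------------------

def oracle_mwmdz(edge_list, part, node):
    mod = part[node]
    size = sum(1 for m in part.values() if m == mod)
    if size == 1:
        return 0.0
    total = 0.0
    for a, b, w in edge_list:
        if node == a and part[b] == mod:
            total += abs(w)
        elif node == b and part[a] == mod:
            total += abs(w)
    return total / (size - 1)


def oracle_pc(edge_list, part, node):
    neigh = [b if a == node else a for a, b, _ in edge_list if node in (a, b)]
    if not neigh:
        return 0.0
    k = len(neigh)
    acc = 0.0
    for mod in set(part.values()):
        k_is = sum(1 for n in neigh if part[n] == mod)
        acc += (k_is / k) ** 2
    return 1.0 - acc


class TestThresholdEdges:
    def test_exact_threshold_excluded(self):
        R = np.eye(3)
        R[0, 1] = R[1, 0] = 0.5
        g = threshold_edges(_cm(R, list("ABC")), 0.5)
        assert g.edges == {}

    def test_just_above_threshold_signed(self):
        R = np.eye(3)
        R[0, 1] = R[1, 0] = 0.51
        R[0, 2] = R[2, 0] = -0.51
        g = threshold_edges(_cm(R, list("ABC")), 0.5)
        assert g.edges[frozenset(("A", "B"))] == pytest.approx(0.51)
        assert g.edges[frozenset(("A", "C"))] == pytest.approx(-0.51)

    def test_identity_matrix_empty_graph(self):
        assert threshold_edges(_cm(np.eye(4), list("ABCD"))).edges == {}

    def test_missing_pair_forms_no_edge(self):
        R = np.eye(3)
        R[0, 1] = R[1, 0] = np.nan
        R[0, 2] = R[2, 0] = 0.9
        with pytest.warns(UserWarning, match="no valid correlation"):
            g = threshold_edges(_cm(R, list("ABC")), 0.5)
        assert set(g.edges) == {frozenset(("A", "C"))}

    @given(t1=st.floats(0.3, 0.95), t2=st.floats(0.3, 0.95))
    def test_raising_threshold_never_adds_edges(self, t1, t2):
        rng = np.random.default_rng(0)
        A = rng.uniform(-1, 1, size=(6, 6))
        R = (A + A.T) / 2
        np.fill_diagonal(R, 1.0)
        labels = [f"R{i}" for i in range(6)]
        lo, hi = sorted((t1, t2))
        assert set(threshold_edges(_cm(R, labels), hi).edges) <= set(
            threshold_edges(_cm(R, labels), lo).edges
        )


class TestNodeMetrics:
    def test_singleton_module_scores_zero(self):
        g = SignedGraph.from_edges(list("ABC"), [("A", "B", 0.9)])
        p = ModulePartition({"A": 1, "B": 2, "C": 3})
        assert mwmdz(g, p, "A") == 0.0

    def test_module_of_three_mixed_signs(self):
        g = SignedGraph.from_edges(
            list("ABC"), [("A", "B", 0.6), ("A", "C", -0.8)]
        )
        p = ModulePartition({"A": 1, "B": 1, "C": 1})
        assert mwmdz(g, p, "A") == pytest.approx(0.7)

    def test_saturated_node_scores_one(self):
        edges = [("A", other, 1.0 if other != "C" else -1.0) for other in "BCD"]
        g = SignedGraph.from_edges(list("ABCD"), edges)
        p = ModulePartition({r: 1 for r in "ABCD"})
        assert mwmdz(g, p, "A") == pytest.approx(1.0)

    def test_pc_all_edges_within_module(self):
        g = SignedGraph.from_edges(list("ABCD"), [("A", "B", 0.9), ("A", "C", 0.8), ("A", "D", -0.7)])
        p = ModulePartition({r: 1 for r in "ABCD"})
        assert participation_coefficient(g, p, "A") == 0.0

    def test_pc_even_two_way_split(self):
        g = SignedGraph.from_edges(
            list("ABCDE"),
            [("A", "B", 0.9), ("A", "C", 0.8), ("A", "D", -0.7), ("A", "E", 0.6)],
        )
        p = ModulePartition({"A": 1, "B": 1, "C": 1, "D": 2, "E": 2})
        assert participation_coefficient(g, p, "A") == pytest.approx(0.5)

    def test_pc_four_way_spread(self):
        g = SignedGraph.from_edges(
            list("ABCDE"),
            [("A", x, 0.9) for x in "BCDE"],
        )
        p = ModulePartition({"A": 1, "B": 1, "C": 2, "D": 3, "E": 4})
        assert participation_coefficient(g, p, "A") == pytest.approx(0.75)

    def test_isolated_node_warns_and_zeroes(self):
        g = SignedGraph.from_edges(list("ABC"), [("A", "B", 0.9)])
        p = ModulePartition({"A": 1, "B": 1, "C": 2})
        with pytest.warns(UserWarning, match="no edges"):
            assert participation_coefficient(g, p, "C") == 0.0

    def test_region_mismatch_rejected_with_symmetric_difference(self):
        g = SignedGraph.from_edges(list("ABC"), [])
        p = ModulePartition({"A": 1, "B": 1, "D": 2})
        with pytest.raises(ValueError, match="C"):
            node_metrics_table(g, p)

    def test_empty_graph_all_zero(self):
        g = SignedGraph.from_edges(list("ABC"), [])
        p = ModulePartition({"A": 1, "B": 1, "C": 2})
        with pytest.warns(UserWarning, match="isolated"):
            m = node_metrics_table(g, p)
        assert (m.table[["mwmdz", "pc", "degree"]].to_numpy() == 0).all()

    def test_exhaustive_enumeration_matches_oracle(self):
        """All 4-node graphs (edges absent / +0.6 / -0.6) x all partitions."""
        nodes = list("ABCD")
        pairs = list(itertools.combinations(nodes, 2))
        partitions = [
            dict(zip(nodes, assign))
            for assign in itertools.product(range(1, 4), repeat=4)
        ]
        for weights in itertools.product((None, 0.6, -0.6), repeat=len(pairs)):
            edge_list = [
                (a, b, w) for (a, b), w in zip(pairs, weights) if w is not None
            ]
            g = SignedGraph.from_edges(nodes, edge_list)
            for part in partitions[:: 7]:  # every 7th partition: 12 per graph
                p = ModulePartition(part)
                for node in nodes:
                    assert mwmdz(g, p, node) == pytest.approx(
                        oracle_mwmdz(edge_list, part, node)
                    )
                    import warnings as _w

                    with _w.catch_warnings():
                        _w.simplefilter("ignore")
                        got = participation_coefficient(g, p, node)
                    assert got == pytest.approx(oracle_pc(edge_list, part, node))

    def test_random_six_node_graphs_match_oracle(self):
        rng = np.random.default_rng(4)
        nodes = [f"R{i}" for i in range(6)]
        pairs = list(itertools.combinations(nodes, 2))
        for rep in range(200):
            edge_list = [
                (a, b, float(rng.uniform(0.5001, 1.0) * rng.choice((-1, 1))))
                for a, b in pairs if rng.random() < 0.4
            ]
            part = {n: int(rng.integers(1, 4)) for n in nodes}
            g = SignedGraph.from_edges(nodes, edge_list)
            p = ModulePartition(part)
            with np.errstate(all="ignore"):
                m = node_metrics_table(g, p)
            for _, row in m.table.iterrows():
                node = row["region"]
                assert row["mwmdz"] == pytest.approx(oracle_mwmdz(edge_list, part, node))
                assert row["pc"] == pytest.approx(oracle_pc(edge_list, part, node))
                assert 0.0 <= row["mwmdz"] <= 1.0
                assert 0.0 <= row["pc"] <= 1.0
                # per-module degrees must sum to the total degree
                assert m.per_module_degree.loc[node].sum() == row["degree"]

    def test_sign_flip_invariance(self):
        nodes = list("ABCDE")
        edges = [("A", "B", 0.8), ("A", "C", 0.7), ("C", "D", -0.9), ("A", "E", 0.6)]
        part = ModulePartition({"A": 1, "B": 1, "C": 2, "D": 2, "E": 3})
        g1 = SignedGraph.from_edges(nodes, edges)
        g2 = SignedGraph.from_edges(nodes, [(a, b, -w) for a, b, w in edges])
        for node in nodes:
            assert mwmdz(g1, part, node) == pytest.approx(mwmdz(g2, part, node))
            import warnings as _w

            with _w.catch_warnings():
                _w.simplefilter("ignore")
                assert participation_coefficient(g1, part, node) == pytest.approx(
                    participation_coefficient(g2, part, node)
                )


class TestExport:
    def _graph_and_metrics(self):
        nodes = list("ABCD")
        g = SignedGraph.from_edges(
            nodes, [("A", "B", 0.8), ("C", "D", -0.6), ("A", "C", 0.55)]
        )
        p = ModulePartition({"A": 1, "B": 1, "C": 2, "D": 2})
        return g, node_metrics_table(g, p)

    def test_graphml_round_trip(self, tmp_path):
        g, m = self._graph_and_metrics()
        path = export_graph(g, m, tmp_path / "net.graphml", fmt="graphml")
        G = nx.read_graphml(path)
        assert set(G.nodes) == set(g.nodes.names)
        for pair, w in g.edges.items():
            a, b = sorted(pair)
            assert G.edges[a, b]["weight"] == pytest.approx(w)
        assert G.edges["C", "D"]["sign"] == "negative"
        assert G.nodes["A"]["module_id"] == 1
        assert G.nodes["A"]["mwmdz"] == pytest.approx(0.8 / 1)

    def test_gexf_and_edgelist(self, tmp_path):
        g, m = self._graph_and_metrics()
        gexf = export_graph(g, m, tmp_path / "net.gexf", fmt="gexf")
        assert nx.read_gexf(gexf).number_of_edges() == 3
        edges = export_graph(g, m, tmp_path / "net.edges", fmt="edgelist")
        assert len(edges.read_text().strip().splitlines()) == 3

    def test_empty_graph_exports_all_nodes(self, tmp_path):
        from fosnet import SDMN_REGIONS

        g = SignedGraph.from_edges(SDMN_REGIONS, [])
        p = ModulePartition({r: i + 1 for i, r in enumerate(SDMN_REGIONS)})
        import warnings as _w

        with _w.catch_warnings():
            _w.simplefilter("ignore")
            m = node_metrics_table(g, p)
        G = nx.read_graphml(export_graph(g, m, tmp_path / "e.graphml"))
        assert G.number_of_nodes() == 13 and G.number_of_edges() == 0

    def test_unknown_format_rejected(self, tmp_path):
        g, m = self._graph_and_metrics()
        with pytest.raises(ValueError, match="format"):
            export_graph(g, m, tmp_path / "x", fmt="dot")
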