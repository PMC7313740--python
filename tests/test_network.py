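"""Network thresholding, shortest-path connectivity and connector enrichment."""

import numpy as np
import pandas as pd
import pytest

from cnvwing import network as net
from cnvwing import synthetic as syn
from oracles import brute_shortest_path, fisher_exact_p


def _edges(rows):
    return pd.DataFrame(rows, columns=["gene_a", "gene_b", "posterior"])


class TestThreshold:
    def test_strict_filter(self):
        g = net.threshold_network(
            _edges([("A", "B", 0.19), ("B", "C", 0.20), ("C", "D", 0.21)]), 0.2
        )
        assert g.number_of_edges() == 1
        assert g.has_edge("C", "D")

    def test_zero_threshold_keeps_all(self):
        g = net.threshold_network(_edges([("A", "B", 0.1), ("B", "C", 0.9)]), 0.0)
        assert g.number_of_edges() == 2

    def test_all_below_threshold_rejected(self):
        with pytest.raises(ValueError, match="lower the threshold"):
            net.threshold_network(_edges([("A", "B", 0.1)]), 0.2)

    def test_weights_are_inverse_posterior(self):
        g = net.threshold_network(_edges([("A", "B", 0.5)]), 0.2)
        assert g["A"]["B"]["weight"] == pytest.approx(2.0)

    def test_bad_probability_rejected(self):
        with pytest.raises(ValueError):
            net.threshold_network(_edges([("A", "B", 1.5)]), 0.2)


class TestShortestPath:
    def test_two_hop_beats_weak_direct_edge(self):
        g = net.threshold_network(
            _edges([("A", "B", 0.5), ("B", "C", 0.5), ("A", "C", 0.21)]), 0.2
        )
        r = net.shortest_path(g, "A", "C")
        assert r.length == pytest.approx(4.0)
        assert r.connectivity == pytest.approx(0.25)
        assert r.connectors == ["B"]

    def test_adjacent_connectivity_equals_posterior(self):
        g = net.threshold_network(_edges([("A", "B", 0.7)]), 0.2)
        r = net.shortest_path(g, "A", "B")
        assert r.connectivity == pytest.approx(0.7)
        assert r.connectors == []

    def test_disconnected_pair(self):
        g = net.threshold_network(_edges([("A", "B", 0.5), ("C", "D", 0.5)]), 0.2)
        r = net.shortest_path(g, "A", "C")
        assert not r.reachable and r.connectivity == 0.0 and r.connectors == []

    def test_missing_node_warns_unreachable(self):
        g = net.threshold_network(_edges([("A", "B", 0.5)]), 0.2)
        with pytest.warns(UserWarning, match="missing"):
            r = net.shortest_path(g, "A", "Z")
        assert not r.reachable

    def test_same_source_target_rejected(self):
        g = net.threshold_network(_edges([("A", "B", 0.5)]), 0.2)
        with pytest.raises(ValueError):
            net.shortest_path(g, "A", "A")

    def test_lexicographic_tie_break(self):
        # two equal-length routes A-b-Z and A-c-Z: canonical picks b
        g = net.threshold_network(
            _edges([("A", "b", 0.5), ("b", "Z", 0.5),
                    ("A", "c", 0.5), ("c", "Z", 0.5)]), 0.2
        )
        r = net.shortest_path(g, "A", "Z")
        assert r.connectors == ["b"]
        u = net.shortest_path(g, "A", "Z", connectors="union")
        assert u.connectors == ["b", "c"]

    def test_matches_brute_force_on_random_graphs(self):
        """Dijkstra + tie-break equals exhaustive enumeration, 120 graphs <=8 nodes."""
        rng = np.random.default_rng(42)
        for _ in range(120):
            n = int(rng.integers(4, 9))
            nodes = [f"n{i}" for i in range(n)]
            rows = [
                (nodes[i], nodes[j], float(rng.uniform(0.21, 1.0)))
                for i in range(n)
                for j in range(i + 1, n)
                if rng.random() < 0.45
            ]
            if not rows:
                continue
            g = net.threshold_network(_edges(rows), 0.2)
            edges = {frozenset((a, b)): 1.0 / p for a, b, p in rows}
            s, t = nodes[0], nodes[n - 1]
            if s not in g or t not in g:
                continue
            r = net.shortest_path(g, s, t)
            length, path = brute_shortest_path(edges, s, t)
            if not r.reachable:
                assert path is None
            else:
                assert r.length == pytest.approx(length)
                assert r.path == path

    def test_connectivity_monotone_under_edge_addition(self):
        rng = np.random.default_rng(7)
        rows = [
            (f"n{i}", f"n{j}", float(rng.uniform(0.25, 0.9)))
            for i in range(7)
            for j in range(i + 1, 7)
            if rng.random() < 0.4
        ]
        g = net.threshold_network(_edges(rows), 0.2)
        pairs = [(a, b) for a in g.nodes for b in g.nodes if a < b]
        before = {p: net.shortest_path(g, *p).connectivity for p in pairs}
        # add a strong new edge
        extra = rows + [("n0", "n6", 0.95)]
        g2 = net.threshold_network(_edges(extra), 0.2)
        for p in pairs:
            assert net.shortest_path(g2, *p).connectivity >= before[p] - 1e-12


class TestPairwise:
    def test_full_cartesian_results(self):
        rows = [("c1", "p1", 0.5), ("c1", "p2", 0.5), ("c2", "p3", 0.5),
                ("c2", "p1", 0.5), ("p2", "p3", 0.5), ("c1", "c2", 0.5)]
        g = net.threshold_network(_edges(rows), 0.2)
        res = net.pairwise_connectivity(g, ["c1", "c2"], ["p1", "p2", "p3"])
        assert len(res) == 6

    def test_absent_gene_excluded_with_warning(self):
        g = net.threshold_network(_edges([("c1", "p1", 0.5)]), 0.2)
        with pytest.warns(UserWarning, match="absent"):
            res = net.pairwise_connectivity(g, ["c1", "cX"], ["p1"])
        assert len(res) == 1

    def test_overlap_gene_skipped(self):
        g = net.threshold_network(
            _edges([("c1", "p1", 0.5), ("p1", "p2", 0.5)]), 0.2
        )
        with pytest.warns(UserWarning, match="skipped"):
            res = net.pairwise_connectivity(g, ["c1", "p1"], ["p1", "p2"])
        assert set(res["source"]) == {"c1"}

    def test_all_missing_rejected(self):
        g = net.threshold_network(_edges([("a", "b", 0.5)]), 0.2)
        with pytest.raises(ValueError):
            with pytest.warns(UserWarning):
                net.pairwise_connectivity(g, ["x"], ["y"])

    def test_planted_pairs_beat_background(self, small_config):
        """Planted-path pairs have higher connectivity than random pairs."""
        sn = syn.gen_network(small_config)
        g = net.threshold_network(sn.edges, 0.2)
        planted = [
            net.shortest_path(g, s, t).connectivity for s, t in sn.planted_paths
        ]
        rng = np.random.default_rng(0)
        nodes = sorted(g.nodes)
        background = []
        while len(background) < 40:
            a, b = rng.choice(nodes, 2, replace=False)
            if (a, b) in sn.planted_paths or (b, a) in sn.planted_paths:
                continue
            background.append(net.shortest_path(g, a, b).connectivity)
        from cnvwing.stats import mann_whitney
        assert mann_whitney(planted, background, "greater").p < 0.01


class TestTissueComparison:
    def test_identical_groups_t_zero(self):
        conn = {"brain": {"wnt": np.array([0.5, 0.5, 0.5])},
                "heart": {"wnt": np.array([0.5, 0.5, 0.5])}}
        out = net.compare_tissue_connectivity(conn)
        assert out["t"].iloc[0] == 0.0 and out["p"].iloc[0] == 1.0

    def test_welch_example(self):
        conn = {"brain": {"wnt": np.array([1.0, 2.0, 3.0])},
                "heart": {"wnt": np.array([2.0, 3.0, 4.0])}}
        out = net.compare_tissue_connectivity(conn)
        assert out["t"].iloc[0] == pytest.approx(-1.224744871, abs=1e-6)
        assert out["df"].iloc[0] == pytest.approx(4.0)
        assert out["p"].iloc[0] == pytest.approx(0.2879, abs=2e-4)

    def test_small_group_skipped_with_warning(self):
        conn = {"brain": {"wnt": np.array([1.0])},
                "heart": {"wnt": np.array([2.0, 3.0])}}
        with pytest.warns(UserWarning, match="too small"):
            out = net.compare_tissue_connectivity(conn)
        assert out.empty


class TestEnrichment:
    def test_hand_computed_example(self):
        ann = {"g1": {"T"}, "g2": {"T"}, "g3": set(), "g4": set()}
        res = net.enrich_connectors({"g1", "g2"}, ann, {"g1", "g2", "g3", "g4"})
        assert len(res) == 1
        assert res[0].fisher.p == pytest.approx(1 / 6)

    def test_term_absent_from_connectors_p_one(self):
        ann = {"g1": set(), "g2": set(), "g3": {"T"}, "g4": {"T"}}
        res = net.enrich_connectors({"g1", "g2"}, ann, set(ann))
        assert res[0].fisher.p == 1.0

    def test_empty_connectors_warns(self):
        with pytest.warns(UserWarning, match="empty connector"):
            assert net.enrich_connectors(set(), {}, {"g1"}) == []

    def test_connector_outside_background_rejected(self):
        with pytest.raises(ValueError):
            net.enrich_connectors({"gX"}, {}, {"g1"})

    def test_matches_hypergeometric_enumeration(self):
        """Backgrounds up to 30 genes agree with direct enumeration."""
        rng = np.random.default_rng(1)
        for _ in range(25):
            n_bg = int(rng.integers(6, 31))
            bg = {f"g{i}" for i in range(n_bg)}
            with_term = set(rng.choice(sorted(bg), int(rng.integers(1, n_bg)), replace=False))
            ann = {g: ({"T"} if g in with_term else set()) for g in bg}
            conn = set(rng.choice(sorted(bg), int(rng.integers(1, n_bg // 2 + 1)), replace=False))
            res = net.enrich_connectors(conn, ann, bg)
            a = len(conn & with_term)
            b = len(conn - with_term)
            c = len((bg - conn) & with_term)
            d = len((bg - conn) - with_term)
            assert res[0].fisher.p == pytest.approx(
                fisher_exact_p([[a, b], [c, d]], "greater"), abs=1e-10
            )

    def test_planted_term_enriched(self, small_config):
        sn = syn.gen_network(small_config)
        g = net.threshold_network(sn.edges, 0.2)
        connectors = {c for p in sn.planted_paths.values() for c in p[1:-1]}
        res = net.enrich_connectors(connectors, sn.annotations, set(g.nodes))
        by_term = {r.term: r for r in res}
        enriched_p = by_term[sn.enriched_term].fisher.p
        assert enriched_p == min(r.fisher.p for r in res)
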