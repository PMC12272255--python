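"""Positive-correlation graphs, centrality formulas, and hub detection.

Betweenness is cross-checked against an independent oracle that enumerates
every simple path between every ordered node pair.
"""

import itertools

import networkx as nx
import numpy as np
import pytest

import alans


def brute_force_betweenness(g, edge_length_rule, normalized):
    """Exhaustive-enumeration betweenness for small graphs.

    For every ordered pair (h, j) all simple paths are enumerated, the
    minimum total length found, and every node interior to a minimal path
    credited with its fraction of minimal paths.
    """
    def length(u, v):
        w = g[u][v]["weight"]
        return 1.0 / w if edge_length_rule == "reciprocal" else 1.0 - w

    nodes = list(g.nodes)
    bc = dict.fromkeys(nodes, 0.0)
    for h, j in itertools.permutations(nodes, 2):
        paths = list(nx.all_simple_paths(g, h, j))
        if not paths:
            continue
        lengths = [sum(length(u, v) for u, v in zip(p, p[1:])) for p in paths]
        best = min(lengths)
        minimal = [p for p, L in zip(paths, lengths) if L <= best * (1 + 1e-12)]
        for p in minimal:
            for i in p[1:-1]:
                bc[i] += 1.0 / len(minimal)
    if normalized:
        n = len(nodes)
        bc = {k: v / ((n - 1) * (n - 2)) for k, v in bc.items()}
    return bc


def random_positive_matrix(rng, n, p_negative=0.2):
    r = rng.uniform(0.05, 0.95, (n, n))
    neg = rng.random((n, n)) < p_negative
    r = np.where(neg, -r, r)
    r = np.triu(r, 1)
    r = r + r.T
    np.fill_diagonal(r, 1.0)
    return r


class TestBuildPositiveGraph:
    def test_all_positive_gives_complete_graph(self):
        r = np.full((4, 4), 0.5)
        np.fill_diagonal(r, 1.0)
        g = alans.build_positive_graph(r)
        assert g.number_of_edges() == 6

    def test_negative_entries_drop_edges(self):
        r = np.full((5, 5), 0.5)
        np.fill_diagonal(r, 1.0)
        for i, j in [(0, 1), (1, 2), (3, 4)]:
            r[i, j] = r[j, i] = -0.3
        g = alans.build_positive_graph(r)
        assert g.number_of_edges() == 10 - 3
        assert not g.has_edge(0, 1)

    def test_too_small_network_rejected(self):
        r = np.eye(2)
        with pytest.raises(ValueError, match=">= 3"):
            alans.build_positive_graph(r)


class TestDegreeCentrality:
    def test_strength_is_sum_of_incident_weights(self):
        g = nx.Graph()
        g.add_nodes_from(range(3))
        g.add_edge(0, 1, weight=0.5)
        g.add_edge(0, 2, weight=0.25)
        dc = alans.degree_centrality(g)
        assert dc[0] == pytest.approx(0.75)
        assert dc[1] == pytest.approx(0.5)

    def test_isolated_node_has_zero_strength(self):
        r = np.eye(4)
        r[0, 1] = r[1, 0] = 0.6
        r[1, 2] = r[2, 1] = 0.4
        r[0, 2] = r[2, 0] = 0.3
        r[:3, 3] = r[3, :3] = -0.5
        dc = alans.degree_centrality(alans.build_positive_graph(r))
        assert dc[3] == 0.0

    def test_matches_positive_row_sums(self):
        """Matrix-level cross-check: DC equals the positive off-diagonal row sum."""
        rng = np.random.default_rng(0)
        r = random_positive_matrix(rng, 8)
        dc = alans.degree_centrality(alans.build_positive_graph(r))
        off = r - np.eye(8)
        expected = np.where(off > 0, off, 0.0).sum(axis=1)
        np.testing.assert_allclose([dc[i] for i in range(8)], expected, rtol=1e-12)


class TestBetweennessCentrality:
    def test_star_center(self):
        """All leaf-to-leaf shortest paths pass the center."""
        g = nx.Graph()
        rng = np.random.default_rng(1)
        n = 6
        for leaf in range(1, n):
            g.add_edge(0, leaf, weight=rng.uniform(0.2, 0.9))
        raw = alans.betweenness_centrality(g, normalized=False)
        norm = alans.betweenness_centrality(g, normalized=True)
        assert raw[0] == pytest.approx((n - 1) * (n - 2))
        assert norm[0] == pytest.approx(1.0)
        assert all(raw[leaf] == 0.0 for leaf in range(1, n))

    def test_equal_weight_complete_graph_is_flat_zero(self):
        r = np.full((5, 5), 0.5)
        np.fill_diagonal(r, 1.0)
        bc = alans.betweenness_centrality(alans.build_positive_graph(r))
        assert all(v == 0.0 for v in bc.values())

    @pytest.mark.parametrize("rule", ["reciprocal", "one_minus_r"])
    def test_matches_enumeration_oracle(self, rule):
        rng = np.random.default_rng(2)
        for trial in range(30):
            n = int(rng.integers(4, 8))
            g = alans.build_positive_graph(random_positive_matrix(rng, n))
            got = alans.betweenness_centrality(g, edge_length_rule=rule)
            expected = brute_force_betweenness(g, rule, normalized=False)
            for node in g.nodes:
                assert got[node] == pytest.approx(expected[node], abs=1e-9), (
                    f"trial {trial}, rule {rule}"
                )

    def test_disconnected_graph_allowed(self):
        g = nx.Graph()
        g.add_edge(0, 1, weight=0.5)
        g.add_edge(2, 3, weight=0.5)
        g.add_node(4)
        bc = alans.betweenness_centrality(g)
        assert set(bc.values()) == {0.0}


class TestSummaryAndHubs:
    def test_identical_participants_have_zero_ci_width(self):
        dc = np.tile([1.0, 2.0, 3.0, 4.0], (6, 1))
        bc = np.tile([0.1, 0.2, 0.3, 0.4], (6, 1))
        s = alans.summarize_over_participants(dc, bc, list("abcd"))
        np.testing.assert_allclose(s.table["dc_ci_low"], s.table["dc_mean"])
        np.testing.assert_allclose(s.table["dc_ci_high"], s.table["dc_mean"])

    def test_thresholds_are_mean_plus_sample_sd(self):
        """Printed network summaries: mean 5.07 sd 0.95 -> 6.02; 2.75/0.84 -> 3.59."""
        assert 5.07 + 0.95 == pytest.approx(6.02)
        dc_means = np.array([5.07 - 0.95, 5.07, 5.07 + 0.95])  # sd(ddof=1)=0.95
        dc = np.tile(dc_means, (4, 1))
        bc = np.tile([2.75 - 0.84, 2.75, 2.75 + 0.84], (4, 1))
        s = alans.summarize_over_participants(dc, bc, list("xyz"))
        assert s.dc_threshold == pytest.approx(6.02, abs=1e-9)
        assert s.bc_threshold == pytest.approx(3.59, abs=1e-9)

    def test_hub_rule_is_inclusive_on_boundary(self):
        dc = np.array([5.0, 4.0, 3.0])
        bc = np.array([3.59, 3.0, 2.0])
        flags = alans.detect_hubs(dc, bc, dc_threshold=4.5, bc_threshold=3.59)
        assert flags.tolist() == [True, False, False]

    def test_hub_set_invariant_to_bc_scaling(self):
        """Raw vs normalized betweenness yield identical hub sets."""
        rng = np.random.default_rng(3)
        dc = rng.uniform(1, 5, (10, 6))
        bc = rng.uniform(0, 2, (10, 6))
        s_raw = alans.summarize_over_participants(dc, bc, range(6))
        s_scaled = alans.summarize_over_participants(dc, bc * 7.3, range(6))
        assert (s_raw.table["hub"] == s_scaled.table["hub"]).all()

    def test_degenerate_identical_regions_all_flagged_inclusive(self):
        dc = np.tile(2.0, (5, 4))
        bc = np.tile(1.0, (5, 4))
        s = alans.summarize_over_participants(dc, bc, range(4))
        assert s.table["hub"].all()  # sd=0: inclusive rule flags all


class TestHubDetectorEstimator:
    def test_planted_connector_hub_recovered(self, small_cohort):
        cfg = small_cohort
        truth = alans.planted_truth(cfg)
        panel = alans.simulate_rest_timeseries(cfg)
        stack = alans.stack_from_timeseries(
            panel.data, panel.region_ids, panel.participant_ids
        )
        det = alans.HubDetector().fit(stack, {m: list(v) for m, v in cfg.module_spec.items()})
        assert set(det.hubs_) == set(cfg.module_spec)
        assert "r00" in det.hubs_["A"]

    def test_sklearn_contract(self):
        det = alans.HubDetector(edge_length_rule="one_minus_r")
        assert det.get_params()["edge_length_rule"] == "one_minus_r"
        det.set_params(edge_length_rule="reciprocal")
        with pytest.raises(ValueError, match="membership"):
            det.fit(None)
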