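"""Disparity filter, alpha sweep, and global-weight baseline."""

import random

import networkx as nx
import pytest
from scipy.integrate import quad

from phenonet.backbone import (BackboneConfig, BackboneError, apply_filter,
                               compare_filters, default_grid, disparity_alpha,
                               edge_significance, extract_backbone,
                               global_weight_filter, match_edge_fraction,
                               pick_alpha, sweep)

from conftest import random_weighted_net


def quad_alpha(p, k):
    """Numerical form of the null probability: 1 - (k-1)∫₀^p (1-x)^(k-2) dx."""
    integral, _ = quad(lambda x: (1 - x) ** (k - 2), 0, p)
    return 1 - (k - 1) * integral


class TestDisparityAlpha:
    @pytest.mark.parametrize("p,k,expected", [
        (0.5, 2, 0.5),
        (1.0, 3, 0.0),
        (0.0, 5, 1.0),
    ])
    def test_closed_form_values(self, p, k, expected):
        assert disparity_alpha(p, k) == pytest.approx(expected)

    def test_degree_one_never_rejects_null(self):
        assert disparity_alpha(0.999, 1) == 1.0

    def test_closed_form_matches_quadrature(self):
        rng = random.Random(0)
        for _ in range(100):
            p = rng.random()
            k = rng.randint(2, 40)
            assert disparity_alpha(p, k) == pytest.approx(quad_alpha(p, k),
                                                          abs=1e-9)


class TestEdgeSignificance:
    def test_normalized_weights_sum_to_one_per_node(self):
        g = random_weighted_net(seed=5, n=25, p=0.3)
        g.remove_nodes_from(list(nx.isolates(g)))
        sig = edge_significance(g)
        for u in g.nodes:
            total = sum(sig.p[(u, v)] for v in g[u])
            assert total == pytest.approx(1.0, abs=1e-12)

    def test_both_directions_computed_independently(self):
        g = nx.Graph()
        g.add_edge("a", "b", weight=3)
        g.add_edge("a", "c", weight=1)
        sig = edge_significance(g)
        assert sig.p[("a", "b")] == pytest.approx(0.75)
        assert sig.p[("b", "a")] == 1.0
        assert sig.alpha[("a", "b")] == pytest.approx(0.25)
        assert sig.alpha[("b", "a")] == 1.0  # degree-1 convention

    def test_non_positive_weight_fatal(self):
        g = nx.Graph()
        g.add_edge("a", "b", weight=0)
        with pytest.raises(BackboneError):
            edge_significance(g)


class TestApplyFilter:
    def test_alpha_zero_removes_everything(self):
        g = random_weighted_net(seed=6)
        bb = extract_backbone(g, 0.0, "OR")
        assert bb.number_of_edges() == 0
        assert bb.number_of_nodes() == 0

    def test_equal_weight_star_empty_under_and(self):
        g = nx.star_graph(5)
        nx.set_edge_attributes(g, 2, "weight")
        bb = extract_backbone(g, 0.9, "AND")
        assert bb.number_of_edges() == 0

    @pytest.mark.parametrize("rule", ["AND", "OR"])
    def test_random_nets_match_edge_by_edge_oracle(self, rule):
        for seed in range(5):
            g = random_weighted_net(seed=seed, n=18, p=0.35)
            sig = edge_significance(g)
            bb = apply_filter(g, sig, BackboneConfig(0.3, rule))
            degree = dict(g.degree())
            strength = dict(g.degree(weight="weight"))
            for u, v, w in g.edges(data="weight"):
                conds = []
                for a in (u, v):
                    k = degree[a]
                    pij = w / strength[a]
                    alpha = 1.0 if k == 1 else (1 - pij) ** (k - 1)
                    conds.append(alpha < 0.3)
                expected = all(conds) if rule == "AND" else any(conds)
                assert bb.has_edge(u, v) == expected

    def test_surviving_edges_keep_weights(self):
        g = random_weighted_net(seed=9)
        bb = extract_backbone(g, 0.4, "OR")
        for u, v, w in bb.edges(data="weight"):
            assert g[u][v]["weight"] == w

    def test_and_backbone_nested_in_or_backbone(self):
        for seed in range(5):
            g = random_weighted_net(seed=100 + seed, n=25)
            for alpha in (0.1, 0.3, 0.7):
                e_and = set(map(frozenset, extract_backbone(g, alpha, "AND").edges))
                e_or = set(map(frozenset, extract_backbone(g, alpha, "OR").edges))
                assert e_and <= e_or

    @pytest.mark.parametrize("rule", ["AND", "OR"])
    def test_backbone_monotone_in_alpha(self, rule):
        for seed in range(5):
            g = random_weighted_net(seed=200 + seed, n=25)
            prev = set()
            for alpha in (0.0, 0.1, 0.25, 0.5, 0.9, 1.0):
                edges = set(map(frozenset, extract_backbone(g, alpha, rule).edges))
                assert prev <= edges
                prev = edges


class TestSweep:
    def test_alpha_zero_row_is_all_zero(self):
        g = random_weighted_net(seed=7)
        row = sweep(g, [0.0]).iloc[0]
        assert (row[["frac_edges", "frac_vertices", "frac_weight",
                     "avg_cc"]] == 0).all()

    def test_alpha_one_keeps_all_edges_when_strictly_significant(self):
        # heterogeneous weights on degree>=2 nodes: every alpha_ij < 1
        g = nx.complete_graph(5)
        rng = random.Random(1)
        for u, v in g.edges:
            g[u][v]["weight"] = rng.randint(1, 20)
        tab = sweep(g, [1.0], "OR")
        assert tab.iloc[0]["frac_edges"] == 1.0

    def test_retained_fractions_non_decreasing_in_alpha(self):
        g = random_weighted_net(seed=8, n=30)
        tab = sweep(g, default_grid(21), "AND")
        assert tab["frac_edges"].is_monotonic_increasing
        assert tab["frac_weight"].is_monotonic_increasing

    def test_empty_grid_fatal(self):
        with pytest.raises(BackboneError):
            sweep(random_weighted_net(seed=1), [])


class TestPickAlpha:
    def test_exact_match_returned(self):
        g = random_weighted_net(seed=12, n=25)
        tab = sweep(g, default_grid(21), "OR")
        target = tab["frac_edges"].iloc[10]
        chosen = pick_alpha(tab, target)
        row = tab[tab["alpha"] == chosen].iloc[0]
        assert row["frac_edges"] == pytest.approx(target)

    def test_tie_breaks_to_smaller_alpha(self):
        import pandas as pd
        tab = pd.DataFrame({"alpha": [0.2, 0.8], "frac_edges": [0.4, 0.6]})
        assert pick_alpha(tab, 0.5) == 0.2

    def test_matches_linear_scan_oracle(self):
        import pandas as pd
        rng = random.Random(4)
        for _ in range(20):
            alphas = sorted(rng.random() for _ in range(8))
            fracs = sorted(rng.random() for _ in range(8))
            tab = pd.DataFrame({"alpha": alphas, "frac_edges": fracs})
            target = rng.random()
            best = min(zip(alphas, fracs),
                       key=lambda t: (abs(t[1] - target), t[0]))[0]
            assert pick_alpha(tab, target) == best


class TestGlobalWeightFilter:
    def test_zero_cutoff_keeps_all_edges(self):
        g = random_weighted_net(seed=14)
        out = global_weight_filter(g, 0)
        assert out.number_of_edges() == g.number_of_edges()

    def test_cutoff_above_max_empties_network(self):
        g = random_weighted_net(seed=15)
        out = global_weight_filter(g, 10**6)
        assert out.number_of_edges() == 0

    def test_matches_comprehension_oracle(self):
        g = random_weighted_net(seed=16)
        cutoff = 25
        out = global_weight_filter(g, cutoff)
        expected = {frozenset((u, v)) for u, v, w in g.edges(data="weight")
                    if w >= cutoff}
        assert set(map(frozenset, out.edges)) == expected


class TestMatchEdgeFraction:
    def test_distinct_weights_half_target(self):
        g = nx.Graph()
        for i, w in enumerate([10, 8, 5, 2]):
            g.add_edge(f"a{i}", f"b{i}", weight=w)
        cutoff, achieved = match_edge_fraction(g, 0.5)
        assert cutoff == 8  # keeps the two largest weights
        assert achieved == 0.5

    def test_target_one_returns_minimum_weight(self):
        g = random_weighted_net(seed=17)
        weights = [w for _, _, w in g.edges(data="weight")]
        cutoff, achieved = match_edge_fraction(g, 1.0)
        assert cutoff == min(weights)
        assert achieved == 1.0

    def test_tied_weights_stay_at_or_below_target(self):
        g = nx.Graph()
        for i in range(6):
            g.add_edge(f"a{i}", f"b{i}", weight=7)
        g.add_edge("x", "y", weight=9)
        cutoff, achieved = match_edge_fraction(g, 0.5)
        assert achieved <= 0.5


class TestCompareFilters:
    def test_identity_filters_report_hundred_percent(self):
        g = random_weighted_net(seed=18)
        g.remove_nodes_from(list(nx.isolates(g)))
        comp = compare_filters(g, g, g)
        for col in ("disparity", "global_weight"):
            assert comp[col]["pct_nodes"] == 100.0
            assert comp[col]["pct_edges"] == 100.0
            assert comp[col]["pct_weight"] == 100.0

    def test_empty_filtered_nets_report_zero(self):
        g = random_weighted_net(seed=19)
        empty = nx.Graph()
        comp = compare_filters(g, empty, empty)
        assert comp["disparity"]["pct_edges"] == 0.0
        assert comp["disparity"]["avg_path_length"] is None

    def test_percentages_recompute_from_counts(self):
        g = random_weighted_net(seed=20, n=25)
        g.remove_nodes_from(list(nx.isolates(g)))
        dfn = extract_backbone(g, 0.4, "OR")
        gwn = global_weight_filter(g, 20)
        comp = compare_filters(g, dfn, gwn)
        for col, net in (("disparity", dfn), ("global_weight", gwn)):
            assert comp[col]["pct_nodes"] == pytest.approx(
                100 * net.number_of_nodes() / g.number_of_nodes())
            assert comp[col]["pct_weight"] == pytest.approx(
                100 * net.size(weight="weight") / g.size(weight="weight"))
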