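"""Topological metrics and key-gene selection vs brute-force oracles."""

import math

import networkx as nx
import numpy as np
import pytest

from metasig import (
    ConfigurationError,
    InputError,
    PARAMETERS,
    build_regulated_network,
    compute_topological_parameters,
    score_and_select_key_genes,
)

from ._oracles import brute_force_metrics


def _values(cards):
    return {c.node: c.values for c in cards}


def test_path_graph_hand_values():
    """Center of a 3-path: betweenness 1, clustering 0, eccentricity 1."""
    net = nx.path_graph(["a", "b", "c"])
    vals = _values(compute_topological_parameters(net))
    assert vals["b"]["betweenness"] == 1.0
    assert vals["b"]["clustering"] == 0.0
    assert vals["b"]["eccentricity_centrality"] == 1.0
    assert vals["a"]["eccentricity_centrality"] == 0.5
    assert vals["b"]["closeness"] == 2.0  # 1/1 + 1/1
    assert vals["a"]["closeness"] == 1.5


def test_triangle_hand_values():
    net = nx.complete_graph(3)
    for v, m in _values(compute_topological_parameters(net)).items():
        assert m["clustering"] == 1.0
        assert m["betweenness"] == 0.0
        assert m["lac"] == 1.0
        assert m["brokering"] == 0.0  # (1 - CC) = 0


def test_bridging_coefficient_on_joined_triangles():
    """Two triangles joined by edge c-d: BC(c) = (1/3)/(1/2+1/2+1/3) = 0.25."""
    net = nx.Graph(
        [("a", "b"), ("a", "c"), ("b", "c"), ("d", "e"), ("d", "f"), ("e", "f"), ("c", "d")]
    )
    vals = _values(compute_topological_parameters(net))
    # betweenness(c): pairs {a,b}x{d,e,f} route through c, plus none inside
    assert vals["c"]["bridging_centrality"] == pytest.approx(vals["c"]["betweenness"] * 0.25)


def test_metrics_match_brute_force_on_random_small_graphs():
    """Spot-check the eight metrics against enumeration (full sweep lives in
    the acceptance suite)."""
    rng = np.random.default_rng(5)
    for _ in range(20):
        n = int(rng.integers(3, 8))
        g = nx.gnp_random_graph(n, 0.5, seed=int(rng.integers(2**31)))
        if g.number_of_edges() == 0:
            continue
        cards = compute_topological_parameters(g)
        oracle = brute_force_metrics(list(g.nodes), list(g.edges))
        for c in cards:
            for param in PARAMETERS:
                assert c.values[param] == pytest.approx(oracle[c.node][param], abs=1e-9), (
                    param,
                    sorted(g.edges),
                )


def test_build_regulated_network():
    ppi = nx.path_graph(["a", "b", "c"])
    net, degs = build_regulated_network({"a"}, ppi)
    assert set(net.nodes) == {"a", "b"} and set(net.edges) == {("a", "b")}
    assert degs == {"a"}

    net, degs = build_regulated_network({"a", "zzz"}, ppi)  # zzz not in the PPI
    assert degs == {"a"}

    with pytest.raises(InputError):
        build_regulated_network({"zzz"}, ppi)

    rng = np.random.default_rng(31)
    g = nx.gnp_random_graph(50, 0.08, seed=9)
    seeds = set(int(x) for x in rng.choice(50, size=10, replace=False))
    net, _ = build_regulated_network(seeds, g)
    closed = set()
    for s in seeds:
        closed.add(s)
        closed.update(g.neighbors(s))  # brute-force closed neighborhood
    assert set(net.nodes) == closed


def test_star_hub_is_group1_winner():
    net = nx.star_graph(9)  # node 0 is the hub
    cards = compute_topological_parameters(net, deg_nodes=set(net.nodes))
    keys, winners = score_and_select_key_genes(cards, top_frac=0.2)
    assert 0 in winners[1]
    assert 0 in keys


def test_top_frac_ceiling_rule():
    """10 DEGs at top_frac 0.2: exactly 2 per parameter unless tied."""
    net = nx.gnp_random_graph(10, 0.5, seed=3)
    cards = compute_topological_parameters(net, deg_nodes=set(net.nodes))
    score_and_select_key_genes(cards, top_frac=0.2)
    for gid, params in [(1, ("degree",)), (2, ("betweenness",))]:
        vals = sorted((c.values[params[0]] for c in cards), reverse=True)
        winners_at_param = sum(1 for c in cards if c.values[params[0]] >= vals[1])
        expected = 2 if vals[1] > vals[2] else winners_at_param
        assert winners_at_param == expected


def _brute_force_selection(cards, top_frac, rule):
    """Independent reimplementation of the scoring rule."""
    degs = [c for c in cards if c.is_deg]
    k = math.ceil(top_frac * len(degs))
    groups = {1: ["degree"], 2: ["betweenness"], 3: ["bridging_centrality"],
              4: ["closeness", "eccentricity_centrality"],
              5: ["clustering", "brokering", "lac"]}
    winners = {}
    for gid, params in groups.items():
        scores = {}
        for c in degs:
            s = 0
            for p in params:
                ranked = sorted(degs, key=lambda x: -x.values[p])
                cutoff = ranked[k - 1].values[p]
                if c.values[p] >= cutoff:
                    s += 1
            scores[c.node] = s
        best = len(params) if rule == "full" else max(scores.values())
        winners[gid] = {n for n, s in scores.items() if s == best and s > 0}
    return set().union(*winners.values()), winners


@pytest.mark.parametrize("rule", ["full", "max"])
def test_selection_matches_brute_force_oracle(rule):
    rng = np.random.default_rng(44)
    g = nx.gnp_random_graph(60, 0.1, seed=8)
    degs = set(int(x) for x in rng.choice(60, size=20, replace=False))
    cards = compute_topological_parameters(g, deg_nodes=degs)
    keys, winners = score_and_select_key_genes(cards, top_frac=0.2, group_winner_rule=rule)
    brute_keys, brute_winners = _brute_force_selection(cards, 0.2, rule)
    assert keys == brute_keys
    assert winners == brute_winners
    assert all(c.is_deg for c in cards if c.selected)


def test_isolated_non_deg_node_does_not_change_selection():
    g = nx.gnp_random_graph(30, 0.15, seed=2)
    degs = set(range(10))
    cards = compute_topological_parameters(g, deg_nodes=degs)
    keys, _ = score_and_select_key_genes(cards, top_frac=0.2)
    g2 = g.copy()
    g2.add_node("isolated")
    cards2 = compute_topological_parameters(g2, deg_nodes=degs)
    keys2, _ = score_and_select_key_genes(cards2, top_frac=0.2)
    assert keys == keys2


def test_selection_guards():
    net = nx.path_graph(3)
    cards = compute_topological_parameters(net, deg_nodes={0})
    with pytest.raises(ConfigurationError):
        score_and_select_key_genes(cards, top_frac=0.0)
    with pytest.raises(ConfigurationError):
        score_and_select_key_genes(cards, top_frac=1.5)
    none_deg = compute_topological_parameters(net, deg_nodes=set())
    with pytest.raises(InputError):
        score_and_select_key_genes(none_deg)
    with pytest.raises(InputError):
        compute_topological_parameters(nx.Graph())
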