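"""MCODE vertex weighting, module prediction and composition reporting."""

import networkx as nx
import numpy as np
import pytest

from mircoord.clustering import detect_clusters
from mircoord.modules import (
    MCODEParams,
    modules_report,
    predict_modules,
    undirected_projection,
    vertex_weights,
)
from mircoord.network import RegulatoryNetwork


# ---------------------------------------------------------------------------
# projection


def test_projection_merges_reciprocal_edges_and_drops_self_loops():
    net = RegulatoryNetwork()
    for n in ("a", "b", "c"):
        net.add_node(n, "TF")
    net.graph.add_edge("a", "a", relation="r")
    net.add_edge("a", "b")
    net.add_edge("b", "a")
    net.add_edge("b", "c")
    net.add_edge("c", "b")
    net.add_edge("a", "c")
    g = undirected_projection(net)
    assert g.number_of_edges() == 3
    assert not any(u == v for u, v in g.edges())


# ---------------------------------------------------------------------------
# vertex weights


def test_weights_on_cliques_and_pendants_match_hand_values():
    k3 = nx.complete_graph(3)
    assert all(w == pytest.approx(2.0) for w in vertex_weights(k3).values())
    k4 = nx.complete_graph(4)
    assert all(w == pytest.approx(3.0) for w in vertex_weights(k4).values())
    star = nx.Graph([("hub", "p1")])
    assert vertex_weights(star)["p1"] == 0.0  # degree 1 < degree_cutoff 2


# ---------------------------------------------------------------------------
# module prediction


def test_k5_with_pendant_recovers_clique_after_haircut():
    g = nx.complete_graph(5)
    g.add_edge(0, "pendant")
    mods = predict_modules(nx.relabel_nodes(g, str), MCODEParams())
    assert len(mods) == 1
    assert mods[0].members == frozenset("01234")
    assert mods[0].score == pytest.approx(5.0)  # density 1 x size 5


def test_two_disjoint_triangles_give_two_modules():
    g = nx.Graph([("a", "b"), ("b", "c"), ("a", "c"), ("x", "y"), ("y", "z"), ("x", "z")])
    mods = predict_modules(g, MCODEParams())
    assert sorted(sorted(m.members) for m in mods) == [["a", "b", "c"], ["x", "y", "z"]]


def test_edgeless_graph_has_no_modules():
    g = nx.empty_graph(6)
    assert predict_modules(g, MCODEParams()) == []


def test_every_module_contains_required_core_and_modules_are_disjoint():
    rng = np.random.default_rng(5)
    g = nx.gnp_random_graph(40, 0.15, seed=7)
    g = nx.relabel_nodes(g, str)
    mods = predict_modules(g, MCODEParams())
    seen = set()
    for m in mods:
        sub = nx.Graph(g.subgraph(m.members))
        assert max(nx.core_number(sub).values()) >= 2
        assert not (m.members & seen)
        seen |= m.members
        assert nx.is_connected(sub)


def test_prediction_is_deterministic():
    g = nx.relabel_nodes(nx.gnp_random_graph(30, 0.2, seed=11), str)
    a = predict_modules(g, MCODEParams())
    b = predict_modules(g, MCODEParams())
    assert [(m.members, m.score, m.seed) for m in a] == [
        (m.members, m.score, m.seed) for m in b
    ]


# --- oracle: independent reimplementation of the seeded expansion rule -----


def oracle_mcode(graph, params):
    """Straight transcription of the staged algorithm, kept naive."""
    weights = {}
    for v in graph.nodes():
        if graph.degree(v) < params.degree_cutoff:
            weights[v] = 0.0
            continue
        nbhd = graph.subgraph(set(graph[v]) | {v})
        cores = nx.core_number(nbhd)
        kmax = max(cores.values())
        core_nodes = [n for n, c in cores.items() if c >= kmax]
        core = graph.subgraph(core_nodes)
        n = core.number_of_nodes()
        dens = 0.0 if n < 2 else 2 * core.number_of_edges() / (n * (n - 1))
        weights[v] = kmax * dens

    visited, results = set(), []
    for seed in sorted(graph.nodes(), key=lambda v: (-weights[v], v)):
        if seed in visited or weights[seed] <= 0:
            continue
        thr = (1 - params.node_score_cutoff) * weights[seed]
        members = {seed}
        changed = True
        depth = 0
        frontier = {seed}
        while changed and depth < params.max_depth:
            nxt = set()
            for u in frontier:
                for w in graph[u]:
                    if w not in members and w not in visited and weights[w] >= thr:
                        nxt.add(w)
            changed = bool(nxt)
            members |= nxt
            frontier = nxt
            depth += 1
        visited |= members
        sub = nx.Graph(graph.subgraph(members))
        if not sub.nodes or max(nx.core_number(sub).values(), default=0) < params.k_core:
            continue
        if params.haircut:
            while True:
                leaves = [n for n in sub if sub.degree(n) <= 1]
                if not leaves:
                    break
                sub.remove_nodes_from(leaves)
        if sub.number_of_nodes() < 2:
            continue
        n = sub.number_of_nodes()
        dens = 2 * sub.number_of_edges() / (n * (n - 1))
        results.append((frozenset(sub.nodes()), dens * n, seed))
    results.sort(key=lambda r: (-r[1], -len(r[0]), r[2]))
    return results


@pytest.mark.parametrize("trial", range(40))
def test_small_graph_modules_match_expansion_oracle(trial):
    rng = np.random.default_rng(200 + trial)
    n = int(rng.integers(4, 13))
    g = nx.gnp_random_graph(n, float(rng.uniform(0.2, 0.7)), seed=int(rng.integers(1e6)))
    g = nx.relabel_nodes(g, lambda i: f"n{i:02d}")
    got = predict_modules(g, MCODEParams())
    want = oracle_mcode(g, MCODEParams())
    assert [(m.members, m.seed) for m in got] == [(r[0], r[2]) for r in want]
    for m, r in zip(got, want):
        assert m.score == pytest.approx(r[1], abs=1e-12)


# ---------------------------------------------------------------------------
# module composition report


def test_report_flags_same_cluster_pairs_and_counts_types(planted):
    scenario, genes, clusters, modules = planted
    df = modules_report(modules, clusters, scenario.network)
    planted_rows = df[df["n_mirna"] >= 2]
    # every planted module hosts one whole cluster -> a same-cluster pair
    assert planted_rows["has_same_cluster_pair"].all()
    assert (df["size"] == df[["n_tf", "n_mirna", "n_gene"]].sum(axis=1)).all()


def test_planted_modules_recovered_almost_completely(planted):
    scenario, genes, clusters, modules = planted
    for true in scenario.ground_truth.true_module_members:
        best = max(modules, key=lambda m: len(m.members & true))
        assert len(best.members & true) / len(true) >= 0.9


def test_module_without_mirnas_reports_zero_counts():
    net = RegulatoryNetwork()
    for n in ("t1", "t2", "t3"):
        net.add_node(n, "TF")
    for a in ("t1", "t2"):
        for b in ("t2", "t3"):
            if a != b:
                net.add_edge(a, b)
    net.add_edge("t1", "t3")
    mods = predict_modules(undirected_projection(net), MCODEParams())
    empty_clusters = detect_clusters([])
    df = modules_report(mods, empty_clusters, net)
    assert (df["n_mirna"] == 0).all()
    assert not df["has_same_cluster_pair"].any()
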