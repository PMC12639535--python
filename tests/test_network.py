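"""Jaccard similarity, network construction, communities and centrality."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from mycscreen import (annotate_moa, build_network, centrality, detect_communities,
                       jaccard_matrix)
from mycscreen.exceptions import ValidationError


def brute_force_jaccard(x, y):
    xs = {i for i, v in enumerate(x) if v}
    ys = {i for i, v in enumerate(y) if v}
    return 1.0 if not (xs | ys) else len(xs & ys) / len(xs | ys)


def brute_force_betweenness(g: nx.Graph) -> dict:
    """Normalized betweenness by explicit enumeration of all shortest paths."""
    nodes = sorted(g.nodes)
    n = len(nodes)
    btw = {v: 0.0 for v in nodes}
    for s, t in itertools.combinations(nodes, 2):
        try:
            paths = list(nx.all_shortest_paths(g, s, t))
        except nx.NetworkXNoPath:
            continue
        for v in nodes:
            if v in (s, t):
                continue
            through = sum(1 for p in paths if v in p)
            btw[v] += through / len(paths)
    norm = (n - 1) * (n - 2) / 2
    return {v: b / norm for v, b in btw.items()}


# ----------------------------------------------------------------- Jaccard

def test_jaccard_examples():
    sim = jaccard_matrix({"a": [1, 1, 0, 0], "b": [1, 0, 1, 0], "c": [0, 0, 0, 1]})
    df = sim.to_frame()
    assert df.loc["a", "a"] == 1.0
    assert df.loc["a", "b"] == pytest.approx(1 / 3)
    assert df.loc["a", "c"] == 0.0


def test_jaccard_all_zero_pair_defined_as_one():
    sim = jaccard_matrix({"a": [0, 0], "b": [0, 0]})
    assert sim.to_frame().loc["a", "b"] == 1.0


def test_jaccard_length_mismatch():
    with pytest.raises(ValidationError):
        jaccard_matrix({"a": [1, 0], "b": [1, 0, 1]})


def test_jaccard_matches_brute_force():
    rng = np.random.default_rng(10)
    profiles = {f"c{i}": rng.integers(0, 2, size=15) for i in range(50)}
    sim = jaccard_matrix(profiles).to_frame()
    ids = list(profiles)
    for a, b in itertools.combinations(ids, 2):
        assert sim.loc[a, b] == pytest.approx(
            brute_force_jaccard(profiles[a], profiles[b]))
        assert sim.loc[a, b] == sim.loc[b, a]


# ----------------------------------------------------------------- network

def _block_profiles(n_blocks=3, per_block=5, seed=0):
    from mycscreen import simulate_community_profiles
    return simulate_community_profiles(n_blocks=n_blocks, per_block=per_block,
                                       profile_len=n_blocks * 10, n_flips=1, seed=seed)


def test_build_network_thresholds():
    sim = jaccard_matrix({"a": [1, 1], "b": [1, 0], "c": [0, 1]})
    complete = build_network(sim, edge_threshold=0.0)
    assert complete.number_of_edges() == 2  # a-b and a-c share support; b-c do not
    empty = build_network(sim, edge_threshold=0.9)
    assert empty.number_of_edges() == 0
    assert set(empty.nodes) == {"a", "b", "c"}
    with pytest.raises(ValidationError):
        build_network(sim, edge_threshold=1.0)


def test_two_disconnected_cliques_are_two_communities():
    g = nx.Graph()
    for block, names in enumerate((["a1", "a2", "a3"], ["b1", "b2", "b3"])):
        for u, v in itertools.combinations(names, 2):
            g.add_edge(u, v, weight=1.0)
    comm = detect_communities(g)
    assert len(set(comm.values())) == 2
    assert comm["a1"] == comm["a2"] == comm["a3"]
    assert comm["b1"] == comm["b2"] == comm["b3"] != comm["a1"]


def test_triangle_single_community_and_edgeless():
    tri = nx.Graph([("a", "b"), ("b", "c"), ("a", "c")])
    nx.set_edge_attributes(tri, 1.0, "weight")
    assert set(detect_communities(tri).values()) == {0}
    lone = nx.Graph()
    lone.add_nodes_from(["x", "y"])
    comm = detect_communities(lone)
    assert sorted(comm.values()) == [0, 1]


def test_planted_blocks_recovered_and_deterministic():
    from sklearn.metrics import adjusted_rand_score
    profiles, labels = _block_profiles()
    sim = jaccard_matrix(profiles)
    g = build_network(sim, edge_threshold=0.0)
    comm1 = detect_communities(g)
    comm2 = detect_communities(build_network(sim, edge_threshold=0.0))
    assert comm1 == comm2
    nodes = sorted(comm1)
    ari = adjusted_rand_score([labels[n] for n in nodes], [comm1[n] for n in nodes])
    assert ari >= 0.9
    # modularity beats the trivial one-community partition
    parts = {}
    for node, cid in comm1.items():
        parts.setdefault(cid, set()).add(node)
    q = nx.algorithms.community.modularity(g, parts.values(), weight="weight")
    q0 = nx.algorithms.community.modularity(g, [set(g.nodes)], weight="weight")
    assert q > q0


# --------------------------------------------------------------- centrality

def test_path_graph_betweenness():
    g = nx.Graph([("A", "B"), ("B", "C")])
    c = centrality(g).set_index("compound_id")
    assert c.loc["B", "betweenness"] == 1.0
    assert c.loc["A", "betweenness"] == c.loc["C", "betweenness"] == 0.0


def test_star_degrees():
    g = nx.star_graph(5)
    g = nx.relabel_nodes(g, {i: f"n{i}" for i in g.nodes})
    c = centrality(g).set_index("compound_id")
    assert c.loc["n0", "degree"] == 5
    assert (c.drop("n0")["degree"] == 1).all()


def test_bridge_node_has_maximal_betweenness():
    g = nx.Graph()
    for names in (["a1", "a2", "a3", "a4"], ["b1", "b2", "b3", "b4"]):
        for u, v in itertools.combinations(names, 2):
            g.add_edge(u, v)
    g.add_edge("a1", "bridge")
    g.add_edge("bridge", "b1")
    c = centrality(g).set_index("compound_id")["betweenness"]
    assert c.idxmax() == "bridge"


def test_centrality_matches_enumeration_oracle():
    rng = np.random.default_rng(11)
    for _ in range(5):
        g = nx.gnp_random_graph(7, 0.45, seed=int(rng.integers(0, 1000)))
        g = nx.relabel_nodes(g, {i: f"n{i}" for i in g.nodes})
        got = centrality(g).set_index("compound_id")
        want_btw = brute_force_betweenness(g)
        for node in g.nodes:
            assert got.loc[node, "betweenness"] == pytest.approx(want_btw[node])
            assert got.loc[node, "degree"] == g.degree(node)


# ---------------------------------------------------------------------- MoA

def test_moa_annotation_and_abundance():
    profiles, labels = _block_profiles(n_blocks=2, per_block=4)
    g = build_network(jaccard_matrix(profiles), 0.0)
    comm = detect_communities(g)
    moa = {n: f"moa{labels[n]}" for n in list(profiles)[:-1]}  # one unannotated
    g, abundance = annotate_moa(g, moa, comm)
    assert g.nodes[list(profiles)[-1]]["moa"] == "unannotated"
    for cid in set(comm.values()):
        top = abundance[abundance.community == cid].iloc[0]
        members = [n for n, c in comm.items() if c == cid]
        assert top["moa"] == f"moa{labels[members[0]]}"


def test_moa_unknown_compound_ignored(caplog):
    g = nx.Graph()
    g.add_nodes_from(["a", "b"])
    with caplog.at_level("WARNING"):
        g, abundance = annotate_moa(g, {"zzz": "kinase"})
    assert all(g.nodes[n]["moa"] == "unannotated" for n in g.nodes)
    assert any("unknown" in r.message for r in caplog.records)
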