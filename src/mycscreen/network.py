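"""Functional drug network from orthogonality-enrichment profiles.

Two compounds with similar sets of predicted synergistic partners are likely
to act through similar mechanisms, so the pairwise Jaccard index of their
binary orthogonality-enrichment profiles defines a weighted similarity graph.
Communities are found by greedy modularity maximization (Clauset-Newman-Moore
agglomeration on edge weights) and bridging compounds are flagged by
betweenness and degree centrality.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd

from .exceptions import ValidationError

logger = logging.getLogger(__name__)


@dataclass
class SimilarityMatrix:
    """Symmetric Jaccard similarity over an ordered compound list."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.ids), len(self.ids)):
            raise ValidationError("similarity matrix shape does not match ids")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValidationError("similarity matrix is not symmetric")
        if (v < -1e-12).any() or (v > 1 + 1e-12).any():
            raise ValidationError("Jaccard values must lie in [0, 1]")
        self.values = v

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


def jaccard_matrix(profiles: Mapping[str, np.ndarray] | pd.DataFrame) -> SimilarityMatrix:
    """Pairwise Jaccard index |x & y| / |x | y| of equal-length binary vectors.

    Accepts a mapping id -> vector or a DataFrame with one row per compound.
    A pair of all-zero vectors gets J = 1 (identical, if empty, profiles);
    this is logged.
    """
    if isinstance(profiles, pd.DataFrame):
        ids = [str(i) for i in profiles.index]
        mat = profiles.to_numpy()
    else:
        ids = list(profiles)
        lengths = {len(np.atleast_1d(profiles[i])) for i in ids}
        if len(lengths) > 1:
            raise ValidationError(f"profile vectors differ in length: {sorted(lengths)}")
        mat = np.stack([np.atleast_1d(profiles[i]) for i in ids])
    if not np.isin(mat, (0, 1)).all():
        raise ValidationError("profiles must be binary (0/1)")
    b = mat.astype(np.float64)
    inter = b @ b.T
    sizes = b.sum(axis=1)
    union = sizes[:, None] + sizes[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        jac = np.where(union > 0, inter / np.maximum(union, 1e-300), 1.0)
    if (union == 0).any():
        logger.info("all-zero profile pairs present; their Jaccard is defined as 1")
    np.fill_diagonal(jac, 1.0)
    return SimilarityMatrix(ids, jac)


def build_network(sim: SimilarityMatrix, edge_threshold: float = 0.0) -> nx.Graph:
    """Undirected weighted graph: edge (i, j) iff similarity > threshold.

    Isolated nodes are retained; nodes are inserted in sorted order so every
    downstream traversal (community detection, export) is deterministic.
    """
    if not 0.0 <= edge_threshold < 1.0:
        raise ValidationError("edge_threshold must lie in [0, 1)")
    g = nx.Graph(edge_threshold=edge_threshold)
    order = sorted(range(len(sim.ids)), key=lambda i: sim.ids[i])
    for i in order:
        g.add_node(sim.ids[i])
    for ai in order:
        for bi in order:
            if sim.ids[ai] < sim.ids[bi] and sim.values[ai, bi] > edge_threshold:
                g.add_edge(sim.ids[ai], sim.ids[bi], weight=float(sim.values[ai, bi]))
    return g


def detect_communities(net: nx.Graph) -> dict[str, int]:
    """Greedy modularity communities on edge weights.

    Returns node -> community id, ids ordered by decreasing community size
    with ties broken by the smallest member id (diff-stable output).  An
    edgeless graph yields one singleton community per node (logged).
    """
    if net.number_of_edges() == 0:
        logger.warning("edgeless network: every node is its own community")
        comms = [{n} for n in sorted(net.nodes)]
    else:
        comms = [set(c) for c in
                 nx.algorithms.community.greedy_modularity_communities(net, weight="weight")]
    comms.sort(key=lambda c: (-len(c), min(c)))
    return {node: cid for cid, comm in enumerate(comms) for node in sorted(comm)}


def centrality(net: nx.Graph, weighted: bool = False) -> pd.DataFrame:
    """Per-node betweenness (normalized) and degree.

    Shortest paths use unweighted hops by default; ``weighted=True`` uses
    distance = 1/weight so strong similarities are short paths.
    """
    if weighted:
        for u, v, d in net.edges(data=True):
            d["_dist"] = 1.0 / d["weight"]
        btw = nx.betweenness_centrality(net, weight="_dist", normalized=True)
    else:
        btw = nx.betweenness_centrality(net, normalized=True)
    deg = dict(net.degree())
    nodes = sorted(net.nodes)
    return pd.DataFrame({"compound_id": nodes,
                         "betweenness": [btw[n] for n in nodes],
                         "degree": [deg[n] for n in nodes]})


def annotate_moa(net: nx.Graph, moa_table: Mapping[str, str],
                 communities: Mapping[str, int] | None = None,
                 ) -> tuple[nx.Graph, pd.DataFrame]:
    """Attach mechanism-of-action labels and tabulate MoA abundance per community.

    Compounds absent from ``moa_table`` are labelled ``unannotated``; labels
    for unknown compounds are ignored with a warning.
    """
    unknown = set(moa_table) - set(net.nodes)
    if unknown:
        logger.warning("MoA labels for unknown compounds ignored: %s",
                       sorted(unknown)[:5])
    for node in net.nodes:
        net.nodes[node]["moa"] = moa_table.get(node, "unannotated")
    communities = communities if communities is not None else detect_communities(net)
    rows = []
    for node in sorted(net.nodes):
        rows.append((communities[node], net.nodes[node]["moa"]))
    abundance = (pd.DataFrame(rows, columns=["community", "moa"])
                 .value_counts().rename("count").reset_index()
                 .sort_values(["community", "count", "moa"],
                              ascending=[True, False, True], kind="mergesort")
                 .reset_index(drop=True))
    for node, cid in communities.items():
        net.nodes[node]["community"] = int(cid)
    return net, abundance
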