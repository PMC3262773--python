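"""Dense-module detection with the MCODE algorithm (Bader & Hogue).

MCODE finds locally dense regions of an undirected graph in three stages:

1. **Vertex weighting.** Each vertex is scored by the density of the highest
   k-core of its closed neighborhood times that core's k ("core-clustering
   coefficient" scaled by k_max). Vertices below a degree cutoff score 0.
2. **Complex prediction.** Starting from the highest-weighted unvisited
   vertex, a complex grows outward over neighbors whose weight is within
   ``node_score_cutoff`` of the seed's weight; each vertex joins at most one
   complex.
3. **Post-processing.** Complexes lacking a 2-core are dropped; *haircut*
   iteratively removes degree-1 members; *fluff* optionally adds boundary
   neighbors with dense neighborhoods.

The regulatory network is directed; module detection runs on its simple
undirected projection. All ties are broken lexicographically so output is
deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import pandas as pd

from .clustering import ClusterCallResult
from .network import RegulatoryNetwork

__all__ = [
    "MCODEParams",
    "NetworkModule",
    "undirected_projection",
    "vertex_weights",
    "predict_modules",
    "modules_report",
    "write_module_table",
]


@dataclass(frozen=True)
class MCODEParams:
    """Tunable parameters of MCODE, with the canonical defaults."""

    degree_cutoff: int = 2
    node_score_cutoff: float = 0.2
    k_core: int = 2
    haircut: bool = True
    fluff: bool = False
    fluff_density: float = 0.1
    max_depth: int = 100

    def __post_init__(self) -> None:
        if not 0.0 <= self.node_score_cutoff <= 1.0:
            raise ValueError("node_score_cutoff must lie in [0, 1]")
        if self.degree_cutoff < 0 or self.k_core < 0 or self.max_depth < 0:
            raise ValueError("cutoffs must be non-negative")


@dataclass(frozen=True)
class NetworkModule:
    module_id: int
    members: frozenset[str]
    score: float
    seed: str

    def __len__(self) -> int:
        return len(self.members)


def undirected_projection(network: RegulatoryNetwork | nx.DiGraph) -> nx.Graph:
    """Simple undirected projection: one edge per regulating node pair."""
    digraph = network.graph if isinstance(network, RegulatoryNetwork) else network
    g = nx.Graph()
    g.add_nodes_from(digraph.nodes())
    g.add_edges_from((u, v) for u, v in digraph.edges() if u != v)
    return g


def _density(g: nx.Graph) -> float:
    n = g.number_of_nodes()
    if n < 2:
        return 0.0
    return 2.0 * g.number_of_edges() / (n * (n - 1))


def _highest_k_core(g: nx.Graph) -> tuple[int, nx.Graph]:
    """(k_max, induced subgraph of the k_max-core) of a simple graph."""
    if g.number_of_nodes() == 0:
        return 0, g
    core_num = nx.core_number(g)
    k_max = max(core_num.values())
    members = [n for n, k in core_num.items() if k >= k_max]
    return k_max, g.subgraph(members)


def vertex_weights(
    graph: nx.Graph, params: MCODEParams = MCODEParams()
) -> dict[str, float]:
    """MCODE stage-1 weights: k_max x density of the closed-neighborhood core.

    Vertices with degree below ``params.degree_cutoff`` get weight 0.
    """
    weights: dict[str, float] = {}
    for v in graph.nodes():
        if graph.degree(v) < params.degree_cutoff:
            weights[v] = 0.0
            continue
        closed = graph.subgraph([v, *graph.neighbors(v)])
        k_max, core = _highest_k_core(closed)
        weights[v] = k_max * _density(core)
    return weights


def _expand_complex(
    graph: nx.Graph,
    weights: Mapping[str, float],
    seed: str,
    visited: set[str],
    params: MCODEParams,
) -> set[str]:
    """Breadth-first expansion from a seed over high-weight unvisited vertices."""
    threshold = (1.0 - params.node_score_cutoff) * weights[seed]
    members = {seed}
    frontier = [seed]
    depth = 0
    while frontier and depth < params.max_depth:
        nxt = []
        for u in frontier:
            for w in sorted(graph.neighbors(u)):
                if w in members or w in visited:
                    continue
                if weights[w] >= threshold:
                    members.add(w)
                    nxt.append(w)
        frontier = nxt
        depth += 1
    return members


def _haircut(sub: nx.Graph) -> nx.Graph:
    sub = nx.Graph(sub)
    while True:
        leaves = [n for n in sub.nodes if sub.degree(n) <= 1]
        if not leaves:
            break
        sub.remove_nodes_from(leaves)
    return sub


def _fluff(graph: nx.Graph, members: set[str], params: MCODEParams) -> set[str]:
    added = set()
    for v in sorted(members):
        for w in sorted(graph.neighbors(v)):
            if w in members or w in added:
                continue
            closed = graph.subgraph([w, *graph.neighbors(w)])
            if _density(closed) > params.fluff_density:
                added.add(w)
    return members | added


def predict_modules(
    graph: nx.Graph, params: MCODEParams = MCODEParams()
) -> list[NetworkModule]:
    """MCODE stages 2-3: seeded expansion plus post-processing.

    Seeds are taken in decreasing weight order (lexicographic among ties);
    each vertex joins at most one complex. A complex is kept only if it
    contains a ``k_core``-core; haircut then trims degree-1 members, fluff
    optionally adds dense boundary neighbors. Score is density x size.
    Output is sorted by score descending, ties by size descending then seed.
    """
    weights = vertex_weights(graph, params)
    visited: set[str] = set()
    raw: list[tuple[str, set[str]]] = []
    for seed in sorted(graph.nodes(), key=lambda v: (-weights[v], v)):
        if seed in visited or weights[seed] <= 0.0:
            continue
        members = _expand_complex(graph, weights, seed, visited, params)
        visited |= members
        raw.append((seed, members))

    modules: list[NetworkModule] = []
    for seed, members in raw:
        sub = graph.subgraph(members)
        core_num = nx.core_number(nx.Graph(sub)) if members else {}
        if not core_num or max(core_num.values()) < params.k_core:
            continue
        if params.haircut:
            sub = _haircut(sub)
            if sub.number_of_nodes() == 0:
                continue
        final = set(sub.nodes())
        if params.fluff:
            final = _fluff(graph, final, params)
        if len(final) < 2:
            continue
        final_sub = graph.subgraph(final)
        score = _density(final_sub) * len(final)
        modules.append(
            NetworkModule(module_id=-1, members=frozenset(final), score=score, seed=seed)
        )

    modules.sort(key=lambda m: (-m.score, -len(m), m.seed))
    return [
        NetworkModule(module_id=i, members=m.members, score=m.score, seed=m.seed)
        for i, m in enumerate(modules)
    ]


def modules_report(
    modules: Sequence[NetworkModule],
    clusters: ClusterCallResult,
    network: RegulatoryNetwork,
    id_map: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Per-module composition: node-type counts, clustered-miRNA categories.

    Reports, per module, how many member miRNAs are homo-clustered,
    hetero-clustered or isolated, which genomic clusters place >=2 members in
    the module, and whether any same-cluster miRNA pair co-occurs.
    """
    id_map = dict(id_map or {})
    cluster_of: dict[str, tuple[int, str]] = {}
    for ci, c in enumerate(clusters.clusters):
        for g in c.members:
            nid = id_map.get(g.id, g.id)
            cluster_of[nid] = (ci, c.cluster_type or "unlabeled")
    isolated_ids = {id_map.get(g.id, g.id) for g in clusters.isolated}

    rows = []
    for m in modules:
        counts = {"TF": 0, "miRNA": 0, "gene": 0}
        homo = hetero = isolated = 0
        member_clusters: dict[int, int] = {}
        for n in m.members:
            t = network.node_type(n)
            counts[t] += 1
            if t != "miRNA":
                continue
            if n in cluster_of:
                ci, ctype = cluster_of[n]
                member_clusters[ci] = member_clusters.get(ci, 0) + 1
                if ctype == "homo":
                    homo += 1
                elif ctype == "hetero":
                    hetero += 1
            elif n in isolated_ids:
                isolated += 1
        shared = sorted(ci for ci, k in member_clusters.items() if k >= 2)
        rows.append(
            {
                "module_id": m.module_id,
                "score": m.score,
                "size": len(m),
                "n_tf": counts["TF"],
                "n_mirna": counts["miRNA"],
                "n_gene": counts["gene"],
                "n_homo_clustered": homo,
                "n_hetero_clustered": hetero,
                "n_isolated": isolated,
                "clusters_with_pair": ";".join(map(str, shared)),
                "has_same_cluster_pair": bool(shared),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "module_id", "score", "size", "n_tf", "n_mirna", "n_gene",
            "n_homo_clustered", "n_hetero_clustered", "n_isolated",
            "clusters_with_pair", "has_same_cluster_pair",
        ],
    )


def write_module_table(modules: Sequence[NetworkModule], path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame(
        [
            {
                "module_id": m.module_id,
                "score": m.score,
                "size": len(m),
                "seed": m.seed,
                "members": ";".join(sorted(m.members)),
            }
            for m in modules
        ],
        columns=["module_id", "score", "size", "seed", "members"],
    )
    df.to_csv(path, sep="\t", index=False)
    return path
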