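"""The directed miRNA-TF regulatory network.

Nodes are typed TF / miRNA / gene (non-TF protein-coding gene); directed
edges are regulation events — a TF activating or repressing transcription of
its target, or a miRNA repressing translation. Gene nodes are regulatory
sinks: they have no outgoing edges.

The network is read from and written to Cytoscape SIF text
(``source relation target``). Reachability within ``k`` regulation steps
defines the (direct and indirect) target set of a miRNA, which feeds the
target-overlap statistic.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import networkx as nx

from .errors import ParseError, ValidationError

__all__ = [
    "NodeType",
    "RegulatoryNetwork",
    "TargetProfile",
    "read_sif",
    "write_sif",
    "k_step_targets",
    "validate_network",
    "default_id_normalizer",
    "read_id_map",
]

logger = logging.getLogger(__name__)

NodeType = Literal["TF", "miRNA", "gene"]

#: id prefixes that mark a node as a miRNA when no explicit type is given
DEFAULT_MIRNA_PREFIXES = ("hsa-mir", "hsa-let", "hsa-miR")

Steps = int | Literal["closure"]


@dataclass
class RegulatoryNetwork:
    """Directed regulation graph over typed nodes.

    Backed by a ``networkx.DiGraph``; node attribute ``node_type`` holds the
    type, edge attribute ``relation`` the regulation label.
    """

    graph: nx.DiGraph = field(default_factory=nx.DiGraph)

    # -- construction -------------------------------------------------------
    def add_node(self, node_id: str, node_type: NodeType) -> None:
        if node_type not in ("TF", "miRNA", "gene"):
            raise ValidationError(f"bad node type {node_type!r} for {node_id!r}")
        self.graph.add_node(node_id, node_type=node_type)

    def add_edge(self, source: str, target: str, relation: str = "regulates") -> None:
        if source == target:
            return  # self-regulation carries no pairwise information here
        for n in (source, target):
            if n not in self.graph:
                raise ValidationError(f"edge endpoint {n!r} is not a declared node")
        self.graph.add_edge(source, target, relation=relation)

    # -- views --------------------------------------------------------------
    def node_type(self, node_id: str) -> NodeType:
        try:
            return self.graph.nodes[node_id]["node_type"]
        except KeyError:
            raise ValidationError(f"unknown node {node_id!r}") from None

    def nodes_of_type(self, node_type: NodeType) -> list[str]:
        return sorted(
            n for n, t in self.graph.nodes(data="node_type") if t == node_type
        )

    @property
    def mirnas(self) -> list[str]:
        return self.nodes_of_type("miRNA")

    @property
    def tfs(self) -> list[str]:
        return self.nodes_of_type("TF")

    @property
    def genes(self) -> list[str]:
        return self.nodes_of_type("gene")

    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def target_universe_size(self, exclude: str | None = None) -> int:
        """Number of distinct nodes that appear as an edge target, minus ``exclude``."""
        cached = getattr(self, "_target_cache", None)
        if cached is None or cached[0] != self.graph.number_of_edges():
            targets = frozenset(v for _u, v in self.graph.edges())
            cached = (self.graph.number_of_edges(), targets)
            object.__setattr__(self, "_target_cache", cached)
        _n_edges, targets = cached
        return len(targets) - (1 if exclude in targets else 0)


@dataclass(frozen=True)
class TargetProfile:
    """Target set of one miRNA within a step bound.

    ``targets`` holds every node reachable from ``mirna_id`` by a directed
    path of length <= ``steps`` (the source itself excluded); ``l`` is the
    target count and ``universe_size`` the network-wide count of regulated
    nodes, recorded for reporting.
    """

    mirna_id: str
    steps: Steps
    targets: frozenset[str]
    universe_size: int

    @property
    def l(self) -> int:  # noqa: E743 - the field's conventional name
        return len(self.targets)


# ---------------------------------------------------------------------------
# SIF IO


def _assign_type(
    node_id: str, tf_set: frozenset[str], mirna_patterns: Sequence[str]
) -> NodeType:
    if node_id in tf_set:
        return "TF"
    for pat in mirna_patterns:
        if node_id.startswith(pat):
            return "miRNA"
    return "gene"


def read_sif(
    path: str | Path,
    tf_list: str | Path | Iterable[str] | None = None,
    mirna_prefixes: Sequence[str] = DEFAULT_MIRNA_PREFIXES,
    strict: bool = False,
) -> RegulatoryNetwork:
    """Read a SIF network and type its nodes.

    Node types are assigned by precedence: explicit TF list > miRNA id
    prefix rule > gene. SIF lines are ``source relation target [target ...]``
    (tab- or whitespace-delimited; multi-target lines are expanded); a line
    with a single field declares an isolated node. Duplicate edges are
    collapsed and self-loops dropped, both with a logged count.

    With ``strict`` true, an edge leaving a gene node raises instead of
    warning.
    """
    path = Path(path)
    if tf_list is None:
        tf_set: frozenset[str] = frozenset()
    elif isinstance(tf_list, (str, Path)):
        tf_set = frozenset(
            line.strip() for line in Path(tf_list).read_text().splitlines() if line.strip()
        )
    else:
        tf_set = frozenset(tf_list)

    raw_edges: list[tuple[str, str, str]] = []
    isolated_nodes: list[str] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            fields = [f for f in (f.strip() for f in fields) if f]
            if len(fields) == 1:
                isolated_nodes.append(fields[0])
                continue
            if len(fields) < 3:
                raise ParseError(
                    f"{path}:{lineno}: SIF line needs 'source relation target', "
                    f"got {len(fields)} fields"
                )
            source, relation, *targets = fields
            for target in targets:
                raw_edges.append((source, relation, target))

    net = RegulatoryNetwork()
    node_ids = set(isolated_nodes)
    for s, _r, t in raw_edges:
        node_ids.update((s, t))
    for n in sorted(node_ids):
        net.add_node(n, _assign_type(n, tf_set, mirna_prefixes))

    n_self, n_dup = 0, 0
    seen: set[tuple[str, str]] = set()
    for s, r, t in raw_edges:
        if s == t:
            n_self += 1
            continue
        if (s, t) in seen:
            n_dup += 1
            continue
        seen.add((s, t))
        if net.node_type(s) == "gene":
            msg = f"{path}: edge out of gene node {s!r} -> {t!r}"
            if strict:
                raise ValidationError(msg)
            logger.warning(msg)
        net.add_edge(s, t, relation=r)
    if n_self:
        logger.info("%s: dropped %d self-loop(s)", path, n_self)
    if n_dup:
        logger.info("%s: collapsed %d duplicate edge(s)", path, n_dup)
    return net


def write_sif(network: RegulatoryNetwork, path: str | Path) -> Path:
    """Write deterministic (lexicographically sorted) SIF.

    Nodes with edges appear on edge lines; isolated nodes are emitted as
    single-column lines, per the Cytoscape SIF dialect.
    """
    path = Path(path)
    lines = [
        f"{u}\t{d.get('relation', 'regulates')}\t{v}"
        for u, v, d in network.graph.edges(data=True)
    ]
    lines.sort()
    isolated = sorted(n for n in network.graph.nodes if network.graph.degree(n) == 0)
    with open(path, "w") as fh:
        for line in lines:
            fh.write(line + "\n")
        for n in isolated:
            fh.write(n + "\n")
    return path


# ---------------------------------------------------------------------------
# id mapping between annotation and network namespaces


def default_id_normalizer(mirna_id: str) -> str:
    """Heuristic mapping of mature-style ids onto precursor-style ids.

    Strips a trailing ``-5p``/``-3p`` arm suffix and case-folds ``miR`` to
    ``mir``.
    """
    stripped = re.sub(r"-[35]p$", "", mirna_id)
    return stripped.replace("miR", "mir")


def read_id_map(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV mapping annotation ids to network ids."""
    mapping = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ParseError(f"{path}:{lineno}: id map needs exactly 2 columns")
            mapping[fields[0]] = fields[1]
    return mapping


# ---------------------------------------------------------------------------
# reachability


def k_step_targets(
    network: RegulatoryNetwork,
    mirna_id: str,
    steps: Steps,
    target_universe: Literal["all", "genes_only"] = "all",
) -> TargetProfile:
    """Targets of a miRNA reachable within ``steps`` regulation steps.

    A regulation step is one directed edge; steps=1 gives the direct targets,
    larger values add indirect targets reached through intermediate TFs or
    miRNAs, and ``"closure"`` gives full reachability (cycle-safe). The
    source node itself is never a target. With ``target_universe=
    "genes_only"`` paths still traverse any regulator but only non-TF gene
    nodes are counted as targets.
    """
    if mirna_id not in network.graph:
        raise ValidationError(f"unknown node {mirna_id!r}")
    if network.node_type(mirna_id) != "miRNA":
        raise ValidationError(f"{mirna_id!r} is not a miRNA node")
    if steps != "closure" and (not isinstance(steps, int) or steps < 1):
        raise ValueError(f"steps must be a positive integer or 'closure', got {steps!r}")

    if steps == "closure":
        reached = nx.descendants(network.graph, mirna_id)
    else:
        # breadth-first within the step bound
        reached = set()
        frontier = {mirna_id}
        for _ in range(steps):
            nxt = {
                v for u in frontier for v in network.graph.successors(u)
            } - reached - {mirna_id}
            if not nxt:
                break
            reached |= nxt
            frontier = nxt
    reached.discard(mirna_id)
    if target_universe == "genes_only":
        reached = {n for n in reached if network.node_type(n) == "gene"}
    return TargetProfile(
        mirna_id=mirna_id,
        steps=steps,
        targets=frozenset(reached),
        universe_size=network.target_universe_size(exclude=mirna_id),
    )


# ---------------------------------------------------------------------------
# validation report


@dataclass(frozen=True)
class NetworkReport:
    n_nodes_by_type: dict[str, int]
    genes_with_outgoing: tuple[str, ...]
    n_weak_components: int
    largest_component_size: int
    n_edges: int

    @property
    def n_violations(self) -> int:
        return len(self.genes_with_outgoing)


def validate_network(network: RegulatoryNetwork) -> NetworkReport:
    """Structural report: type counts, gene-out-edge violations, components."""
    g = network.graph
    counts = {"TF": 0, "miRNA": 0, "gene": 0}
    for _n, t in g.nodes(data="node_type"):
        counts[t] += 1
    bad_genes = tuple(
        sorted(
            n for n, t in g.nodes(data="node_type")
            if t == "gene" and g.out_degree(n) > 0
        )
    )
    comps = list(nx.weakly_connected_components(g)) if g.number_of_nodes() else []
    return NetworkReport(
        n_nodes_by_type=counts,
        genes_with_outgoing=bad_genes,
        n_weak_components=len(comps),
        largest_component_size=max((len(c) for c in comps), default=0),
        n_edges=g.number_of_edges(),
    )
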