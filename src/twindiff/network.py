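"""Molecular-complex (MCODE) detection on a confidence-weighted gene network.

The MCODE scheme has three stages. (1) Vertex weighting: for each node with
degree >= ``degree_cutoff``, take the subgraph induced by its closed
neighborhood, find that subgraph's highest k-core, and set the node weight to
``k_max * density(core)``; other nodes weigh 0. (2) Complex prediction: seed
at the highest-weight unvisited node and grow outward breadth-first,
admitting neighbors whose weight is at least ``(1 - node_score_cutoff)``
times the seed weight, to at most ``max_depth`` hops; visited nodes never
join a second complex, so complexes are vertex-disjoint. (3) Post-processing:
complexes not containing a ``k_core``-core are dropped, and the optional
haircut iteratively strips singly-connected members. Complexes are ranked by
``density * size``.

Association-confidence scores only gate which edges enter the graph (default
minimum 0.4); the clustering itself runs on the unweighted topology.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

log = logging.getLogger(__name__)

__all__ = ["MCODEParams", "MCODECluster", "mcode_weight", "mcode_complexes", "build_string_graph"]


@dataclass(frozen=True)
class MCODEParams:
    degree_cutoff: int = 2
    node_score_cutoff: float = 0.2
    k_core: int = 2
    max_depth: int = 100
    haircut: bool = True
    fluff: bool = False
    edge_confidence_min: float = 0.4

    def __post_init__(self) -> None:
        if self.degree_cutoff < 0 or self.k_core < 0 or self.max_depth < 0:
            raise ValueError("cutoffs must be nonnegative")
        if not 0.0 <= self.node_score_cutoff <= 1.0:
            raise ValueError("node_score_cutoff must lie in [0, 1]")


@dataclass
class MCODECluster:
    members: list[str]
    seed: str
    score: float
    density: float = field(default=float("nan"))

    @property
    def size(self) -> int:
        return len(self.members)


def _density(g: nx.Graph) -> float:
    n = g.number_of_nodes()
    if n < 2:
        return 0.0
    return 2.0 * g.number_of_edges() / (n * (n - 1))


def _highest_kcore(g: nx.Graph) -> tuple[int, nx.Graph]:
    """Highest k-core of a graph: (k_max, core subgraph)."""
    core_num = nx.core_number(g)
    k_max = max(core_num.values())
    nodes = [v for v, k in core_num.items() if k == k_max]
    return k_max, g.subgraph(nodes)


def mcode_weight(graph: nx.Graph, params: MCODEParams = MCODEParams()) -> dict[str, float]:
    """Core-clustering-coefficient vertex weights."""
    weights: dict[str, float] = {}
    for v in graph.nodes:
        if graph.degree(v) < params.degree_cutoff:
            weights[v] = 0.0
            continue
        nbhd = graph.subgraph(list(graph.neighbors(v)) + [v])
        k_max, core = _highest_kcore(nbhd)
        weights[v] = k_max * _density(core)
    return weights


def mcode_complexes(
    graph: nx.Graph,
    params: MCODEParams = MCODEParams(),
) -> list[MCODECluster]:
    """Detect complexes; returns clusters ranked by score (density * size)."""
    weights = mcode_weight(graph, params)
    visited: set = set()
    clusters: list[MCODECluster] = []
    # deterministic seed order: weight desc, then lexicographic node id
    order = sorted(graph.nodes, key=lambda v: (-weights[v], str(v)))
    for seed in order:
        if seed in visited or weights[seed] <= 0.0:
            continue
        threshold = (1.0 - params.node_score_cutoff) * weights[seed]
        members = {seed}
        frontier = [seed]
        depth = 0
        while frontier and depth < params.max_depth:
            nxt = []
            for u in frontier:
                for w in sorted(graph.neighbors(u), key=str):
                    if w in members or w in visited:
                        continue
                    if weights[w] >= threshold:
                        members.add(w)
                        nxt.append(w)
            frontier = nxt
            depth += 1
        visited |= members
        sub = graph.subgraph(members).copy()
        # must contain a k_core-core
        if sub.number_of_nodes() == 0:
            continue
        core_num = nx.core_number(sub)
        if max(core_num.values(), default=0) < params.k_core:
            continue
        if params.haircut:
            while True:
                leaves = [v for v, d in sub.degree() if d < 2]
                if not leaves or sub.number_of_nodes() - len(leaves) < 2:
                    break
                sub.remove_nodes_from(leaves)
        dens = _density(sub)
        clusters.append(
            MCODECluster(
                members=sorted(sub.nodes, key=str),
                seed=seed,
                score=dens * sub.number_of_nodes(),
                density=dens,
            )
        )
    clusters.sort(key=lambda c: (-c.score, c.members))
    return clusters


def build_string_graph(
    edges: pd.DataFrame,
    genes=None,
    edge_confidence_min: float = 0.4,
) -> nx.Graph:
    """Graph from an edge list, induced on ``genes``, filtered by confidence.

    ``edges`` needs columns (node_a, node_b, score) with scores in [0, 1]
    (``twindiff.io.read_network_tsv`` normalizes 0-1000 exports). Self-loops
    and duplicate edges collapse; scores are kept as the ``score`` edge
    attribute for reporting and plot weighting only.
    """
    g = nx.Graph()
    gene_set = None if genes is None else {str(x) for x in genes}
    for row in edges.itertuples(index=False):
        a, b, s = str(row.node_a), str(row.node_b), float(row.score)
        if a == b:
            continue
        if s < edge_confidence_min:
            continue
        if gene_set is not None and (a not in gene_set or b not in gene_set):
            continue
        g.add_edge(a, b, score=s)
    if gene_set is not None:
        g.add_nodes_from(gene_set - set(g.nodes))
        if g.number_of_edges() == 0:
            log.warning("no edges among the provided genes at confidence >= %g", edge_confidence_min)
    return g
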