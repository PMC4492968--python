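"""Decomposition of an interaction network into Molecular Interaction
Subnetworks (MISs) and PageRank node scores.

An MIS is a small, tightly connected induced subgraph of the gene network;
it is the unit that is scored and ranked against the phenotype contrast.
The splitting rule here is greedy modularity community detection with
deterministic tie-breaking: oversized communities are recursively re-split
(falling back to a seeded Kernighan-Lin bisection when modularity cannot
split further) and undersized communities are merged into the neighboring
community sharing the most edges.  MISs are disjoint by construction;
overlapping subnetworks are never merged.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field

import networkx as nx

from .io import GeneNetwork

logger = logging.getLogger("icossy")

__all__ = ["MIS", "PageRankVector", "decompose", "pagerank"]


@dataclass(frozen=True)
class MIS:
    """One Molecular Interaction Subnetwork: a gene set plus induced edges."""

    mis_id: str
    genes: frozenset
    edges: frozenset  # frozenset of frozenset node pairs

    @classmethod
    def from_nodes(cls, g: nx.Graph, nodes) -> "MIS":
        nodes = frozenset(nodes)
        sub = g.subgraph(nodes)
        digest = hashlib.sha1(",".join(sorted(nodes)).encode()).hexdigest()[:10]
        return cls(f"MIS-{digest}", nodes, frozenset(frozenset(e) for e in sub.edges))

    def to_graph(self) -> nx.Graph:
        h = nx.Graph()
        h.add_nodes_from(sorted(self.genes))
        h.add_edges_from(tuple(sorted(e)) for e in self.edges)
        return h

    @property
    def sorted_genes(self) -> tuple:
        return tuple(sorted(self.genes))


@dataclass
class PageRankVector:
    scores: dict
    damping: float = 0.85
    tolerance: float = 1e-10

    def __getitem__(self, node) -> float:
        return self.scores[node]


def _sorted_subgraph(g: nx.Graph, nodes) -> nx.Graph:
    """Induced subgraph rebuilt in lexicographic node/edge order so that the
    community heuristics see a canonical iteration order."""
    h = nx.Graph()
    h.add_nodes_from(sorted(nodes))
    h.add_edges_from(sorted(tuple(sorted(e)) for e in g.subgraph(nodes).edges))
    return h


def _split(g: nx.Graph, nodes: frozenset, max_size: int, seed: int, depth: int = 0) -> list[frozenset]:
    if len(nodes) <= max_size:
        return [nodes]
    sub = _sorted_subgraph(g, nodes)
    parts: list[set] = []
    if sub.number_of_edges() > 0:
        communities = nx.community.greedy_modularity_communities(sub)
        if len(communities) > 1:
            parts = [set(c) for c in communities]
    if not parts or len(parts) == 1:
        # dense blobs modularity refuses to cut: deterministic seeded bisection
        a, b = nx.community.kernighan_lin_bisection(sub, seed=(seed + depth) % 2**31)
        parts = [set(a), set(b)]
    out: list[frozenset] = []
    for part in sorted(parts, key=lambda p: min(p)):
        for comp in nx.connected_components(sub.subgraph(part)):
            out.extend(_split(g, frozenset(comp), max_size, seed, depth + 1))
    return out


def _merge_small(g: nx.Graph, parts: list[set], min_size: int) -> list[set]:
    parts = [set(p) for p in parts]
    while True:
        small = [p for p in parts if len(p) < min_size]
        if not small or len(parts) == 1:
            break
        p = min(small, key=lambda q: (len(q), min(q)))
        best, best_key = None, None
        for q in parts:
            if q is p:
                continue
            n_edges = sum(1 for u in p for v in g.neighbors(u) if v in q)
            key = (-n_edges, min(q))
            if n_edges > 0 and (best_key is None or key < best_key):
                best, best_key = q, key
        if best is None:
            break  # no connected neighbor (cannot happen inside one component)
        best.update(p)
        parts.remove(p)
    return parts


def decompose(net: GeneNetwork, min_size: int = 5, max_size: int = 50, seed: int = 0) -> list[MIS]:
    """Split the network into disjoint, connected MISs of bounded size.

    Every node lying in a connected component of at least ``min_size`` nodes
    is assigned to exactly one MIS; smaller components are skipped with a
    logged message.  Deterministic given (network, parameters, seed).
    """
    if not (2 <= min_size <= max_size):
        raise ValueError(f"need 2 <= min_size <= max_size, got [{min_size}, {max_size}]")
    g = net.graph
    if g.number_of_nodes() == 0:
        raise ValueError("cannot decompose an empty network")
    components = sorted(nx.connected_components(g), key=min)
    usable = [c for c in components if len(c) >= min_size]
    skipped = len(components) - len(usable)
    if skipped:
        logger.info("skipping %d connected component(s) smaller than %d nodes", skipped, min_size)
    if not usable:
        raise ValueError(f"no connected component has >= {min_size} nodes")
    mis_list: list[MIS] = []
    for comp in usable:
        parts = _split(g, frozenset(comp), max_size, seed)
        parts = _merge_small(g, [set(p) for p in parts], min_size)
        for part in parts:
            if len(part) > max_size:
                logger.info("community of %d nodes exceeds max_size after merging", len(part))
            mis_list.append(MIS.from_nodes(g, part))
    return sorted(mis_list, key=lambda m: m.sorted_genes)


def pagerank(net: GeneNetwork, damping: float = 0.85, tolerance: float = 1e-10) -> PageRankVector:
    """Standard PageRank on the undirected graph (each edge as two arcs).

    Isolated nodes receive teleport-only mass; scores sum to 1.
    """
    if net.graph.number_of_nodes() == 0:
        raise ValueError("cannot compute PageRank of an empty network")
    scores = nx.pagerank(net.graph, alpha=damping, tol=tolerance, max_iter=200)
    return PageRankVector(scores, damping, tolerance)
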