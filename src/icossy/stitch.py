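"""Stitch top-ranked MISs into one hypothesis graph.

Two selected subnetworks that are directly linked in the reference
interaction network are joined by those edges (phase 1).  Subnetworks still
in different connected components afterwards are joined by the best bridging
shortest paths in the reference network (phase 2): candidate paths of at
most ``max_path_len`` edges are ordered by length (shorter first), then by
mean |fold difference| of their intermediate nodes (larger first), then by
mean PageRank over all path nodes (larger first), and the top
``paths_per_pair`` are added.  Pairs with no qualifying path remain
disconnected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping

import networkx as nx
import numpy as np

from .io import GeneNetwork
from .network import MIS, PageRankVector

logger = logging.getLogger("icossy")

__all__ = ["StitchParams", "StitchedGraph", "shortest_paths_bounded", "stitch"]

MAX_PATH_LEN_HARD_BOUND = 4


@dataclass
class StitchParams:
    max_path_len: int = 4
    paths_per_pair: int = 3
    pagerank_damping: float = 0.85

    def __post_init__(self) -> None:
        if not (1 <= self.max_path_len <= MAX_PATH_LEN_HARD_BOUND):
            raise ValueError(
                f"max_path_len must lie in [1, {MAX_PATH_LEN_HARD_BOUND}], got {self.max_path_len}"
            )
        if self.paths_per_pair < 1:
            raise ValueError("paths_per_pair must be >= 1")


@dataclass
class StitchedGraph:
    """Union of the selected MISs plus bridging edges/paths.

    Node attributes: ``mis_id`` (or ``bridge`` role for path intermediates),
    ``fold_difference`` and regulation ``direction``; edge attribute
    ``provenance`` in {mis-internal, bridge-edge, bridge-path}.
    """

    graph: nx.Graph
    added_paths: list = field(default_factory=list)


def shortest_paths_bounded(ref: GeneNetwork, src: str, dst: str, max_len: int) -> list[list[str]]:
    """All shortest simple paths from src to dst, if the shortest length is
    within ``max_len`` edges; empty list otherwise."""
    if src == dst:
        raise ValueError("src and dst must differ")
    g = ref.graph
    if src not in g or dst not in g:
        raise ValueError(f"node absent from the reference network: {src if src not in g else dst}")
    try:
        length = nx.shortest_path_length(g, src, dst)
    except nx.NetworkXNoPath:
        return []
    if length > max_len:
        return []
    return sorted(nx.all_shortest_paths(g, src, dst))


def _direction(fold: float) -> str:
    return "up" if fold >= 0 else "down"


def _path_key(path: list[str], de: Mapping[str, float], pr: PageRankVector):
    inner = path[1:-1]
    mean_fold = float(np.mean([abs(de.get(n, 0.0)) for n in inner])) if inner else 0.0
    mean_pr = float(np.mean([pr.scores.get(n, 0.0) for n in path]))
    return (len(path) - 1, -mean_fold, -mean_pr, tuple(path))


def stitch(
    selected: list[MIS],
    ref: GeneNetwork,
    de: Mapping[str, float],
    pr: PageRankVector,
    p: StitchParams | None = None,
) -> StitchedGraph:
    """Merge the selected MISs into one graph using the reference network.

    ``de`` maps genes to signed fold differences (class1 - class2 mean
    normalized expression); ``pr`` are reference-network PageRank scores.
    Raises if an MIS gene is missing from the reference network: stitching
    must use the same network the MISs were derived from.
    """
    p = p or StitchParams()
    if not selected:
        raise ValueError("nothing to stitch: no MIS selected")
    for mis in selected:
        for gene in mis.sorted_genes:
            if gene not in ref.graph:
                raise ValueError(f"MIS gene {gene!r} absent from the reference network")
    g = nx.Graph()
    mis_of: dict[str, str] = {}
    for mis in sorted(selected, key=lambda x: x.mis_id):
        for gene in mis.sorted_genes:
            fold = float(de.get(gene, 0.0))
            g.add_node(gene, mis_id=mis.mis_id, role="mis", symbol=gene,
                       fold_difference=fold, direction=_direction(fold))
            mis_of[gene] = mis.mis_id
        for e in sorted(tuple(sorted(pair)) for pair in mis.edges):
            g.add_edge(*e, provenance="mis-internal")

    # Phase 1: direct reference edges between different MISs
    for a, b in sorted(tuple(sorted(e)) for e in ref.graph.edges):
        if a in mis_of and b in mis_of and mis_of[a] != mis_of[b] and not g.has_edge(a, b):
            g.add_edge(a, b, provenance="bridge-edge")

    # Phase 2: bounded shortest paths between still-disconnected MIS pairs
    added_paths: list[tuple[list[str], tuple]] = []
    ordered = sorted(selected, key=lambda x: x.mis_id)
    for mis_a, mis_b in combinations(ordered, 2):
        node_a, node_b = min(mis_a.genes), min(mis_b.genes)
        if nx.has_path(g, node_a, node_b):
            continue
        candidates: dict[tuple, tuple] = {}
        for u in mis_a.sorted_genes:
            for v in mis_b.sorted_genes:
                for path in shortest_paths_bounded(ref, u, v, p.max_path_len):
                    canon = min(tuple(path), tuple(reversed(path)))
                    candidates.setdefault(canon, _path_key(list(canon), de, pr))
        if not candidates:
            logger.info(
                "MIS pair (%s, %s): no reference path of <= %d edges; left disconnected",
                mis_a.mis_id, mis_b.mis_id, p.max_path_len,
            )
            continue
        best = sorted(candidates, key=candidates.get)[: p.paths_per_pair]
        for canon in best:
            path = list(canon)
            for node in path[1:-1]:
                if node not in g:
                    fold = float(de.get(node, 0.0))
                    g.add_node(node, mis_id="", role="bridge", symbol=node,
                               fold_difference=fold, direction=_direction(fold))
            for a, b in zip(path[:-1], path[1:]):
                if not g.has_edge(a, b):
                    g.add_edge(a, b, provenance="bridge-path")
            added_paths.append((path, candidates[canon]))
    return StitchedGraph(g, added_paths)
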