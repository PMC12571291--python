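"""Evacuation-corridor inference from an oriented EOF mode.

The qualitative reading — evacuees move from negative-anomaly cores
(origins) to positive-anomaly zones (shelters or transit hubs) along
corridors of strong loading — is operationalized deterministically:

1. *cores*: connected components (grid adjacency) of the top-q fraction
   of cells by most-negative loading (origins) and by most-positive
   loading (destinations);
2. *routes*: for every graph-connected (origin, destination) core pair,
   the minimum-cost path where each cell costs 1 − |loading|/max|loading|,
   so strongly loaded corridor cells are cheap to traverse.

This replaces the visual road-map overlay of the original workflow with
an explicit algorithm; a user-supplied road graph can stand in for the
default 8-neighbour lattice adjacency.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np


@dataclass
class Cores:
    """Polarity cores: lists of grid-id sets, one set per connected component."""

    origins: list[set[str]]
    destinations: list[set[str]]


@dataclass
class Route:
    origin_core: int
    destination_core: int
    path: list[str]
    cost: float
    score: float  # mean normalized |loading| along the path (higher = stronger)


@dataclass
class RouteSet:
    routes: list[Route]
    cores: Cores
    unconnected: list[tuple[int, int]] = field(default_factory=list)


def lattice_adjacency(positions: dict[str, tuple[int, int]]) -> nx.Graph:
    """8-neighbour adjacency over integer (row, col) cell positions."""
    graph = nx.Graph()
    graph.add_nodes_from(positions)
    by_pos = {pos: gid for gid, pos in positions.items()}
    for gid, (r, c) in positions.items():
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == dc == 0:
                    continue
                other = by_pos.get((r + dr, c + dc))
                if other is not None:
                    graph.add_edge(gid, other)
    return graph


def adjacency_from_edges(edges: list[tuple[str, str]]) -> nx.Graph:
    """Adjacency from an explicit edge list (e.g. a road graph)."""
    graph = nx.Graph()
    graph.add_edges_from(edges)
    return graph


def extract_polarity_cores(
    grid_index: np.ndarray,
    loadings: np.ndarray,
    adjacency: nx.Graph,
    q: float = 0.2,
) -> Cores:
    """Connected components of the strongest negative / positive loadings.

    The top ⌈qG⌉ cells by most-negative loading (only those actually
    negative) seed the origin cores; most-positive likewise for
    destinations. Singleton components are allowed.
    """
    if not 0.0 < q <= 1.0:
        raise ValueError("q must lie in (0, 1]")
    ids = np.asarray(grid_index, dtype=object)
    vals = np.asarray(loadings, dtype=float)
    if ids.shape != vals.shape:
        raise ValueError("grid_index and loadings must align")
    m = int(np.ceil(q * ids.size))

    def components(cells: np.ndarray) -> list[set[str]]:
        sub = adjacency.subgraph([str(g) for g in cells])
        return [set(c) for c in nx.connected_components(sub)]

    neg_order = np.argsort(vals, kind="stable")[:m]
    neg_cells = ids[neg_order][vals[neg_order] < 0]
    pos_order = np.argsort(-vals, kind="stable")[:m]
    pos_cells = ids[pos_order][vals[pos_order] > 0]
    return Cores(origins=components(neg_cells), destinations=components(pos_cells))


def infer_routes(
    cores: Cores,
    grid_index: np.ndarray,
    loadings: np.ndarray,
    adjacency: nx.Graph,
) -> RouteSet:
    """Minimum-cost paths between every connected (origin, destination) pair.

    Per-cell traversal cost is 1 − |loading|/max|loading| (invariant to
    global rescaling of the loadings); a path's cost is the sum over all
    its cells. Pairs in different graph components are reported in
    ``unconnected``. Routes are ranked by descending score.
    """
    if not cores.origins or not cores.destinations:
        warnings.warn("empty origin or destination cores: no routes to infer", stacklevel=2)
        return RouteSet(routes=[], cores=cores)

    ids = [str(g) for g in grid_index]
    vals = np.abs(np.asarray(loadings, dtype=float))
    peak = vals.max()
    norm = vals / peak if peak > 0 else vals
    norm_map = dict(zip(ids, norm))
    cost = dict(zip(ids, 1.0 - norm))

    graph = adjacency.copy()
    routes: list[Route] = []
    unconnected: list[tuple[int, int]] = []
    super_src = "__origin__"
    for oi, origin in enumerate(cores.origins):
        # Virtual super-source so the first cell's own cost counts too.
        graph.add_node(super_src)
        for cell in origin:
            graph.add_edge(super_src, cell)

        def weight(u: str, v: str, _d: dict) -> float:
            return cost.get(v, 1.0) if u != v else 0.0

        dist, paths = nx.single_source_dijkstra(graph, super_src, weight=weight)
        graph.remove_node(super_src)

        for di, dest in enumerate(cores.destinations):
            reachable = [c for c in dest if c in dist]
            if not reachable:
                unconnected.append((oi, di))
                continue
            target = min(reachable, key=lambda c: (dist[c], c))
            path = paths[target][1:]  # drop the virtual source
            score = float(np.mean([norm_map.get(c, 0.0) for c in path]))
            routes.append(
                Route(
                    origin_core=oi,
                    destination_core=di,
                    path=path,
                    cost=float(dist[target]),
                    score=score,
                )
            )
    routes.sort(key=lambda r: (-r.score, r.origin_core, r.destination_core))
    return RouteSet(routes=routes, cores=cores, unconnected=unconnected)
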