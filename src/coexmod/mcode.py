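"""MCODE-style module detection: vertex weighting, complex prediction,
post-processing, and the module selection filter.

Stage 1 weights each vertex by ``k* x density`` of the highest k-core of its
closed neighborhood.  Stage 2 grows complexes outward from the
highest-weight unvisited seed, admitting neighbors whose weight is within
``node_score_cutoff`` of the seed's.  Stage 3 discards complexes without a
2-core and optionally trims degree-1 vertices (haircut) or adds dense
boundary vertices (fluff).  Modules are ranked by average connectivity
(edges per gene), the score convention under which the reference module's
printed value 36.6 equals 3078/84 exactly; the classical MCODE score
(core density x size) is reported alongside.
"""
from __future__ import annotations

import dataclasses
from collections import deque
from typing import Sequence

import networkx as nx

from .config import MCODEParams
from .coexnet import network_density
from .datatypes import GeneModule


def _highest_kcore(graph: nx.Graph) -> tuple[int, nx.Graph]:
    """(max core number, induced subgraph of the highest core)."""
    core = nx.core_number(graph)
    kmax = max(core.values()) if core else 0
    nodes = [v for v, c in core.items() if c >= kmax]
    return kmax, graph.subgraph(nodes)


def vertex_weights(network: nx.Graph, degree_cutoff: int = 2) -> dict[str, float]:
    """MCODE stage-1 weights: ``k* x density(highest k-core of N[v])``.

    Vertices with degree below ``degree_cutoff`` or whose closed neighborhood
    has no 2-core weigh 0.
    """
    weights: dict[str, float] = {}
    for v in network.nodes:
        if network.degree(v) < degree_cutoff:
            weights[v] = 0.0
            continue
        closed = set(network[v]) | {v}
        kmax, core = _highest_kcore(network.subgraph(closed))
        if kmax < 2:
            weights[v] = 0.0
            continue
        n = core.number_of_nodes()
        density = network_density(n, core.number_of_edges()) if n >= 2 else 0.0
        weights[v] = kmax * density
    return weights


def _grow_complex(
    network: nx.Graph,
    seed: str,
    weights: dict[str, float],
    claimed: set[str],
    params: MCODEParams,
) -> set[str]:
    """Breadth-first expansion from the seed (each vertex in <= 1 complex)."""
    threshold = weights[seed] * (1.0 - params.node_score_cutoff)
    members = {seed}
    queue: deque[tuple[str, int]] = deque([(seed, 0)])
    while queue:
        v, depth = queue.popleft()
        if depth >= params.max_depth:
            continue
        for u in sorted(network[v]):
            if u in members or u in claimed:
                continue
            if weights[u] >= threshold:
                members.add(u)
                queue.append((u, depth + 1))
    return members


def _postprocess(
    network: nx.Graph, members: set[str], weights: dict[str, float],
    params: MCODEParams,
) -> set[str] | None:
    """Stage 3: k-core filter, optional fluff, optional haircut."""
    sub = network.subgraph(members)
    core = nx.core_number(sub)
    if not core or max(core.values()) < params.k_core:
        return None
    if params.fluff:
        boundary = set()
        for v in sorted(members):
            for u in sorted(network[v]):
                if u in members or u in boundary:
                    continue
                closed = set(network[u]) | {u}
                nbhd = network.subgraph(closed)
                n = nbhd.number_of_nodes()
                dens = network_density(n, nbhd.number_of_edges()) if n >= 2 else 0.0
                if dens > params.fluff_density_cutoff:
                    boundary.add(u)
        members = members | boundary
    if params.haircut:
        # iterated removal of degree-1 vertices == restriction to the 2-core
        # (plus the degenerate case of a complex that is a single edge)
        sub = network.subgraph(members).copy()
        while True:
            leaves = [v for v, d in sub.degree() if d < 2]
            if not leaves or sub.number_of_nodes() <= len(leaves):
                break
            sub.remove_nodes_from(leaves)
        members = set(sub.nodes)
    return members if members else None


def find_modules(network: nx.Graph, params: MCODEParams | None = None) -> list[GeneModule]:
    """Ranked MCODE complexes of a co-expression network.

    Seeding order, neighbor iteration and ranking ties are broken
    lexicographically by gene symbol, so results are deterministic.
    """
    params = params or MCODEParams()
    weights = vertex_weights(network, params.degree_cutoff)
    order = sorted(network.nodes, key=lambda v: (-weights[v], v))
    claimed: set[str] = set()
    modules: list[GeneModule] = []
    for seed in order:
        if seed in claimed or weights[seed] <= 0:
            continue
        members = _grow_complex(network, seed, weights, claimed, params)
        claimed |= members
        final = _postprocess(network, members, weights, params)
        if final is None:
            continue
        modules.append(module_from_genes(network, final))
    modules.sort(key=lambda m: (-m.avg_connectivity, -m.n_nodes, m.genes[0]))
    return [dataclasses.replace(m, rank=i + 1) for i, m in enumerate(modules)]


def module_from_genes(network: nx.Graph, genes: Sequence[str]) -> GeneModule:
    """Score a gene set against its parent network's induced subgraph."""
    genes = tuple(sorted(set(genes)))
    if not genes:
        raise ValueError("cannot score an empty module")
    sub = network.subgraph(genes)
    n, m = len(genes), sub.number_of_edges()
    density = network_density(n, m) if n >= 2 else 0.0
    return GeneModule(
        genes=genes,
        n_nodes=n,
        n_edges=m,
        density=density,
        avg_connectivity=score_module_counts(n, m),
        mcode_score=density * n,
    )


def score_module_counts(n_nodes: int, n_edges: int) -> float:
    """Average connectivity = edges per gene (the module ranking score)."""
    if n_nodes < 1:
        raise ValueError("module must have at least one node")
    return n_edges / n_nodes


def score_module(module: GeneModule) -> float:
    return score_module_counts(module.n_nodes, module.n_edges)


def select_modules(
    modules: Sequence[GeneModule],
    min_nodes: int = 10,
    min_avg_conn: float = 10.0,
    min_density: float = 0.80,
) -> list[GeneModule]:
    """Apply the selection filter: >= 10 nodes, avg connectivity >= 10,
    density >= 0.80 (order preserved)."""
    return [
        m
        for m in modules
        if m.n_nodes >= min_nodes
        and m.avg_connectivity >= min_avg_conn
        and m.density >= min_density
    ]
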