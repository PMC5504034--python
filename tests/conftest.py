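"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the library calls used by the package
(networkx metrics, statsmodels BH, scipy hypergeom) so that tests compare
two independent routes to the same quantity.
"""
from __future__ import annotations

import itertools
from collections import deque

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from coexmod.datatypes import DISEASED, HEALTHY, ExpressionDataset


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_dataset(
    values: np.ndarray,
    n_diseased: int,
    genes: list[str] | None = None,
    dataset_id: str = "toy",
) -> ExpressionDataset:
    """Wrap a genes x samples array into an ExpressionDataset."""
    values = np.asarray(values, dtype=float)
    n_genes, n_samples = values.shape
    genes = genes or [f"G{i + 1:03d}" for i in range(n_genes)]
    samples = [f"S{i + 1:03d}" for i in range(n_samples)]
    states = pd.Series(
        [DISEASED] * n_diseased + [HEALTHY] * (n_samples - n_diseased),
        index=samples,
    )
    frame = pd.DataFrame(values, index=pd.Index(genes, name="gene"), columns=samples)
    return ExpressionDataset(dataset_id, frame, states)


# ---------------------------------------------------------------------------
# graph oracles (pure-python, no networkx algorithms)
# ---------------------------------------------------------------------------

def brute_density(n_nodes: int, edges: set[tuple]) -> float:
    return 2.0 * len(edges) / (n_nodes * (n_nodes - 1))


def brute_clustering(nodes: list, edges: set[frozenset]) -> float:
    """Mean local clustering by direct triangle counting."""
    adj = {v: set() for v in nodes}
    for e in edges:
        u, v = tuple(e)
        adj[u].add(v)
        adj[v].add(u)
    total = 0.0
    for v in nodes:
        nbrs = sorted(adj[v])
        k = len(nbrs)
        if k < 2:
            continue
        links = sum(
            1
            for a, b in itertools.combinations(nbrs, 2)
            if frozenset((a, b)) in edges
        )
        total += 2.0 * links / (k * (k - 1))
    return total / len(nodes)


def brute_betweenness(nodes: list, edges: set[frozenset]) -> dict:
    """Unnormalized shortest-path betweenness by explicit path enumeration."""
    adj = {v: set() for v in nodes}
    for e in edges:
        u, v = tuple(e)
        adj[u].add(v)
        adj[v].add(u)

    def all_shortest_paths(s, t):
        # BFS distances from s, then DFS back-tracking along decreasing depth
        dist = {s: 0}
        q = deque([s])
        while q:
            u = q.popleft()
            for w in adj[u]:
                if w not in dist:
                    dist[w] = dist[u] + 1
                    q.append(w)
        if t not in dist:
            return []
        paths = []

        def walk(path):
            u = path[-1]
            if u == t:
                paths.append(list(path))
                return
            for w in adj[u]:
                if dist.get(w) == dist[u] + 1 and dist[w] <= dist[t]:
                    walk(path + [w])

        walk([s])
        return paths

    btw = {v: 0.0 for v in nodes}
    for s, t in itertools.combinations(nodes, 2):
        paths = all_shortest_paths(s, t)
        if not paths:
            continue
        for p in paths:
            for v in p[1:-1]:
                btw[v] += 1.0 / len(paths)
    return btw


def brute_core_numbers(nodes: list, edges: set[frozenset]) -> dict:
    """k-core decomposition by iterative minimum-degree peeling."""
    adj = {v: set() for v in nodes}
    for e in edges:
        u, v = tuple(e)
        adj[u].add(v)
        adj[v].add(u)
    core = {}
    remaining = set(nodes)
    k = 0
    while remaining:
        while True:
            peel = [v for v in remaining if len(adj[v] & remaining) < k + 1]
            if not peel:
                break
            for v in peel:
                core[v] = k
                remaining.discard(v)
        if remaining:
            k += 1
            for v in remaining:
                core[v] = k
    return core


def brute_bh(p: list[float]) -> list[float]:
    """Step-up BH by the definition: q_(i) = min_{j>=i} p_(j) * m / j."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [0.0] * m
    for rank, idx in enumerate(order, start=1):
        q[idx] = min(
            min(p[order[j - 1]] * m / j for j in range(rank, m + 1)), 1.0
        )
    return q


def brute_hypergeom_tail(N: int, K: int, n: int, k: int, universe=None) -> float:
    """P(overlap >= k) by enumerating every n-subset of an N-universe."""
    universe = list(range(N)) if universe is None else list(universe)
    success = set(universe[:K])
    hits = total = 0
    for draw in itertools.combinations(universe, n):
        total += 1
        if len(success.intersection(draw)) >= k:
            hits += 1
    return hits / total


def all_graphs(n: int):
    """Every labelled simple graph on n nodes (edge-subset enumeration)."""
    nodes = list(range(n))
    possible = list(itertools.combinations(nodes, 2))
    for bits in range(2 ** len(possible)):
        edges = {frozenset(e) for i, e in enumerate(possible) if bits >> i & 1}
        yield nodes, edges


def to_nx(nodes, edges) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(nodes)
    g.add_edges_from(tuple(e) for e in edges)
    return g
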