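"""Differential co-expression of a module between diseased and healthy states.

A module found in the diseased-state network is projected onto both state
networks and its topology compared.  Densities use the FULL module gene set
as denominator in both states (the convention that reproduces the reference
module's healthy-state density of 0.029 = 100 edges over C(84,2) pairs, not
100 over C(48,2)).  Significance comes from a state-label permutation null
in which the data-derived PCC cutoff is recomputed for every shuffle; the
source study asserts "significantly altered" topology without naming a
test, so the permutation scheme is this package's own addition.
"""
from __future__ import annotations

from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .coexnet import (
    MIN_VALUES_FOR_CUTOFF,
    avg_clustering_coefficient,
    empirical_cutoff,
    network_density,
    offdiagonal_values,
)
from .datatypes import DISEASED, HEALTHY, DifferentialCoexpressionReport

MIN_PERMUTATIONS = 99


def project_module(module_genes: Sequence[str], network: nx.Graph) -> nx.Graph:
    """Induced subgraph over the FULL module gene set.

    Genes absent from the network appear as isolated nodes; all network
    edges internal to the set are kept with their attributes.
    """
    genes = sorted(set(module_genes))
    sub = nx.Graph()
    sub.graph.update(network.graph)
    sub.add_nodes_from(genes)
    present = [g for g in genes if g in network]
    for u, v, data in network.subgraph(present).edges(data=True):
        sub.add_edge(u, v, **data)
    return sub


def compare_module_states(
    module_genes: Sequence[str],
    net_diseased: nx.Graph,
    net_healthy: nx.Graph,
) -> DifferentialCoexpressionReport:
    """Paired topology metrics of one module in the two state networks."""
    genes = tuple(sorted(set(module_genes)))
    if len(genes) < 2:
        raise ValueError("module must contain at least 2 genes")
    proj_d = project_module(genes, net_diseased)
    proj_h = project_module(genes, net_healthy)
    n = len(genes)
    return DifferentialCoexpressionReport(
        module_genes=genes,
        n_edges_diseased=proj_d.number_of_edges(),
        n_edges_healthy=proj_h.number_of_edges(),
        density_diseased=network_density(n, proj_d.number_of_edges()),
        density_healthy=network_density(n, proj_h.number_of_edges()),
        cc_diseased=avg_clustering_coefficient(proj_d),
        cc_healthy=avg_clustering_coefficient(proj_h),
        n_connected_healthy=sum(1 for _, d in proj_h.degree() if d > 0),
    )


def _module_density_delta(
    arr: np.ndarray,
    is_diseased: np.ndarray,
    module_idx: np.ndarray,
    alpha: float,
    symmetric: bool,
) -> float:
    """density(module, diseased) - density(module, healthy) for one labeling."""
    n_mod = module_idx.size
    denom = n_mod * (n_mod - 1) / 2
    densities = []
    for mask in (is_diseased, ~is_diseased):
        pcc = np.corrcoef(arr[:, mask])
        cut = empirical_cutoff(offdiagonal_values(pcc), alpha, symmetric=symmetric)
        sub = pcc[np.ix_(module_idx, module_idx)]
        vals = sub[np.triu_indices(n_mod, k=1)]
        m = int(np.sum((vals > cut.high) | (vals < cut.low)))
        densities.append(m / denom)
    return densities[0] - densities[1]


def permutation_significance(
    module_genes: Sequence[str],
    expression: pd.DataFrame,
    states: pd.Series,
    n_perm: int = 199,
    seed: int | np.random.Generator = 0,
    alpha: float = 0.05,
    symmetric: bool = True,
) -> float:
    """State-label permutation p-value for the module's density change.

    ``expression`` is the pooled genes x samples matrix over the full
    co-expression universe (the cutoff is data-derived, so it is recomputed
    inside each permutation); ``states`` labels every sample.  The statistic
    is T = density_diseased - density_healthy over the module's gene pairs,
    and ``p = (1 + #{T_perm >= T_obs}) / (n_perm + 1)``.
    """
    if n_perm < MIN_PERMUTATIONS:
        raise ValueError(f"need >= {MIN_PERMUTATIONS} permutations, got {n_perm}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    states = states.loc[expression.columns]
    is_diseased = (states == DISEASED).to_numpy()
    if is_diseased.sum() < 3 or (~is_diseased).sum() < 3:
        raise ValueError("need >= 3 samples in each state for the permutation test")
    gene_pos = {g: i for i, g in enumerate(expression.index)}
    module_idx = np.asarray(sorted(gene_pos[g] for g in set(module_genes) if g in gene_pos))
    if module_idx.size < 2:
        raise ValueError("fewer than 2 module genes present in the expression matrix")
    n_pairs = expression.shape[0] * (expression.shape[0] - 1) // 2
    if n_pairs < MIN_VALUES_FOR_CUTOFF:
        raise ValueError(
            "expression universe too small for an empirical cutoff "
            f"({n_pairs} gene pairs < {MIN_VALUES_FOR_CUTOFF})"
        )
    arr = expression.to_numpy(dtype=float)
    t_obs = _module_density_delta(arr, is_diseased, module_idx, alpha, symmetric)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(is_diseased)
        t_perm = _module_density_delta(arr, perm, module_idx, alpha, symmetric)
        if t_perm >= t_obs:
            count += 1
    return (1 + count) / (n_perm + 1)


def classify_differential(
    report: DifferentialCoexpressionReport,
    density_delta_min: float = 0.5,
    p_max: float = 0.05,
) -> bool:
    """Differentially co-expressed iff the density drop is large and
    significant: ``density_delta >= density_delta_min`` and ``p <= p_max``."""
    if report.p_value is None:
        raise ValueError("report has no permutation p-value; run the test first")
    flag = bool(report.density_delta >= density_delta_min and report.p_value <= p_max)
    report.is_differential = flag
    return flag
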