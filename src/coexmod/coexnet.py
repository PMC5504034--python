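"""State-wise Pearson co-expression networks and their topology metrics.

Edges connect gene pairs whose PCC magnitude exceeds a cutoff derived from
the empirical PCC distribution itself: the pairwise correlations are
approximately normal, so the two-sided alpha cutoff is ``mean + z_{1-a/2} *
sd``.  The negative cutoff mirrors the positive one by default (the study
applied symmetric cutoffs of +/-0.815); the asymmetric ``mean - z*sd``
variant is available via ``symmetric=False``.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import HubSet, TopologySummary, as_state_graph

MIN_SAMPLES_FOR_PCC = 3
MIN_VALUES_FOR_CUTOFF = 100


def pearson_matrix(values: pd.DataFrame) -> pd.DataFrame:
    """All-pairs Pearson correlation of gene expression profiles.

    ``values`` is genes x samples (>= 3 samples).  Zero-variance genes must
    be removed beforehand; one reaching this operation is a hard error.
    """
    if values.shape[1] < MIN_SAMPLES_FOR_PCC:
        raise ValueError(
            f"need >= {MIN_SAMPLES_FOR_PCC} samples to compute correlations, "
            f"got {values.shape[1]}"
        )
    arr = values.to_numpy(dtype=float)
    sd = arr.std(axis=1)
    if (sd == 0).any():
        gene = values.index[int(np.argmax(sd == 0))]
        raise ValueError(f"zero-variance gene {gene!r} in correlation input")
    pcc = np.corrcoef(arr)
    np.fill_diagonal(pcc, 1.0)
    return pd.DataFrame(pcc, index=values.index, columns=values.index)


def drop_zero_variance_genes(values: pd.DataFrame) -> pd.DataFrame:
    """Remove constant genes (with a warning) before correlation."""
    sd = values.to_numpy(dtype=float).std(axis=1)
    if (sd == 0).any():
        dropped = values.index[sd == 0].tolist()
        warnings.warn(f"dropping {len(dropped)} zero-variance gene(s): {dropped[:5]}")
        values = values.loc[sd > 0]
    return values


def offdiagonal_values(pcc: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Upper-triangle (i < j) correlations as a flat vector."""
    arr = np.asarray(pcc, dtype=float)
    iu = np.triu_indices_from(arr, k=1)
    return arr[iu]


@dataclass(frozen=True)
class CorrelationCutoff:
    low: float
    high: float
    mean: float
    sd: float
    alpha: float


def empirical_cutoff(
    values: Sequence[float], alpha: float = 0.05, symmetric: bool = True
) -> CorrelationCutoff:
    """Two-sided normal-quantile cutoff fitted to the PCC distribution.

    ``high = mean + z_{1-alpha/2} * sd``; ``low = -high`` when symmetric
    (default), else ``mean - z * sd``.  Note: with the study's printed
    distribution (mean 0.05, SD 0.39) this formula gives 0.814, a 0.001
    discrepancy from the printed 0.815 whose exact derivation is unstated;
    the formula, not the printed constant, is implemented.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < MIN_VALUES_FOR_CUTOFF:
        raise ValueError(
            f"need >= {MIN_VALUES_FOR_CUTOFF} correlation values, got {arr.size}"
        )
    mean, sd = float(arr.mean()), float(arr.std())
    if sd < 1e-12:  # constant input up to rounding
        raise ValueError("correlation values have zero spread; no cutoff exists")
    z = float(stats.norm.ppf(1 - alpha / 2))
    high = mean + z * sd
    low = -high if symmetric else mean - z * sd
    return CorrelationCutoff(low=low, high=high, mean=mean, sd=sd, alpha=alpha)


def build_network(
    pcc: pd.DataFrame, cutoff: CorrelationCutoff, state: str
) -> nx.Graph:
    """Edge (i, j) iff pcc > high or pcc < low; isolated genes are dropped.

    The study's node counts (237 and 455 genes out of 698) imply that genes
    without any super-threshold partner were not part of the networks.
    """
    g = as_state_graph(state)
    arr = pcc.to_numpy(dtype=float)
    genes = list(pcc.index)
    ii, jj = np.where(np.triu((arr > cutoff.high) | (arr < cutoff.low), k=1))
    for i, j in zip(ii, jj):
        r = float(arr[i, j])
        g.add_edge(genes[i], genes[j], pcc=r, sign="+" if r > 0 else "-")
    return g


def network_density(n_nodes: int, n_edges: int) -> float:
    """Undirected simple-graph density ``2m / (n(n-1))``."""
    if n_nodes < 2:
        raise ValueError(f"density undefined for {n_nodes} node(s)")
    return 2.0 * n_edges / (n_nodes * (n_nodes - 1))


def graph_density(network: nx.Graph) -> float:
    return network_density(network.number_of_nodes(), network.number_of_edges())


def avg_clustering_coefficient(network: nx.Graph) -> float:
    """Mean local clustering coefficient; degree < 2 nodes contribute 0."""
    if network.number_of_nodes() < 1:
        raise ValueError("clustering coefficient undefined for an empty graph")
    return float(nx.average_clustering(network))


def scale_free_fit(degrees: Sequence[int]) -> float:
    """R^2 of log10(frequency) on log10(degree) over distinct positive degrees."""
    degs = np.asarray([d for d in degrees if d > 0], dtype=float)
    ks, counts = np.unique(degs, return_counts=True)
    if ks.size < 3:
        raise ValueError(
            f"scale-free fit needs >= 3 distinct positive degrees, got {ks.size}"
        )
    fit = stats.linregress(np.log10(ks), np.log10(counts))
    return float(fit.rvalue**2)


def betweenness(network: nx.Graph) -> dict[str, float]:
    """Exact unnormalized shortest-path betweenness (Brandes accumulation)."""
    return {n: float(b) for n, b in
            nx.betweenness_centrality(network, normalized=False).items()}


def dual_metric_hubs(network: nx.Graph, k: int = 5) -> HubSet:
    """Union of the top-k genes by degree and by betweenness centrality.

    Ties at rank k are all included; if every node ties, all nodes are hubs
    (with a warning).
    """
    if network.number_of_nodes() < k:
        raise ValueError(f"need >= {k} nodes to call top-{k} hubs")
    degree = {n: int(d) for n, d in network.degree()}
    btw = betweenness(network)

    def top_with_ties(metric: Mapping[str, float]) -> set[str]:
        ranked = sorted(metric.items(), key=lambda kv: (-kv[1], kv[0]))
        threshold = ranked[k - 1][1]
        return {n for n, v in metric.items() if v >= threshold}

    hubs = top_with_ties(degree) | top_with_ties(btw)
    if len(hubs) == network.number_of_nodes() and network.number_of_nodes() > k:
        warnings.warn("all nodes tie on both hub metrics; every node reported as hub")
    return HubSet(hubs=tuple(sorted(hubs)), degree=degree, betweenness=btw)


def topology_summary(network: nx.Graph) -> TopologySummary:
    degrees = tuple(sorted((int(d) for _, d in network.degree()), reverse=True))
    try:
        r2 = scale_free_fit(degrees)
    except ValueError:
        r2 = None
    n, m = network.number_of_nodes(), network.number_of_edges()
    return TopologySummary(
        state=str(network.graph.get("state", "unknown")),
        n_nodes=n,
        n_edges=m,
        density=network_density(n, m) if n >= 2 else 0.0,
        avg_clustering=avg_clustering_coefficient(network) if n else 0.0,
        degree_sequence=degrees,
        scale_free_r2=r2,
    )
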