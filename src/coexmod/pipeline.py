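"""End-to-end orchestration of the differential co-expression analysis.

Stage order follows the method: per-dataset differential expression with the
moderated t; intersection to mutual DEGs; state-wise pooling, duplicate
collapsing and quantile renormalization; empirical-cutoff PCC networks per
state; MCODE module detection and the selection filter on the diseased-state
network; differential co-expression of the top module with a permutation
test; and, when survival records are supplied, PCA + k-means stratification
with Kaplan-Meier / log-rank / Cox statistics.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from . import coexnet, diffcoexp, diffexpr, mcode, prognosis
from .config import STREAM_PERMUTATION, PipelineConfig, substream
from .datatypes import (
    DISEASED,
    HEALTHY,
    DifferentialCoexpressionReport,
    ExpressionDataset,
    GeneModule,
    GroundTruth,
    SurvivalResult,
    TopologySummary,
)


@dataclass
class PipelineResult:
    deg_tables: dict[str, pd.DataFrame]
    mutual_degs: frozenset[str]
    pooled_expression: pd.DataFrame | None  # mutual genes x all samples
    states: pd.Series | None
    networks: dict[str, nx.Graph] = field(default_factory=dict)
    cutoffs: dict[str, coexnet.CorrelationCutoff] = field(default_factory=dict)
    summaries: dict[str, TopologySummary] = field(default_factory=dict)
    modules: dict[str, list[GeneModule]] = field(default_factory=dict)
    selected_modules: list[GeneModule] = field(default_factory=list)
    top_module: GeneModule | None = None
    dc_report: DifferentialCoexpressionReport | None = None
    pca_variance_fraction: float | None = None
    cluster_labels: pd.Series | None = None
    survival_result: SurvivalResult | None = None

    def summary_dict(self) -> dict:
        out: dict = {
            "n_mutual_degs": len(self.mutual_degs),
            "deg_counts": {k: int((t["direction"] != "ns").sum())
                           for k, t in self.deg_tables.items()},
        }
        for state in self.networks:
            out[f"network_{state}"] = self.summaries[state].as_dict()
            out[f"cutoff_{state}"] = {
                "low": self.cutoffs[state].low,
                "high": self.cutoffs[state].high,
                "mean": self.cutoffs[state].mean,
                "sd": self.cutoffs[state].sd,
            }
            out[f"n_modules_{state}"] = len(self.modules.get(state, []))
        out["n_selected_modules"] = len(self.selected_modules)
        if self.top_module is not None:
            out["top_module"] = self.top_module.as_dict()
        if self.dc_report is not None:
            out["differential_coexpression"] = self.dc_report.as_dict()
        if self.pca_variance_fraction is not None:
            out["pca_variance_fraction"] = self.pca_variance_fraction
        if self.survival_result is not None:
            out["survival"] = self.survival_result.as_dict()
        return out


def pool_states(
    datasets: Sequence[ExpressionDataset], genes: Sequence[str]
) -> tuple[pd.DataFrame, pd.Series]:
    """Concatenate all datasets' samples, renormalize, restrict to ``genes``.

    Duplicate gene rows are collapsed per dataset first.  Each state's
    pooled sub-matrix is quantile normalized over the FULL shared gene
    universe (renormalization operates on whole arrays, as array-level
    summarization does), and only then restricted to the requested genes.
    """
    genes = sorted(set(genes))
    collapsed = [diffexpr.collapse_duplicate_genes(ds) for ds in datasets]
    shared = set(collapsed[0].values.index)
    for ds in collapsed[1:]:
        shared &= set(ds.values.index)
    missing = set(genes) - shared
    if missing:
        raise ValueError(
            f"{len(missing)} requested gene(s) absent from some dataset, "
            f"e.g. {sorted(missing)[:5]}"
        )
    universe = sorted(shared)
    pooled = pd.concat([ds.values.loc[universe] for ds in collapsed], axis=1)
    state = pd.concat([ds.states for ds in collapsed])
    norm_parts = []
    for s in (DISEASED, HEALTHY):
        cols = state.index[state == s]
        sub = ExpressionDataset(f"pooled_{s}", pooled[cols], state.loc[cols])
        norm_parts.append(diffexpr.quantile_normalize(sub).values)
    pooled = pd.concat(norm_parts, axis=1)[pooled.columns]
    return pooled.loc[genes], state.loc[pooled.columns]


def state_network(
    pooled: pd.DataFrame,
    states: pd.Series,
    state: str,
    config: PipelineConfig,
) -> tuple[nx.Graph, coexnet.CorrelationCutoff]:
    cols = states.index[states == state]
    values = coexnet.drop_zero_variance_genes(pooled[cols])
    pcc = coexnet.pearson_matrix(values)
    cutoff = coexnet.empirical_cutoff(
        coexnet.offdiagonal_values(pcc), config.corr_alpha,
        symmetric=config.symmetric_cutoff,
    )
    return coexnet.build_network(pcc, cutoff, state), cutoff


def run_pipeline(
    datasets: Sequence[ExpressionDataset],
    config: PipelineConfig | None = None,
    survival: pd.DataFrame | None = None,
    min_mutual_genes: int = 15,
) -> PipelineResult:
    """Run the full analysis on a collection of two-state datasets.

    ``survival`` (optional) carries ``sample, time, event`` records for a
    subset of the diseased samples; clusters are estimated from the top
    module's expression, never taken from the input table.
    """
    config = config or PipelineConfig()
    deg_tables = {
        ds.dataset_id: diffexpr.moderated_t_test(
            ds, alpha=config.deg_alpha, fc_up=config.fc_up, fc_down=config.fc_down
        )
        for ds in datasets
    }
    if len(datasets) >= 2:
        mutual = diffexpr.intersect_mutual_degs(
            [diffexpr.deg_gene_set(t) for t in deg_tables.values()]
        )
    else:
        mutual = diffexpr.deg_gene_set(next(iter(deg_tables.values())))
    result = PipelineResult(
        deg_tables=deg_tables, mutual_degs=mutual,
        pooled_expression=None, states=None,
    )
    if len(mutual) < min_mutual_genes:
        return result

    pooled, states = pool_states(datasets, mutual)
    result.pooled_expression, result.states = pooled, states
    for state in (DISEASED, HEALTHY):
        net, cutoff = state_network(pooled, states, state, config)
        result.networks[state] = net
        result.cutoffs[state] = cutoff
        result.summaries[state] = coexnet.topology_summary(net)
        result.modules[state] = mcode.find_modules(net, config.mcode)

    result.selected_modules = mcode.select_modules(
        result.modules[DISEASED],
        min_nodes=config.min_nodes,
        min_avg_conn=config.min_avg_conn,
        min_density=config.min_density,
    )
    if not result.selected_modules:
        return result
    top = result.selected_modules[0]
    result.top_module = top

    report = diffcoexp.compare_module_states(
        top.genes, result.networks[DISEASED], result.networks[HEALTHY]
    )
    report.p_value = diffcoexp.permutation_significance(
        top.genes,
        pooled,
        states,
        n_perm=config.n_permutations,
        seed=substream(config.rng_seed, STREAM_PERMUTATION),
        alpha=config.corr_alpha,
        symmetric=config.symmetric_cutoff,
    )
    diffcoexp.classify_differential(
        report, density_delta_min=config.density_delta_min, p_max=config.perm_p_max
    )
    result.dc_report = report

    if survival is not None:
        diseased_cols = states.index[states == DISEASED]
        cohort = [s for s in survival["sample"] if s in set(diseased_cols)]
        if len(cohort) >= config.pca_components + 2:
            module_expr = pooled.loc[list(top.genes), cohort].T
            pca = prognosis.pca_first_k(
                module_expr, k=config.pca_components, zscore=config.zscore_pca
            )
            result.pca_variance_fraction = pca.variance_fraction
            labels = prognosis.kmeans2(
                pca.scores, seed=config.rng_seed, n_restarts=config.kmeans_restarts
            )
            result.cluster_labels = labels
            table = survival.loc[survival["sample"].isin(cohort),
                                 ["sample", "time", "event"]].copy()
            table["cluster"] = labels.loc[table["sample"]].to_numpy()
            result.survival_result = prognosis.analyze_survival(table)
    return result


def recovery_metrics(module: GeneModule, truth: GroundTruth) -> dict[str, float]:
    """Fraction of planted genes recovered and of intruder genes included."""
    found = set(module.genes)
    planted = set(truth.module_genes)
    return {
        "recovered_fraction": len(found & planted) / len(planted) if planted else 0.0,
        "intruder_fraction": len(found - planted) / len(found) if found else 0.0,
    }


def align_clusters(labels: pd.Series, truth: Mapping[str, int]) -> pd.Series:
    """Relabel estimated clusters to best match ground-truth labels."""
    common = [s for s in labels.index if s in truth]
    if not common:
        return labels
    agree = sum(labels[s] == truth[s] for s in common)
    if agree >= len(common) / 2:
        return labels
    return labels.map({1: 2, 2: 1})
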