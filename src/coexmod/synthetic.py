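"""Synthetic two-state expression studies with planted structure.

The generator emulates the statistical structure the analysis assumes:
several datasets sharing a core of truly differential genes; a planted gene
block whose members are strongly pairwise-correlated in the diseased state
(single latent factor per diseased sample, loading ``sqrt(r)`` so the
within-block PCC equals ``module_corr``) and independent noise in the
healthy state; survival times whose hazard depends on a latent sample
cluster defined by the sign of the module factor; and regulator tables in
which a few TFs each cover most of the planted block while miRNA targeting
is dispersed.

Defaults mirror the reference study's conditions: 6 datasets totalling 140
diseased and 51 healthy samples, an 84-gene block at r = 0.9 (0 when
healthy) and a true hazard ratio of 2.36 between latent clusters.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .config import (
    STREAM_REGULATORS,
    STREAM_SIMULATE,
    STREAM_SURVIVAL,
    substream,
)
from .datatypes import (
    DISEASED,
    HEALTHY,
    MIRNA,
    TF,
    ExpressionDataset,
    GroundTruth,
    RegulatorMap,
)


@dataclass
class SyntheticConfig:
    """Study-condition parameters of the generator.

    Sample totals are split as evenly as possible across datasets.  Baseline
    log2 intensities are uniform on ``baseline_range``; planted DEGs are
    shifted by ``deg_log2fc`` (log2 units, sign per gene); residual noise is
    Gaussian with ``noise_sd`` log2 units.  Survival times are exponential
    with rate ``baseline_hazard`` (per month) in cluster 1 and
    ``baseline_hazard * hazard_ratio`` in cluster 2, with administrative
    censoring at the empirical ``1 - censoring_rate`` quantile.
    """

    n_datasets: int = 6
    genes_total: int = 4000
    n_diseased_total: int = 140
    n_healthy_total: int = 51
    planted_module_size: int = 84
    module_corr: float = 0.9
    healthy_corr: float = 0.0
    deg_fraction: float = 0.05
    deg_log2fc: float = 2.0
    noise_sd: float = 0.5
    baseline_range: tuple[float, float] = (4.0, 14.0)
    batch_shift_sd: float = 0.0  # per-dataset gene-wise offsets (off by default)
    baseline_hazard: float = 1.0 / 60.0
    hazard_ratio: float = 2.36
    censoring_rate: float = 0.30
    n_tfs: int = 6
    tf_coverage: float = 0.89
    n_mirnas: int = 40
    mirna_target_max: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(self.module_corr) >= 1 or abs(self.healthy_corr) >= 1:
            raise ValueError("|module_corr| and |healthy_corr| must be < 1")
        if self.module_corr < 0 or self.healthy_corr < 0:
            raise ValueError("block correlations must be >= 0")
        if self.planted_module_size > self.genes_total:
            raise ValueError("planted_module_size cannot exceed genes_total")
        if self.hazard_ratio <= 0 or self.baseline_hazard <= 0:
            raise ValueError("hazard ratio and baseline hazard must be > 0")
        if not (0 <= self.censoring_rate < 1):
            raise ValueError("censoring_rate must be in [0, 1)")
        if not (0 <= self.deg_fraction <= 1):
            raise ValueError("deg_fraction must be in [0, 1]")
        if self.n_datasets < 1 or self.genes_total < 1:
            raise ValueError("need at least one dataset and one gene")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")


def _split_evenly(total: int, parts: int) -> list[int]:
    base, extra = divmod(total, parts)
    return [base + (1 if i < extra else 0) for i in range(parts)]


def _block_values(
    rng: np.random.Generator, z: np.ndarray, n_genes: int, corr: float, sd: float
) -> np.ndarray:
    """Factor-model draws: ``sd * (sqrt(r) z_s + sqrt(1-r) eps)`` (genes x samples)."""
    eps = rng.standard_normal((n_genes, z.size))
    return sd * (math.sqrt(corr) * z[None, :] + math.sqrt(1.0 - corr) * eps)


def generate_two_state_dataset(
    config: SyntheticConfig,
) -> tuple[list[ExpressionDataset], GroundTruth]:
    """Generate the full multi-dataset study and its ground truth.

    All datasets share one gene universe; the planted DEG core (which
    contains the planted module) is shifted in every dataset, so the
    per-dataset DEG calls intersect back to the core.  Latent sample
    clusters are the sign of the module factor: cluster 2 samples (z >= 0)
    express the block above its diseased-state mean.
    """
    rng = substream(config.seed, STREAM_SIMULATE)
    width = len(str(config.genes_total))
    genes = np.array([f"G{i + 1:0{width}d}" for i in range(config.genes_total)])

    n_core = max(int(round(config.deg_fraction * config.genes_total)),
                 config.planted_module_size)
    core = rng.choice(genes, size=n_core, replace=False)
    module = frozenset(core[: config.planted_module_size])
    directions = dict(zip(core, rng.choice(["up", "down"], size=n_core)))
    shift = {
        g: (config.deg_log2fc if d == "up" else -config.deg_log2fc)
        for g, d in directions.items()
    }
    baseline = pd.Series(
        rng.uniform(*config.baseline_range, size=config.genes_total), index=genes
    )
    # differential genes stay inside the globally dense intensity range even
    # after shifting (as on real arrays, where intensities are bounded);
    # otherwise renormalization flattens profiles in the sparse tails
    lo, hi = config.baseline_range
    lo_core, hi_core = lo + abs(config.deg_log2fc), hi - abs(config.deg_log2fc)
    if hi_core <= lo_core:
        raise ValueError("deg_log2fc too large for the baseline range")
    baseline.loc[core] = rng.uniform(lo_core, hi_core, size=n_core)
    module_mask = np.isin(genes, list(module))
    shift_vec = np.array([shift.get(g, 0.0) for g in genes])

    n_dis = _split_evenly(config.n_diseased_total, config.n_datasets)
    n_hea = _split_evenly(config.n_healthy_total, config.n_datasets)
    datasets: list[ExpressionDataset] = []
    cluster_labels: dict[str, int] = {}
    factor_scores: dict[str, float] = {}
    for d in range(config.n_datasets):
        ds_id = f"DS{d + 1}"
        dis_samples = [f"{ds_id}_D{i + 1:03d}" for i in range(n_dis[d])]
        hea_samples = [f"{ds_id}_H{i + 1:03d}" for i in range(n_hea[d])]
        nG = config.genes_total

        dis = baseline.to_numpy()[:, None] + shift_vec[:, None] + \
            config.noise_sd * rng.standard_normal((nG, len(dis_samples)))
        z = rng.standard_normal(len(dis_samples))
        if module and len(dis_samples):
            dis[module_mask, :] = (
                baseline.to_numpy()[module_mask, None]
                + shift_vec[module_mask, None]
                + _block_values(rng, z, int(module_mask.sum()),
                                config.module_corr, config.noise_sd)
            )
        for s, zs in zip(dis_samples, z):
            cluster_labels[s] = 2 if zs >= 0 else 1
            factor_scores[s] = float(zs)

        hea = baseline.to_numpy()[:, None] + \
            config.noise_sd * rng.standard_normal((nG, len(hea_samples)))
        if module and len(hea_samples) and config.healthy_corr > 0:
            zh = rng.standard_normal(len(hea_samples))
            hea[module_mask, :] = baseline.to_numpy()[module_mask, None] + _block_values(
                rng, zh, int(module_mask.sum()), config.healthy_corr, config.noise_sd
            )
        values = pd.DataFrame(
            np.hstack([dis, hea]),
            index=pd.Index(genes, name="gene"),
            columns=dis_samples + hea_samples,
        )
        if config.batch_shift_sd > 0:
            values = values.add(
                rng.normal(0.0, config.batch_shift_sd, size=nG), axis=0
            )
        states = pd.Series(
            [DISEASED] * len(dis_samples) + [HEALTHY] * len(hea_samples),
            index=values.columns,
            name="state",
        )
        datasets.append(ExpressionDataset(ds_id, values, states))

    truth = GroundTruth(
        module_genes=module,
        deg_directions=directions,
        cluster_labels=cluster_labels,
        factor_scores=factor_scores,
    )
    return datasets, truth


def generate_survival(
    config: SyntheticConfig,
    cluster_labels: Mapping[str, int],
    seed: int | None = None,
) -> pd.DataFrame:
    """Exponential survival with hazard ``h0`` (cluster 1) vs ``h0*HR``
    (cluster 2) and administrative censoring at a config quantile.

    Returns a table with columns ``sample, time, event, cluster`` (the true
    cluster; the pipeline replaces it with its own estimate before testing).
    """
    if not cluster_labels:
        raise ValueError("cluster_labels is empty")
    labels = pd.Series(dict(cluster_labels)).sort_index()
    bad = sorted(set(labels.unique()) - {1, 2})
    if bad:
        raise ValueError(f"cluster labels must be 1 or 2, found {bad}")
    if labels.nunique() < 2:
        raise ValueError("both clusters must be non-empty")
    rng = substream(seed if seed is not None else config.seed, STREAM_SURVIVAL)
    rate = np.where(labels.to_numpy() == 2,
                    config.baseline_hazard * config.hazard_ratio,
                    config.baseline_hazard)
    t_event = rng.exponential(1.0 / rate)
    if config.censoring_rate > 0:
        cutoff = float(np.quantile(t_event, 1.0 - config.censoring_rate))
        event = (t_event <= cutoff).astype(int)
        time = np.minimum(t_event, cutoff)
    else:
        event = np.ones(t_event.size, dtype=int)
        time = t_event
    return pd.DataFrame(
        {
            "sample": labels.index,
            "time": time,
            "event": event,
            "cluster": labels.to_numpy(),
        }
    )


def generate_regulator_map(
    config: SyntheticConfig,
    module_genes: Mapping | frozenset | list,
    seed: int | None = None,
    background_genes: list[str] | None = None,
) -> RegulatorMap:
    """Planted regulator tables: a handful of broad TFs, dispersed miRNAs.

    The planted TFs co-regulate one shared pool of ``ceil(tf_coverage *
    |module|)`` module genes (so each TF, and their union, covers the
    configured fraction — a few master regulators dominating the module),
    plus distinct random background targets when a background universe is
    given.  Each miRNA targets a small random module subset of size 1 to
    ``mirna_target_max``.
    """
    module = sorted(set(module_genes))
    if not module:
        raise ValueError("module_genes is empty")
    rng = substream(seed if seed is not None else config.seed, STREAM_REGULATORS)
    background = sorted(set(background_genes or []) - set(module))
    rmap = RegulatorMap()
    n_per_tf = math.ceil(config.tf_coverage * len(module))
    pool = list(rng.choice(module, size=n_per_tf, replace=False))
    for i in range(config.n_tfs):
        targets = list(pool)
        if background:
            n_bg = min(len(background), n_per_tf)
            targets += list(rng.choice(background, size=n_bg, replace=False))
        rmap.add(f"TF{i + 1:02d}", TF, targets)
    for i in range(config.n_mirnas):
        size = int(rng.integers(1, config.mirna_target_max + 1))
        targets = list(rng.choice(module, size=min(size, len(module)), replace=False))
        rmap.add(f"miR-{i + 1:03d}", MIRNA, targets)
    return rmap
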