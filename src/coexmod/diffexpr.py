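"""Per-dataset differential expression with an empirical-Bayes moderated t.

The test statistic shrinks each gene's pooled two-sample variance toward a
prior variance ``s0^2`` with prior degrees of freedom ``d0`` estimated from
all genes, then refers the moderated t to a t distribution with ``d0 + d_g``
degrees of freedom.  The hyperparameters are fitted by matching the mean and
variance of the log sample variances to the scaled-F prior predictive
(digamma/trigamma moment equations).  P-values are adjusted by the
Benjamini-Hochberg step-up rule and genes are filtered at adjusted p < 0.01
with linear fold change > 2.0 or < 0.5.
"""
from __future__ import annotations

import math
import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from statsmodels.stats.multitest import multipletests

from .datatypes import DISEASED, HEALTHY, ExpressionDataset, ModeratedVariancePrior

MIN_GENES_FOR_PRIOR = 10

DEG_COLUMNS = ["gene", "log2fc", "t_mod", "df_total", "p", "p_adj", "direction"]


def collapse_duplicate_genes(dataset: ExpressionDataset) -> ExpressionDataset:
    """Average duplicate gene rows per sample (one row per symbol afterwards)."""
    if dataset.values.index.is_unique:
        return dataset
    collapsed = dataset.values.groupby(level=0, sort=False).mean()
    return dataset.copy_with(collapsed)


def quantile_normalize(dataset: ExpressionDataset) -> ExpressionDataset:
    """Force every sample onto the common empirical distribution.

    The reference distribution is the row-wise mean of the per-sample sorted
    value vectors; tied values within a sample share the mean of their target
    quantiles.  After normalization all samples have identical sorted values
    (exactly, up to ties).
    """
    values = dataset.values
    if values.shape[1] < 2:
        raise ValueError("quantile normalization needs at least 2 samples")
    arr = values.to_numpy(dtype=float)
    reference = np.sort(arr, axis=0).mean(axis=1)
    out = np.empty_like(arr)
    for j in range(arr.shape[1]):
        col = arr[:, j]
        order = np.argsort(col, kind="mergesort")
        mapped = np.empty_like(col)
        mapped[order] = reference
        # ties: every occurrence of an identical input value receives the
        # mean of the reference values its occurrences were assigned
        col_s = pd.Series(col)
        tied = col_s.duplicated(keep=False).to_numpy()
        if tied.any():
            means = pd.Series(mapped).groupby(col_s).transform("mean").to_numpy()
            mapped[tied] = means[tied]
        out[:, j] = mapped
    return dataset.copy_with(pd.DataFrame(out, index=values.index, columns=values.columns))


def _trigamma_inverse(y: float) -> float:
    """Solve ``polygamma(1, x) = y`` for x > 0 (trigamma is decreasing)."""
    if y <= 0:
        raise ValueError("trigamma inverse requires a positive argument")
    f = lambda x: special.polygamma(1, x) - y
    lo, hi = 1e-8, 1e8
    if f(lo) < 0:  # y above trigamma(1e-8): essentially x -> 0
        return lo
    if f(hi) > 0:  # y below trigamma(1e8): essentially x -> inf
        return hi
    return float(optimize.brentq(f, lo, hi, xtol=1e-12, rtol=1e-12))


def fit_variance_prior(
    variances: Sequence[float], df: Sequence[float] | float
) -> ModeratedVariancePrior:
    """Estimate (d0, s0^2) from gene-wise residual variances.

    Matches the mean and variance of ``log s_g^2`` to the scaled-F prior
    predictive ``s_g^2 ~ s0^2 F(d_g, d0)``.  If the empirical variance of the
    log variances does not exceed what sampling alone explains, the moment
    equation has no positive solution and ``d0 = +inf`` is returned with
    ``s0^2`` equal to the df-weighted mean variance.
    """
    variances = np.asarray(variances, dtype=float)
    df_arr = np.broadcast_to(np.asarray(df, dtype=float), variances.shape).copy()
    ok = df_arr >= 1
    variances, df_arr = variances[ok], df_arr[ok]
    if variances.size < MIN_GENES_FOR_PRIOR:
        raise ValueError(
            f"need >= {MIN_GENES_FOR_PRIOR} genes with df >= 1 to fit the prior, "
            f"got {variances.size}"
        )
    if np.all(variances == 0):
        raise ValueError("all gene variances are zero; cannot fit a variance prior")
    positive = variances > 0
    if not positive.all():
        warnings.warn(
            f"{(~positive).sum()} zero-variance gene(s) excluded from the prior fit"
        )
        variances, df_arr = variances[positive], df_arr[positive]

    z = np.log(variances)
    # E[log s^2] = log sigma^2 + psi(d/2) - log(d/2); remove the sampling bias
    e = z - special.digamma(df_arr / 2) + np.log(df_arr / 2)
    mean_e = float(e.mean())
    if variances.size < 2 or np.allclose(z, z[0]):
        d0 = math.inf
    else:
        excess = float(np.var(z, ddof=1)) - float(
            np.mean(special.polygamma(1, df_arr / 2))
        )
        d0 = 2 * _trigamma_inverse(excess) if excess > 0 else math.inf
    if math.isinf(d0):
        s0_sq = float(np.sum(df_arr * variances) / np.sum(df_arr))
    else:
        s0_sq = float(np.exp(mean_e + special.digamma(d0 / 2) - np.log(d0 / 2)))
    return ModeratedVariancePrior(d0=d0, s0_sq=s0_sq)


def moderated_t_test(
    dataset: ExpressionDataset,
    prior: ModeratedVariancePrior | None = None,
    alpha: float = 0.01,
    fc_up: float = 2.0,
    fc_down: float = 0.5,
) -> pd.DataFrame:
    """Moderated two-sample t-test of diseased vs healthy, per gene.

    Returns a DEG table with columns ``gene, log2fc, t_mod, df_total, p,
    p_adj, direction`` where ``log2fc`` is the diseased-minus-healthy mean
    difference on the log2 scale and ``direction`` applies the thresholds
    (``up``/``down``/``ns``).  Genes with zero variance in both groups and a
    zero mean difference get p = 1 (flagged, not an error).
    """
    dataset = collapse_duplicate_genes(dataset)
    xs = dataset.state_matrix(DISEASED).to_numpy(dtype=float)
    ys = dataset.state_matrix(HEALTHY).to_numpy(dtype=float)
    n1, n2 = xs.shape[1], ys.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValueError(
            f"need >= 2 samples per state for the moderated t-test, got "
            f"{n1} diseased / {n2} healthy"
        )
    m1, m2 = xs.mean(axis=1), ys.mean(axis=1)
    rss = ((xs - m1[:, None]) ** 2).sum(axis=1) + ((ys - m2[:, None]) ** 2).sum(axis=1)
    dg = n1 + n2 - 2
    s_sq = rss / dg
    if prior is None:
        prior = fit_variance_prior(s_sq, dg)
    d0, s0_sq = prior.d0, prior.s0_sq
    if math.isinf(d0):
        s_tilde_sq = np.full_like(s_sq, s0_sq)
        df_total = math.inf
    else:
        s_tilde_sq = (d0 * s0_sq + dg * s_sq) / (d0 + dg)
        df_total = d0 + dg
    log2fc = m1 - m2
    denom = np.sqrt(s_tilde_sq * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = np.where(denom > 0, log2fc / denom, np.where(log2fc == 0, 0.0, np.inf))
    t_mod = np.where((denom == 0) & (log2fc < 0), -np.inf, t_mod)
    if (denom == 0).any():
        warnings.warn(
            f"{int((denom == 0).sum())} gene(s) with zero moderated variance flagged"
        )
    p = 2 * stats.t.sf(np.abs(t_mod), df_total)
    p = np.clip(p, 0.0, 1.0)
    table = pd.DataFrame(
        {
            "gene": dataset.values.index,
            "log2fc": log2fc,
            "t_mod": t_mod,
            "df_total": df_total,
            "p": p,
            "p_adj": bh_adjust(p),
        }
    )
    fc = 2.0 ** table["log2fc"]
    passes = (table["p_adj"] < alpha) & ((fc > fc_up) | (fc < fc_down))
    table["direction"] = np.where(
        passes & (table["log2fc"] > 0), "up", np.where(passes, "down", "ns")
    )
    return table.reset_index(drop=True)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def filter_degs(
    table: pd.DataFrame,
    alpha: float = 0.01,
    fc_up: float = 2.0,
    fc_down: float = 0.5,
) -> pd.DataFrame:
    """Keep genes with adjusted p < alpha and fold change > fc_up or < fc_down."""
    fc = 2.0 ** table["log2fc"]
    keep = (table["p_adj"] < alpha) & ((fc > fc_up) | (fc < fc_down))
    out = table.loc[keep].copy()
    out["direction"] = np.where(out["log2fc"] > 0, "up", "down")
    return out.reset_index(drop=True)


def deg_gene_set(table: pd.DataFrame) -> frozenset[str]:
    """Genes called differentially expressed in a DEG table."""
    if "direction" in table.columns:
        return frozenset(table.loc[table["direction"] != "ns", "gene"])
    return frozenset(table["gene"])


def intersect_mutual_degs(deg_sets: Sequence[Iterable[str]]) -> frozenset[str]:
    """Direction-agnostic intersection of per-dataset DEG sets.

    Direction is ignored deliberately: regulation patterns can disagree
    between datasets while the same genes keep being called.
    """
    sets = [frozenset(s) for s in deg_sets]
    if len(sets) < 2:
        raise ValueError("need at least 2 DEG sets to intersect")
    mutual = frozenset.intersection(*sets)
    if not mutual:
        warnings.warn("the mutual DEG set is empty")
    return mutual
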