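"""Survival stratification by module expression and its statistics.

Samples are projected onto the first K principal components of the module
gene expression (genes z-scored by default), split into two clusters by
k-means, and the clusters compared via Kaplan-Meier curves, the two-group
log-rank test and a single-covariate Cox proportional-hazards model
(Breslow tie handling, Newton-Raphson to |delta beta| < 1e-8).
"""
from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

from .config import STREAM_KMEANS, derived_int_seed
from .datatypes import CoxResult, LogrankResult, PCAResult, SurvivalResult

NEWTON_TOL = 1e-8
MAX_NEWTON_ITER = 100
_Z975 = 1.959963984540054


def pca_first_k(
    expression: pd.DataFrame, k: int = 3, zscore: bool = True
) -> PCAResult:
    """Scores on the top-k principal components of a samples x genes matrix.

    Genes are z-scored across samples by default (raw centering via
    ``zscore=False``); constant genes are excluded with a warning.  Each
    component's orientation is fixed by making its largest-magnitude loading
    positive, so results are deterministic.
    """
    if expression.shape[0] < k + 1:
        raise ValueError(f"need >= {k + 1} samples for {k} components")
    X = expression.to_numpy(dtype=float)
    sd = X.std(axis=0)
    if (sd == 0).any():
        dropped = expression.columns[sd == 0].tolist()
        warnings.warn(f"excluding {len(dropped)} constant gene(s) from PCA: {dropped[:5]}")
        expression = expression.loc[:, sd > 0]
        X, sd = X[:, sd > 0], sd[sd > 0]
    if expression.shape[1] == 0:
        raise ValueError("no non-constant genes left for PCA")
    X = X - X.mean(axis=0)
    if zscore:
        X = X / sd
    u, s, vt = np.linalg.svd(X, full_matrices=False)
    for i in range(s.size):  # sign convention: largest |loading| positive
        j = int(np.argmax(np.abs(vt[i])))
        if vt[i, j] < 0:
            vt[i] *= -1
            u[:, i] *= -1
    k = min(k, s.size)
    cols = [f"PC{i + 1}" for i in range(k)]
    scores = pd.DataFrame(u[:, :k] * s[:k], index=expression.index, columns=cols)
    loadings = pd.DataFrame(vt[:k].T, index=expression.columns, columns=cols)
    total = float((s**2).sum())
    return PCAResult(
        scores=scores,
        variance_fraction=float((s[:k] ** 2).sum() / total) if total > 0 else 1.0,
        loadings=loadings,
        singular_values=tuple(float(x) for x in s),
    )


def kmeans2(scores: pd.DataFrame, seed: int = 0, n_restarts: int = 50) -> pd.Series:
    """Two-cluster k-means (Lloyd, Euclidean, seeded random restarts).

    Labels are canonicalized so that cluster 1 is the cluster containing the
    lexicographically smallest sample id.
    """
    X = scores.to_numpy(dtype=float)
    if np.all(X == X[0]):
        raise ValueError("all points identical; two clusters are undefined")
    km = KMeans(
        n_clusters=2,
        n_init=n_restarts,
        init="random",
        algorithm="lloyd",
        random_state=derived_int_seed(seed, STREAM_KMEANS),
    )
    raw = km.fit_predict(X)
    first = min(range(len(scores.index)), key=lambda i: str(scores.index[i]))
    labels = np.where(raw == raw[first], 1, 2)
    return pd.Series(labels, index=scores.index, name="cluster")


def _check_clusters(table: pd.DataFrame) -> None:
    if "cluster" not in table.columns:
        raise ValueError("survival table needs a 'cluster' column")
    present = sorted(table["cluster"].unique())
    if len(present) < 2:
        raise ValueError(f"both clusters must be non-empty, found {present}")


def kaplan_meier(table: pd.DataFrame) -> dict[int, pd.DataFrame]:
    """Product-limit survival estimate per cluster.

    Returns, per cluster, a step table with columns ``time, n_at_risk,
    n_events, n_censored, survival``; S(0) = 1 and the estimate is
    right-continuous and non-increasing.
    """
    _check_clusters(table)
    curves: dict[int, pd.DataFrame] = {}
    for cluster, grp in table.groupby("cluster"):
        times = grp["time"].to_numpy(dtype=float)
        events = grp["event"].to_numpy(dtype=int)
        order = np.argsort(times, kind="mergesort")
        times, events = times[order], events[order]
        rows = []
        surv = 1.0
        n_at_risk = times.size
        for t in np.unique(times):
            at_t = times == t
            d = int(events[at_t].sum())
            c = int(at_t.sum() - d)
            if d > 0:
                surv *= 1.0 - d / n_at_risk
            rows.append((float(t), int(n_at_risk), d, c, surv))
            n_at_risk -= int(at_t.sum())
        curves[int(cluster)] = pd.DataFrame(
            rows, columns=["time", "n_at_risk", "n_events", "n_censored", "survival"]
        )
    return curves


def _logrank_terms(table: pd.DataFrame) -> tuple[float, float]:
    """(sum of O1 - E1, sum of hypergeometric variances) over event times."""
    clusters = sorted(table["cluster"].unique())
    g1 = clusters[0]
    times = table["time"].to_numpy(dtype=float)
    events = table["event"].to_numpy(dtype=int)
    in_g1 = (table["cluster"] == g1).to_numpy()
    o_minus_e = 0.0
    var = 0.0
    for t in np.unique(times[events == 1]):
        at_risk = times >= t
        n = int(at_risk.sum())
        n1 = int((at_risk & in_g1).sum())
        d = int(((times == t) & (events == 1)).sum())
        d1 = int(((times == t) & (events == 1) & in_g1).sum())
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o_minus_e, var


def logrank_test(table: pd.DataFrame) -> LogrankResult:
    """Standard two-group log-rank test; chi-square with 1 df."""
    _check_clusters(table)
    o_minus_e, var = _logrank_terms(table)
    if var == 0:
        warnings.warn("no events (or no variance) in the log-rank table; p = 1")
        return LogrankResult(chi2=0.0, p=1.0)
    chi2 = o_minus_e**2 / var
    return LogrankResult(chi2=float(chi2), p=float(stats.chi2.sf(chi2, df=1)))


def cox_hr(table: pd.DataFrame) -> CoxResult:
    """Cox PH hazard ratio for cluster 2 vs cluster 1 (binary covariate).

    Breslow tie handling; Newton-Raphson on the partial likelihood to
    |delta beta| < 1e-8.  A monotone likelihood (all events in one group, or
    numerically diverging beta) raises an error advising exact or penalized
    methods.
    """
    _check_clusters(table)
    clusters = sorted(table["cluster"].unique())
    if len(clusters) != 2:
        raise ValueError(f"expected exactly 2 clusters, found {clusters}")
    x = (table["cluster"] == clusters[1]).to_numpy(dtype=float)
    times = table["time"].to_numpy(dtype=float)
    events = table["event"].to_numpy(dtype=int)
    for g, lbl in ((0.0, clusters[0]), (1.0, clusters[1])):
        if events[x == g].sum() < 1:
            raise ValueError(
                f"cluster {lbl} has no events; the partial likelihood is monotone "
                "- consider exact or penalized methods"
            )
    event_times = np.unique(times[events == 1])
    d_j = np.empty(event_times.size)
    s_j = np.empty(event_times.size)
    r1_j = np.empty(event_times.size)
    r0_j = np.empty(event_times.size)
    for j, t in enumerate(event_times):
        dying = (times == t) & (events == 1)
        at_risk = times >= t
        d_j[j] = dying.sum()
        s_j[j] = x[dying].sum()
        r1_j[j] = (at_risk & (x == 1)).sum()
        r0_j[j] = (at_risk & (x == 0)).sum()

    beta = 0.0
    for _ in range(MAX_NEWTON_ITER):
        eb = np.exp(beta)
        denom = r0_j + r1_j * eb
        mean_x = r1_j * eb / denom
        grad = float(s_j.sum() - (d_j * mean_x).sum())
        info = float((d_j * mean_x * (1 - mean_x)).sum())
        if info <= 0:
            raise ValueError(
                "Cox information is zero; the partial likelihood is degenerate"
            )
        step = grad / info
        beta += step
        if abs(beta) > 15:
            raise ValueError(
                "Cox estimate diverged (complete separation of events) "
                "- consider exact or penalized methods"
            )
        if abs(step) < NEWTON_TOL:
            break
    eb = np.exp(beta)
    denom = r0_j + r1_j * eb
    mean_x = r1_j * eb / denom
    se = float(1.0 / np.sqrt((d_j * mean_x * (1 - mean_x)).sum()))
    hr = float(np.exp(beta))
    return CoxResult(
        beta=float(beta),
        se=se,
        hazard_ratio=hr,
        ci95_low=float(np.exp(beta - _Z975 * se)),
        ci95_high=float(np.exp(beta + _Z975 * se)),
        p=float(2 * stats.norm.sf(abs(beta) / se)),
    )


def analyze_survival(table: pd.DataFrame) -> SurvivalResult:
    """Log-rank test plus Cox hazard ratio for a clustered survival table."""
    lr = logrank_test(table)
    cox = cox_hr(table)
    return SurvivalResult(
        logrank_chi2=lr.chi2,
        logrank_p=lr.p,
        hazard_ratio=cox.hazard_ratio,
        ci95_low=cox.ci95_low,
        ci95_high=cox.ci95_high,
        cox_p=cox.p,
    )
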