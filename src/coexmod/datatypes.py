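"""Shared domain types for the differential co-expression pipeline.

The unit of analysis is a two-state (diseased vs healthy) log2 expression
matrix.  Downstream stages exchange a small set of containers defined here:
expression datasets, co-expression networks (plain :class:`networkx.Graph`
objects tagged with a ``state``), gene modules, differential co-expression
reports, survival results and regulator maps.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

DISEASED = "diseased"
HEALTHY = "healthy"
STATES = (DISEASED, HEALTHY)


@dataclass
class ExpressionDataset:
    """A log2-scale gene x sample expression matrix with per-sample states.

    Parameters
    ----------
    dataset_id:
        Short label for the dataset (e.g. a study accession).
    values:
        DataFrame indexed by gene symbol (duplicates allowed until
        :func:`coexmod.diffexpr.collapse_duplicate_genes` is applied),
        columns are unique sample ids, entries are finite log2 intensities.
    states:
        Series mapping each sample id to ``"diseased"`` or ``"healthy"``.
    """

    dataset_id: str
    values: pd.DataFrame
    states: pd.Series

    def __post_init__(self) -> None:
        if self.values.columns.duplicated().any():
            dupes = self.values.columns[self.values.columns.duplicated()].tolist()
            raise ValueError(f"duplicate sample ids in {self.dataset_id!r}: {dupes}")
        missing = [s for s in self.values.columns if s not in self.states.index]
        if missing:
            raise ValueError(
                f"no state for sample(s) {missing} in dataset {self.dataset_id!r}"
            )
        self.states = self.states.loc[self.values.columns]
        bad_states = sorted(set(self.states) - set(STATES))
        if bad_states:
            raise ValueError(f"unknown state label(s) {bad_states}; expected {STATES}")
        arr = self.values.to_numpy()
        if arr.size and not np.isfinite(arr).all():
            i, j = np.argwhere(~np.isfinite(arr))[0]
            raise ValueError(
                f"non-finite expression value at gene {self.values.index[i]!r}, "
                f"sample {self.values.columns[j]!r}"
            )

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def samples_of_state(self, state: str) -> list[str]:
        return [s for s in self.values.columns if self.states[s] == state]

    def state_matrix(self, state: str) -> pd.DataFrame:
        """Sub-matrix of the samples in one state (genes x samples)."""
        return self.values[self.samples_of_state(state)]

    def restrict_genes(self, genes: Iterable[str]) -> "ExpressionDataset":
        keep = [g for g in self.values.index if g in set(genes)]
        return ExpressionDataset(self.dataset_id, self.values.loc[keep], self.states)

    def copy_with(self, values: pd.DataFrame) -> "ExpressionDataset":
        return ExpressionDataset(self.dataset_id, values, self.states)


@dataclass(frozen=True)
class ModeratedVariancePrior:
    """Empirical-Bayes variance prior: ``s_g^2 ~ s0_sq * chi2_d0 / d0``.

    ``d0`` may be ``math.inf`` when gene-wise variances are homogeneous, in
    which case every gene shares the prior variance exactly.
    """

    d0: float
    s0_sq: float

    def __post_init__(self) -> None:
        if not (self.d0 > 0):
            raise ValueError("prior df d0 must be > 0")
        if not (self.s0_sq > 0):
            raise ValueError("prior variance s0_sq must be > 0")


@dataclass(frozen=True)
class GeneModule:
    """A densely interconnected gene set found in a co-expression network."""

    genes: tuple[str, ...]
    n_nodes: int
    n_edges: int
    density: float
    avg_connectivity: float  # edges per gene, the module ranking score
    mcode_score: float  # classical MCODE score: core density x size
    rank: int = 0

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["genes"] = list(self.genes)
        return d


@dataclass(frozen=True)
class TopologySummary:
    state: str
    n_nodes: int
    n_edges: int
    density: float
    avg_clustering: float
    degree_sequence: tuple[int, ...]
    scale_free_r2: float | None

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["degree_sequence"] = list(self.degree_sequence)
        return d


@dataclass(frozen=True)
class HubSet:
    """Dual-metric hubs: union of top-k genes by degree and by betweenness."""

    hubs: tuple[str, ...]
    degree: Mapping[str, int]
    betweenness: Mapping[str, float]


@dataclass
class DifferentialCoexpressionReport:
    """Paired topology of one module in the two states, plus permutation p."""

    module_genes: tuple[str, ...]
    n_edges_diseased: int
    n_edges_healthy: int
    density_diseased: float
    density_healthy: float
    cc_diseased: float
    cc_healthy: float
    n_connected_healthy: int
    p_value: float | None = None
    is_differential: bool | None = None

    @property
    def density_delta(self) -> float:
        return self.density_diseased - self.density_healthy

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["module_genes"] = list(self.module_genes)
        d["density_delta"] = self.density_delta
        return d


@dataclass(frozen=True)
class PCAResult:
    scores: pd.DataFrame  # samples x PC1..PCk
    variance_fraction: float
    loadings: pd.DataFrame  # genes x PC1..PCk
    singular_values: tuple[float, ...]


@dataclass(frozen=True)
class LogrankResult:
    chi2: float
    p: float


@dataclass(frozen=True)
class CoxResult:
    beta: float
    se: float
    hazard_ratio: float
    ci95_low: float
    ci95_high: float
    p: float


@dataclass(frozen=True)
class SurvivalResult:
    logrank_chi2: float
    logrank_p: float
    hazard_ratio: float
    ci95_low: float
    ci95_high: float
    cox_p: float

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


TF = "TF"
MIRNA = "miRNA"
REGULATOR_TYPES = (TF, MIRNA)


@dataclass(frozen=True)
class RegulatorEntry:
    regulator: str
    type: str
    targets: frozenset[str]

    def __post_init__(self) -> None:
        if self.type not in REGULATOR_TYPES:
            raise ValueError(
                f"unknown regulator type {self.type!r} for {self.regulator!r}; "
                f"expected one of {REGULATOR_TYPES}"
            )
        if not self.targets:
            raise ValueError(f"regulator {self.regulator!r} has an empty target set")


@dataclass
class RegulatorMap:
    """Regulator -> (type, de-duplicated target gene set)."""

    entries: dict[str, RegulatorEntry] = field(default_factory=dict)

    def add(self, regulator: str, type: str, targets: Iterable[str]) -> None:
        targets = frozenset(targets)
        if regulator in self.entries:
            prev = self.entries[regulator]
            if prev.type != type:
                raise ValueError(
                    f"regulator {regulator!r} listed with conflicting types "
                    f"{prev.type!r} and {type!r}"
                )
            targets = prev.targets | targets
        self.entries[regulator] = RegulatorEntry(regulator, type, targets)

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, regulator: str) -> bool:
        return regulator in self.entries

    def targets_of(self, regulator: str) -> frozenset[str]:
        return self.entries[regulator].targets

    def of_type(self, type: str) -> dict[str, frozenset[str]]:
        return {
            r: e.targets for r, e in sorted(self.entries.items()) if e.type == type
        }

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RegulatorMap):
            return NotImplemented
        return self.entries == other.entries


@dataclass(frozen=True)
class GroundTruth:
    """Planted structure of a synthetic two-state study, for recovery tests."""

    module_genes: frozenset[str]
    deg_directions: Mapping[str, str]  # gene -> 'up' | 'down'
    cluster_labels: Mapping[str, int]  # diseased sample -> 1 | 2
    factor_scores: Mapping[str, float]  # diseased sample -> latent factor z

    @property
    def deg_genes(self) -> frozenset[str]:
        return frozenset(self.deg_directions)


def as_state_graph(state: str) -> nx.Graph:
    """Empty co-expression network tagged with its state."""
    g = nx.Graph()
    g.graph["state"] = state
    return g
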