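"""Pipeline configuration and deterministic random-stream derivation.

All randomized stages draw from substreams derived from one top-level seed,
so a full pipeline run is reproducible bit-for-bit from ``(config, seed)``.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

# Fixed substream labels; changing these changes every downstream stream.
STREAM_SIMULATE = 1
STREAM_SURVIVAL = 2
STREAM_REGULATORS = 3
STREAM_PERMUTATION = 4
STREAM_KMEANS = 5


def substream(seed: int, *key: int) -> np.random.Generator:
    """Independent generator for stage ``key`` of the run seeded by ``seed``."""
    return np.random.default_rng(np.random.SeedSequence((int(seed), *map(int, key))))


def derived_int_seed(seed: int, *key: int) -> int:
    """A 31-bit integer seed for libraries that take plain ints."""
    ss = np.random.SeedSequence((int(seed), *map(int, key)))
    return int(ss.generate_state(1)[0] % (2**31 - 1))


@dataclass
class MCODEParams:
    """Published MCODE defaults; the source study does not report its settings."""

    degree_cutoff: int = 2
    node_score_cutoff: float = 0.2
    k_core: int = 2
    haircut: bool = True
    fluff: bool = False
    fluff_density_cutoff: float = 0.2
    max_depth: int = 100

    def __post_init__(self) -> None:
        if not (0 <= self.node_score_cutoff < 1):
            raise ValueError("node_score_cutoff must be in [0, 1)")
        if self.k_core < 2:
            raise ValueError("k_core must be >= 2")
        if self.degree_cutoff < 0 or self.max_depth < 1:
            raise ValueError("degree_cutoff must be >= 0 and max_depth >= 1")


@dataclass
class PipelineConfig:
    """Thresholds and sizes for every stage of the pipeline.

    Defaults are the source study's stated settings: adjusted-p < 0.01 with
    fold change > 2 or < 0.5 for differential expression; a two-sided
    alpha = 0.05 cutoff on the empirical PCC distribution for network edges;
    module selection at >= 10 nodes, average connectivity >= 10 and density
    >= 0.80.
    """

    deg_alpha: float = 0.01
    fc_up: float = 2.0
    fc_down: float = 0.5
    corr_alpha: float = 0.05
    symmetric_cutoff: bool = True
    mcode: MCODEParams = field(default_factory=MCODEParams)
    min_nodes: int = 10
    min_avg_conn: float = 10.0
    min_density: float = 0.80
    density_delta_min: float = 0.5
    perm_p_max: float = 0.05
    n_permutations: int = 199
    pca_components: int = 3
    zscore_pca: bool = True
    kmeans_restarts: int = 50
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("deg_alpha", "corr_alpha", "perm_p_max"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        if not (self.fc_up > 1 > self.fc_down > 0):
            raise ValueError("fold-change cutoffs must satisfy fc_up > 1 > fc_down > 0")
        if self.n_permutations < 99:
            raise ValueError("n_permutations must be >= 99")
        if isinstance(self.mcode, dict):
            self.mcode = MCODEParams(**self.mcode)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(**d)

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")
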