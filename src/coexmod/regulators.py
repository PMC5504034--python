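"""Regulator-overlap analysis, cross-condition screening and enrichment.

Covers the downstream characterization of a selected module: how many TFs
and miRNAs target each module gene, which few regulators cover most of the
module, Venn-style co-regulation counts, the fraction of the module
differentially expressed in other conditions, genes recurrently DE across
conditions, chromosome tabulation, and hypergeometric gene-set enrichment
(the one-sided Fisher exact test on a 2x2 table equals the hypergeometric
upper tail, so the hypergeometric form is the single code path).
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import MIRNA, TF, RegulatorMap
from .diffexpr import bh_adjust


def count_regulators_per_gene(
    rmap: RegulatorMap, module_genes: Iterable[str]
) -> pd.DataFrame:
    """Per-module-gene TF and miRNA counts (0 for unregulated genes)."""
    genes = sorted(set(module_genes))
    tf_sets = rmap.of_type(TF)
    mir_sets = rmap.of_type(MIRNA)
    rows = [
        (
            g,
            sum(1 for targets in tf_sets.values() if g in targets),
            sum(1 for targets in mir_sets.values() if g in targets),
        )
        for g in genes
    ]
    return pd.DataFrame(rows, columns=["gene", "n_tf", "n_mirna"])


@dataclass(frozen=True)
class RankedRegulators:
    """Top regulators by module-target count plus their joint coverage."""

    table: pd.DataFrame  # regulator, type, n_module_targets
    coverage: float  # |(union of top-k target sets) & module| / |module|


def top_regulators(
    rmap: RegulatorMap,
    module_genes: Iterable[str],
    k: int,
    type: str | None = None,
) -> RankedRegulators:
    """Regulators ranked by module-target count (ties lexicographic).

    ``coverage`` is the fraction of module genes hit by the union of the
    top-k regulators' target sets.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    module = set(module_genes)
    if not module:
        raise ValueError("module gene set is empty")
    entries = [
        (r, e.type, e.targets & module)
        for r, e in rmap.entries.items()
        if type is None or e.type == type
    ]
    entries.sort(key=lambda item: (-len(item[2]), item[0]))
    table = pd.DataFrame(
        [(r, t, len(hit)) for r, t, hit in entries],
        columns=["regulator", "type", "n_module_targets"],
    )
    union: set[str] = set()
    for _, _, hit in entries[:k]:
        union |= hit
    return RankedRegulators(table=table, coverage=len(union) / len(module))


def mutual_targets(
    rmap: RegulatorMap, regulators: Sequence[str]
) -> dict[frozenset[str], int]:
    """Exclusive Venn region counts over 2-4 regulators' target sets.

    Keys are the non-empty regulator subsets; values count the genes hit by
    exactly that subset.  The counts sum to the union cardinality.
    """
    if not (2 <= len(regulators) <= 4):
        raise ValueError("mutual_targets needs between 2 and 4 regulators")
    missing = [r for r in regulators if r not in rmap]
    if missing:
        raise ValueError(f"regulator(s) absent from the map: {missing}")
    target_sets = {r: rmap.targets_of(r) for r in regulators}
    universe = set().union(*target_sets.values())
    regions: dict[frozenset[str], int] = {}
    for size in range(1, len(regulators) + 1):
        for combo in itertools.combinations(regulators, size):
            regions[frozenset(combo)] = 0
    for gene in universe:
        members = frozenset(r for r in regulators if gene in target_sets[r])
        regions[members] += 1
    return regions


@dataclass(frozen=True)
class CoverageRow:
    """Module coverage by one condition's DEG set."""

    condition: str
    n_module_de: int
    coverage: float  # fraction of the FULL module

    @property
    def pct(self) -> int:
        return int(round(100 * self.coverage))


def module_coverage(
    deg_genes: Iterable[str], module_genes: Iterable[str], condition: str
) -> CoverageRow:
    """Fraction of module genes differentially expressed in a condition.

    The denominator is always the full module size.
    """
    module = set(module_genes)
    if not module:
        raise ValueError("module gene set is empty")
    n_de = len(module & set(deg_genes))
    return CoverageRow(condition=condition, n_module_de=n_de, coverage=n_de / len(module))


def _condition_rows(condition: str, table: pd.DataFrame) -> pd.DataFrame:
    """Normalize a per-condition DEG table to (gene, direction, fc-magnitude).

    Accepts either a DEG table with ``log2fc`` (direction from its sign,
    linear fold-change magnitude ``2**|log2fc|``) or a pre-formed table with
    ``direction`` and linear ``fc`` columns.
    """
    if "log2fc" in table.columns:
        if "direction" in table.columns:
            table = table.loc[table["direction"] != "ns"]
        direction = np.where(table["log2fc"] > 0, "up", "down")
        fc = 2.0 ** table["log2fc"].abs()
    elif {"direction", "fc"}.issubset(table.columns):
        direction = table["direction"].to_numpy()
        fc = pd.to_numeric(table["fc"])
        if (fc <= 0).any():
            raise ValueError(f"fold changes must be positive in condition {condition!r}")
        fc = np.where(fc < 1, 1 / fc, fc)  # report magnitudes, like the direction flag
    else:
        raise ValueError(
            f"condition {condition!r}: need a 'log2fc' or 'direction'+'fc' table"
        )
    return pd.DataFrame(
        {
            "gene": table["gene"].to_numpy(),
            "condition": condition,
            "direction": direction,
            "fc": np.round(np.asarray(fc, dtype=float), 2),
        }
    )


def mutual_de_genes(
    deg_tables: Mapping[str, pd.DataFrame],
    module_genes: Iterable[str],
    min_conditions: int = 3,
) -> pd.DataFrame:
    """Module genes differentially expressed in >= ``min_conditions`` conditions.

    Returns one row per (gene, condition) with the condition's own direction
    and linear fold-change magnitude, sorted by gene then condition.  No
    cross-condition direction consistency is enforced.
    """
    if len(deg_tables) < 3:
        raise ValueError("need >= 3 conditions to screen for recurrent DE genes")
    module = set(module_genes)
    rows = [
        _condition_rows(cond, tbl) for cond, tbl in sorted(deg_tables.items())
    ]
    long = pd.concat(rows, ignore_index=True)
    long = long.loc[long["gene"].isin(module)]
    counts = long.groupby("gene")["condition"].nunique()
    keep = counts.index[counts >= min_conditions]
    out = long.loc[long["gene"].isin(keep)]
    return out.sort_values(["gene", "condition"]).reset_index(drop=True)


def chromosome_distribution(
    annotation: Mapping[str, str], module_genes: Iterable[str]
) -> tuple[pd.Series, list[str]]:
    """Counts of module genes per chromosome, plus unannotated genes.

    Counts sum to the number of annotated module genes.
    """
    genes = sorted(set(module_genes))
    annotated = {g: str(annotation[g]) for g in genes if g in annotation}
    if not annotated:
        raise ValueError("annotation covers no module gene")
    unannotated = [g for g in genes if g not in annotation]
    counts = pd.Series(annotated).value_counts().sort_index()
    counts.name = "n_genes"
    return counts, unannotated


def hypergeometric_enrichment(
    query: Iterable[str],
    gene_sets: Sequence[tuple[str, str, Sequence[str]]],
    universe: Iterable[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation of the query in each set.

    ``p = P(X >= overlap)`` with population size ``|universe|``, successes
    ``|set & universe|`` and draws ``|query|``; BH adjustment across sets
    and a significance flag at adjusted p < ``alpha``.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("the gene universe is empty")
    query = set(query)
    stray = query - universe
    if stray:
        raise ValueError(f"query gene(s) outside the universe: {sorted(stray)[:5]}")
    n_universe, n_query = len(universe), len(query)
    rows = []
    for name, _desc, members in gene_sets:
        in_universe = set(members) & universe
        overlap = len(in_universe & query)
        p = float(stats.hypergeom.sf(overlap - 1, n_universe, len(in_universe), n_query))
        rows.append((name, len(in_universe), overlap, min(p, 1.0)))
    table = pd.DataFrame(rows, columns=["set", "set_size", "overlap", "p"])
    table["p_adj"] = bh_adjust(table["p"].to_numpy()) if len(table) else []
    table["significant"] = table["p_adj"] < alpha
    return table
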