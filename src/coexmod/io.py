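"""Readers and writers for the pipeline's plain-text formats.

All tables are tab-separated text.  Writers accept a ``meta`` mapping that is
emitted as ``# key=value`` header lines (the run seed is recorded this way in
every output); readers skip ``#`` comment lines.  Every reader/writer pair is
an identity on valid data at the stated numeric precision.
"""
from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .datatypes import ExpressionDataset, RegulatorMap, as_state_graph

PCC_DECIMALS = 3  # correlations and densities printed to 3 decimals
CONNECTIVITY_DECIMALS = 1


def _meta_lines(meta: Mapping | None) -> str:
    if not meta:
        return ""
    return "".join(f"# {k}={v}\n" for k, v in meta.items())


def _read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    path = Path(path)
    if not path.exists() or path.stat().st_size == 0:
        raise ValueError(f"empty or missing file: {path}")
    df = pd.read_csv(path, sep="\t", comment="#", **kwargs)
    if df.empty and df.columns.empty:
        raise ValueError(f"empty file: {path}")
    return df


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------

def read_state_map(path: str | Path) -> pd.Series:
    """Read a two-column ``sample\\tstate`` table into a Series."""
    df = _read_tsv(path, dtype=str)
    if not {"sample", "state"}.issubset(df.columns):
        raise ValueError(f"state map {path} must have columns 'sample' and 'state'")
    if df["sample"].duplicated().any():
        dupes = df.loc[df["sample"].duplicated(), "sample"].tolist()
        raise ValueError(f"duplicate sample(s) in state map: {dupes}")
    return pd.Series(df["state"].to_numpy(), index=df["sample"].to_numpy(), name="state")


def read_expression_matrix(
    path: str | Path,
    state_map: Mapping[str, str] | pd.Series,
    dataset_id: str | None = None,
) -> ExpressionDataset:
    """Read a gene x sample log2 expression TSV (first column = gene symbol).

    Duplicate gene rows are retained; they are collapsed later by
    :func:`coexmod.diffexpr.collapse_duplicate_genes`.
    """
    df = _read_tsv(path)
    gene_col = df.columns[0]
    genes = df[gene_col].astype(str)
    values = df.drop(columns=[gene_col])
    if values.shape[1] == 0:
        raise ValueError(f"expression file {path} has no sample columns")
    if not isinstance(state_map, pd.Series):
        state_map = pd.Series(dict(state_map))
    missing = [s for s in values.columns if s not in state_map.index]
    if missing:
        raise ValueError(f"sample(s) {missing} missing from the state map")
    for col in values.columns:
        numeric = pd.to_numeric(values[col], errors="coerce")
        bad = numeric.isna() & values[col].notna()
        if bad.any() or values[col].isna().any():
            row = genes[(bad | values[col].isna())].iloc[0]
            raise ValueError(
                f"non-numeric expression value at gene {row!r}, sample {col!r} in {path}"
            )
        values[col] = numeric
    values.index = pd.Index(genes, name="gene")
    if dataset_id is None:
        dataset_id = Path(path).stem
    return ExpressionDataset(dataset_id, values, state_map.loc[values.columns])


def write_expression_matrix(
    dataset: ExpressionDataset, path: str | Path, meta: Mapping | None = None
) -> None:
    with open(path, "w") as fh:
        fh.write(_meta_lines(meta))
        dataset.values.to_csv(fh, sep="\t", index_label="gene", lineterminator="\n")


def write_state_map(states: pd.Series, path: str | Path, meta: Mapping | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(_meta_lines(meta))
        fh.write("sample\tstate\n")
        for sample, state in states.items():
            fh.write(f"{sample}\t{state}\n")


# ---------------------------------------------------------------------------
# survival tables
# ---------------------------------------------------------------------------

def read_survival_table(path: str | Path) -> pd.DataFrame:
    """Read ``sample, time, event[, cluster]`` survival records.

    Times are months and must be >= 0; event is 0 (censored) or 1 (death).
    """
    df = _read_tsv(path)
    required = {"sample", "time", "event"}
    if not required.issubset(df.columns):
        raise ValueError(f"survival table {path} must have columns {sorted(required)}")
    if df["sample"].duplicated().any():
        dupes = df.loc[df["sample"].duplicated(), "sample"].tolist()
        raise ValueError(f"duplicate sample(s) in survival table: {dupes}")
    df["time"] = pd.to_numeric(df["time"])
    df["event"] = pd.to_numeric(df["event"])
    if (df["time"] < 0).any():
        bad = df.loc[df["time"] < 0, "sample"].tolist()
        raise ValueError(f"negative survival time for sample(s) {bad}")
    if not df["event"].isin([0, 1]).all():
        bad = df.loc[~df["event"].isin([0, 1]), "sample"].tolist()
        raise ValueError(f"event indicator not in {{0,1}} for sample(s) {bad}")
    df["event"] = df["event"].astype(int)
    if "cluster" in df.columns:
        df["cluster"] = pd.to_numeric(df["cluster"]).astype(int)
    return df.reset_index(drop=True)


def write_survival_table(
    table: pd.DataFrame, path: str | Path, meta: Mapping | None = None
) -> None:
    with open(path, "w") as fh:
        fh.write(_meta_lines(meta))
        table.to_csv(fh, sep="\t", index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# regulator tables
# ---------------------------------------------------------------------------

def read_regulator_table(path: str | Path) -> RegulatorMap:
    """Read ``regulator, type, target`` rows into a RegulatorMap.

    Duplicated (regulator, target) rows collapse to one target; an unknown
    type token is a hard error.
    """
    df = _read_tsv(path, dtype=str)
    required = {"regulator", "type", "target"}
    if not required.issubset(df.columns):
        raise ValueError(f"regulator table {path} must have columns {sorted(required)}")
    rmap = RegulatorMap()
    for regulator, group in df.groupby("regulator", sort=True):
        types = group["type"].unique()
        if len(types) > 1:
            raise ValueError(
                f"regulator {regulator!r} listed with conflicting types {types.tolist()}"
            )
        rmap.add(str(regulator), str(types[0]), group["target"].astype(str))
    return rmap


def write_regulator_table(
    rmap: RegulatorMap, path: str | Path, meta: Mapping | None = None
) -> None:
    with open(path, "w") as fh:
        fh.write(_meta_lines(meta))
        fh.write("regulator\ttype\ttarget\n")
        for regulator in sorted(rmap.entries):
            entry = rmap.entries[regulator]
            for target in sorted(entry.targets):
                fh.write(f"{regulator}\t{entry.type}\t{target}\n")


# ---------------------------------------------------------------------------
# gene sets (GMT) and gene lists
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> list[tuple[str, str, list[str]]]:
    """Read a GMT gene-set collection: ``name, description, members...``.

    Repeated members within a set are de-duplicated (first occurrence kept).
    """
    sets: list[tuple[str, str, list[str]]] = []
    path = Path(path)
    if not path.exists() or path.stat().st_size == 0:
        raise ValueError(f"empty or missing GMT file: {path}")
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"GMT line {lineno} in {path} has {len(fields)} field(s); "
                    "need name, description and at least one member"
                )
            name, desc, *members = fields
            members = [m for m in members if m]
            deduped = list(dict.fromkeys(members))
            if not deduped:
                raise ValueError(f"GMT line {lineno} in {path} has an empty gene set")
            sets.append((name, desc, deduped))
    if not sets:
        raise ValueError(f"GMT file {path} contains no gene sets")
    return sets


def write_gmt(sets: Sequence[tuple[str, str, Sequence[str]]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, desc, members in sets:
            fh.write("\t".join([name, desc, *members]) + "\n")


def read_gene_list(path: str | Path) -> list[str]:
    genes: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                genes.append(line.split("\t")[0])
    if not genes:
        raise ValueError(f"gene list {path} is empty")
    return genes


def write_gene_list(genes: Iterable[str], path: str | Path, meta: Mapping | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(_meta_lines(meta))
        for g in genes:
            fh.write(f"{g}\n")


# ---------------------------------------------------------------------------
# networks
# ---------------------------------------------------------------------------

def write_edge_list(
    network: nx.Graph, path: str | Path, meta: Mapping | None = None
) -> None:
    """Write an undirected network as ``geneA, geneB, pcc, sign`` rows.

    Each edge appears once with geneA < geneB lexicographically; rows are
    sorted, and correlations are printed to 3 decimals.
    """
    rows = []
    for u, v, data in network.edges(data=True):
        a, b = sorted((str(u), str(v)))
        pcc = float(data.get("pcc", np.nan))
        sign = data.get("sign", "+" if pcc >= 0 else "-")
        rows.append((a, b, pcc, sign))
    rows.sort(key=lambda r: (r[0], r[1]))
    with open(path, "w") as fh:
        fh.write(_meta_lines(meta))
        fh.write("geneA\tgeneB\tpcc\tsign\n")
        for a, b, pcc, sign in rows:
            fh.write(f"{a}\t{b}\t{pcc:.{PCC_DECIMALS}f}\t{sign}\n")


def read_edge_list(path: str | Path, state: str | None = None) -> nx.Graph:
    df = _read_tsv(path)
    required = {"geneA", "geneB", "pcc", "sign"}
    if not required.issubset(df.columns):
        raise ValueError(f"edge list {path} must have columns {sorted(required)}")
    g = as_state_graph(state or "unknown")
    for _, row in df.iterrows():
        g.add_edge(str(row["geneA"]), str(row["geneB"]), pcc=float(row["pcc"]),
                   sign=str(row["sign"]))
    return g


# ---------------------------------------------------------------------------
# JSON run reports
# ---------------------------------------------------------------------------

def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    if hasattr(obj, "as_dict"):
        return obj.as_dict()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def write_json_report(
    results: Mapping, path: str | Path, config: Mapping | None = None,
    seed: int | None = None,
) -> None:
    """Write a run report carrying the config, the seed and summary results."""
    payload = {"config": config, "seed": seed, "results": dict(results)}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=_jsonable)
        fh.write("\n")


def read_json_report(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)
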