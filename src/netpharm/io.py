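"""Readers/writers for the on-disk formats: TSV tables, SIF, GraphML, manifests.

TSV is the canonical dialect (tab-delimited, UTF-8, ``#`` comment lines
ignored). Networks are written as SIF (relations ``pp`` and ``dt``) and
GraphML with all node/edge attributes, both importable by Cytoscape, plus a
flat node-attribute table. Writers are deterministic: same network, same
bytes.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import networkx as nx
import pandas as pd

from .netbuild import DRUG, DRUG_TARGET, PPI, PROTEIN

logger = logging.getLogger("netpharm.io")


class SchemaError(ValueError):
    """A table does not match its declared schema."""


@dataclass(frozen=True)
class TableSchema:
    name: str
    columns: tuple[str, ...]
    key: tuple[str, ...] | None = None  # dedup key; None = keep all rows


SCHEMAS = {
    "annotation": TableSchema("annotation", ("sample_id", "group"), key=("sample_id",)),
    "probe_map": TableSchema("probe_map", ("probe_id", "gene_symbol"),
                             key=("probe_id", "gene_symbol")),
    "orthologs": TableSchema("orthologs", ("mouse_symbol", "human_symbol"),
                             key=("mouse_symbol", "human_symbol")),
    "ppi": TableSchema("ppi", ("protein_a", "protein_b")),
    "drugs": TableSchema("drugs", ("drug_id", "drug_name", "target_symbol"),
                         key=("drug_id", "target_symbol")),
}


def read_table(path: str | Path, schema: str | TableSchema) -> pd.DataFrame:
    """Read and validate a TSV table against a named schema.

    Missing columns raise :class:`SchemaError` naming the column; duplicate
    key rows and rows with empty required fields are dropped with warnings.
    """
    if isinstance(schema, str):
        schema = SCHEMAS[schema]
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input table not found: {path}")
    table = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    for col in schema.columns:
        if col not in table.columns:
            raise SchemaError(f"{schema.name} table {path}: missing column '{col}'")
    table = table[list(schema.columns)]
    empty = table.isna().any(axis=1) | (table == "").any(axis=1)
    if empty.any():
        logger.warning("read_table[%s]: dropping %d row(s) with empty fields",
                       schema.name, int(empty.sum()))
        table = table[~empty]
    if schema.key:
        dup = table.duplicated(list(schema.key))
        if dup.any():
            logger.warning("read_table[%s]: deduplicated %d row(s) on key %s",
                           schema.name, int(dup.sum()), schema.key)
            table = table[~dup]
    return table.reset_index(drop=True)


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Probe x sample matrix: first column probe ids, header row sample ids."""
    matrix = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    if matrix.index.has_duplicates:
        raise SchemaError(f"expression matrix {path}: duplicate probe ids")
    if matrix.columns.has_duplicates:
        raise SchemaError(f"expression matrix {path}: duplicate sample ids")
    return matrix.astype(float)


def read_gene_list(path: str | Path) -> list[str]:
    lines = Path(path).read_text().splitlines()
    return [ln.strip() for ln in lines if ln.strip() and not ln.startswith("#")]


def write_gene_list(genes: Iterable[str], path: str | Path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in sorted(genes)))


# --- network formats -------------------------------------------------------

_SIF_REL = {PPI: "pp", DRUG_TARGET: "dt"}
_REL_TYPE = {v: k for k, v in _SIF_REL.items()}


def write_sif(graph: nx.Graph, path: str | Path) -> None:
    """SIF export: one ``source relation target`` line per edge, drugs first on dt."""
    lines = []
    for u, v, data in graph.edges(data=True):
        rel = _SIF_REL[data.get("edge_type", PPI)]
        if rel == "dt" and not u.startswith("D:"):
            u, v = v, u
        elif rel == "pp":
            u, v = sorted((u, v))
        lines.append(f"{u}\t{rel}\t{v}")
    Path(path).write_text("".join(f"{ln}\n" for ln in sorted(lines)))


def read_sif(path: str | Path) -> nx.Graph:
    """Rebuild a network from SIF (topology and types only, no attributes)."""
    graph = nx.Graph()
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        u, rel, v = line.split("\t")
        if rel not in _REL_TYPE:
            raise SchemaError(f"unknown SIF relation {rel!r} in {path}")
        for node in (u, v):
            graph.add_node(node, node_type=DRUG if node.startswith("D:") else PROTEIN)
        graph.add_edge(u, v, edge_type=_REL_TYPE[rel])
    return graph


def write_graphml(graph: nx.Graph, path: str | Path) -> None:
    """GraphML with all node/edge attributes (NaN floats round-trip)."""
    clean = nx.Graph()
    clean.graph.update({k: _plain(v) for k, v in graph.graph.items()})
    for node in sorted(graph.nodes):
        clean.add_node(node, **{k: _plain(v) for k, v in graph.nodes[node].items()})
    for u, v in sorted(map(tuple, map(sorted, graph.edges))):
        clean.add_edge(u, v, **{k: _plain(val) for k, val in graph.edges[u, v].items()})
    nx.write_graphml(clean, str(path), infer_numeric_types=False)


def read_graphml(path: str | Path) -> nx.Graph:
    return nx.read_graphml(str(path), node_type=str)


def write_node_table(graph: nx.Graph, path: str | Path) -> None:
    """Flat per-node attribute TSV (Cytoscape-importable)."""
    keys: list[str] = []
    for _, data in graph.nodes(data=True):
        for k in data:
            if k not in keys:
                keys.append(k)
    rows = []
    for node in sorted(graph.nodes):
        data = graph.nodes[node]
        rows.append({"node_id": node, **{k: data.get(k, "") for k in keys}})
    pd.DataFrame(rows, columns=["node_id", *keys]).to_csv(
        path, sep="\t", index=False, float_format="%.6g", lineterminator="\n")


def graphs_equal(a: nx.Graph, b: nx.Graph) -> bool:
    """Structural + attribute equality, treating NaN as equal to NaN."""
    if set(a.nodes) != set(b.nodes):
        return False
    if {frozenset(e) for e in a.edges} != {frozenset(e) for e in b.edges}:
        return False
    for node in a.nodes:
        if not _attrs_equal(a.nodes[node], b.nodes[node]):
            return False
    for u, v in a.edges:
        if not _attrs_equal(a.edges[u, v], b.edges[u, v]):
            return False
    return True


def _attrs_equal(x: dict, y: dict) -> bool:
    if set(x) != set(y):
        return False
    for k in x:
        a, b = x[k], y[k]
        if isinstance(a, float) and isinstance(b, float):
            if not (a == b or (math.isnan(a) and math.isnan(b))):
                return False
        elif a != b:
            return False
    return True


def _plain(value):
    """Cast numpy scalars to plain python for GraphML serialization."""
    if hasattr(value, "item"):
        return value.item()
    return value


# --- manifest ---------------------------------------------------------------

def sha256_of(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_manifest(manifest: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")


def read_manifest(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
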