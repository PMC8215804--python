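"""Seed-anchored base PPI network construction and drug/expression annotation.

Node ids are namespaced -- ``P:<SYMBOL>`` for proteins, ``D:<drug_id>`` for
drugs -- so a drug name can never collide with a gene symbol. The base network
keeps exactly the protein-protein interactions that involve a seed gene;
drug-target edges are grafted on afterwards, and gene-level differential
expression (best-probe fold change, p, q and the called flag for each
comparison) is stored as node attributes.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

from .expression import GeneCallSet

logger = logging.getLogger("netpharm.netbuild")

PROTEIN = "protein"
DRUG = "drug"
PPI = "ppi"
DRUG_TARGET = "drug_target"

#: node-attribute fields written per comparison (``"<comparison>.<field>"``)
DE_FIELDS = ("lfc", "p", "q", "called", "measured")


def protein_id(symbol: str) -> str:
    return "P:" + symbol


def drug_id(drug: str) -> str:
    return "D:" + drug


def symbol_of(node: str) -> str:
    """Strip the namespace prefix from a node id."""
    return node.split(":", 1)[1]


def map_seeds(
    cis_mouse_symbols: Iterable[str], orthologs: pd.DataFrame
) -> tuple[set[str], list[str]]:
    """Map mouse CIS symbols to human seed symbols through an ortholog table.

    Returns the union of all human symbols reached from any input symbol
    (one-to-many rows keep every human ortholog) plus the sorted list of
    inputs with no ortholog row. Unmapped inputs are reported, not fatal.
    """
    symbols = list(cis_mouse_symbols)
    if orthologs.empty:
        logger.warning("map_seeds: empty ortholog table; all %d seed(s) unmapped", len(symbols))
        return set(), sorted(set(symbols))
    by_mouse = orthologs.groupby("mouse_symbol")["human_symbol"].agg(set)
    seeds: set[str] = set()
    unmapped: list[str] = []
    for sym in symbols:
        if sym in by_mouse.index:
            seeds |= by_mouse[sym]
        else:
            unmapped.append(sym)
    if unmapped:
        logger.warning("map_seeds: %d CIS symbol(s) without human ortholog: %s",
                       len(unmapped), ", ".join(sorted(set(unmapped))[:10]))
    return seeds, sorted(set(unmapped))


def build_base_network(
    seeds: set[str], ppi_edges: pd.DataFrame, include_neighbor_edges: bool = False
) -> nx.Graph:
    """Base network: every PPI edge with at least one seed endpoint.

    Symbols are upper-cased before matching. Self-loops and duplicate
    unordered pairs are removed with a warning. Seeds with no retrieved
    interaction are retained as isolated nodes (they still anchor the
    analysis and are reported). With ``include_neighbor_edges=True``, edges
    between two non-seed neighbours already in the network are also kept
    (permissive variant).
    """
    graph = nx.Graph()
    seeds = {s.upper() for s in seeds}
    if not seeds:
        logger.warning("build_base_network: empty seed set; returning empty network")
        return graph
    a = ppi_edges["protein_a"].astype(str).str.upper()
    b = ppi_edges["protein_b"].astype(str).str.upper()
    n_loops = int((a == b).sum())
    if n_loops:
        logger.warning("build_base_network: removed %d self-loop(s)", n_loops)
    pairs = {tuple(sorted(pair)) for pair in zip(a, b) if pair[0] != pair[1]}
    n_dupes = len(a) - n_loops - len(pairs)
    if n_dupes:
        logger.debug("build_base_network: collapsed %d duplicate edge(s)", n_dupes)

    for u, v in sorted(pairs):
        if u in seeds or v in seeds:
            for sym in (u, v):
                _ensure_protein(graph, sym, is_seed=sym in seeds)
            graph.add_edge(protein_id(u), protein_id(v), edge_type=PPI)
    isolated = sorted(s for s in seeds if protein_id(s) not in graph)
    for sym in seeds:
        _ensure_protein(graph, sym, is_seed=True)
    if isolated:
        logger.info("build_base_network: %d seed(s) with no retrieved interaction kept "
                    "as isolated nodes: %s", len(isolated), ", ".join(isolated[:10]))
    if include_neighbor_edges:
        present = {symbol_of(n) for n, d in graph.nodes(data=True) if d["node_type"] == PROTEIN}
        for u, v in sorted(pairs):
            if u in present and v in present:
                graph.add_edge(protein_id(u), protein_id(v), edge_type=PPI)
    return graph


def attach_drugs(graph: nx.Graph, drugs: pd.DataFrame) -> nx.Graph:
    """Graft drug-target edges onto the network (idempotent).

    For each (drug_id, drug_name, target_symbol) row whose target protein is
    already a node, the drug node is added once and linked by a
    ``drug_target`` edge; drugs with no target in the network are omitted.
    """
    for row in drugs.sort_values(["drug_id", "target_symbol"]).itertuples(index=False):
        target = protein_id(str(row.target_symbol).upper())
        if target not in graph:
            continue
        node = drug_id(row.drug_id)
        if node not in graph:
            graph.add_node(node, node_type=DRUG, name=str(row.drug_name), is_seed=False)
        graph.add_edge(node, target, edge_type=DRUG_TARGET)
    return graph


def annotate_de(graph: nx.Graph, call_sets: Mapping[str, GeneCallSet]) -> nx.Graph:
    """Attach per-comparison best-probe statistics to every protein node.

    Each protein node receives, for each comparison ``c``, flat attributes
    ``c.lfc``, ``c.p``, ``c.q`` (floats; NaN when the gene was not measured),
    ``c.called`` and ``c.measured`` (booleans). Drug nodes are never
    annotated. The comparison names are recorded on the graph itself.
    """
    comparisons = sorted(call_sets)
    graph.graph["comparisons"] = ";".join(comparisons)
    for node, data in graph.nodes(data=True):
        if data["node_type"] != PROTEIN:
            continue
        sym = symbol_of(node)
        for comp in comparisons:
            best = call_sets[comp].best
            if sym in best.index:
                row = best.loc[sym]
                data[f"{comp}.lfc"] = float(row["lfc"])
                data[f"{comp}.p"] = float(row["p"])
                data[f"{comp}.q"] = float(row["q"])
                data[f"{comp}.called"] = bool(row["called"])
                data[f"{comp}.measured"] = True
            else:
                data[f"{comp}.lfc"] = float("nan")
                data[f"{comp}.p"] = float("nan")
                data[f"{comp}.q"] = float("nan")
                data[f"{comp}.called"] = False
                data[f"{comp}.measured"] = False
    return graph


def comparisons_of(graph: nx.Graph) -> list[str]:
    raw = graph.graph.get("comparisons", "")
    return [c for c in raw.split(";") if c]


def connected_components(graph: nx.Graph) -> list[set[str]]:
    """Connected components, largest first (ties: lexicographic smallest member)."""
    comps = [set(c) for c in nx.connected_components(graph)]
    comps.sort(key=lambda c: (-len(c), min(c)))
    return comps


def _ensure_protein(graph: nx.Graph, symbol: str, is_seed: bool) -> None:
    node = protein_id(symbol)
    if node not in graph:
        graph.add_node(node, node_type=PROTEIN, name=symbol, is_seed=bool(is_seed))
    elif is_seed:
        graph.nodes[node]["is_seed"] = True
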