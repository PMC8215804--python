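"""Sub-network extraction, druggable-target reporting and bridging-node detection.

From the annotated drug-target network, each comparison's significantly
over-expressed protein nodes are expanded one step (direct protein
neighbours plus any drugs targeting them), giving a per-subgroup
sub-network; the refined *common* sub-network starts instead from the genes
over-expressed in every non-reference subgroup. Druggable over-expressed
proteins are reported with their adjacent seed (CIS) proteins, and those
with two or more distinct seed partners are flagged as bridging nodes --
points where otherwise separate seed neighbourhoods meet, and therefore
prioritized repurposing candidates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx

from .expression import GeneCallSet
from .netbuild import DRUG, DRUG_TARGET, PPI, PROTEIN, comparisons_of, protein_id, symbol_of

logger = logging.getLogger("netpharm.discovery")

#: node provenance labels within a sub-network
OVEREXPRESSED = "overexpressed"
NEIGHBOR = "neighbor"
DRUG_PROV = "drug"


@dataclass
class SubnetworkResult:
    """An extracted sub-network with per-node provenance."""

    name: str
    graph: nx.Graph
    provenance: dict[str, str] = field(default_factory=dict)


@dataclass(frozen=True)
class DruggableTarget:
    """One report row: an over-expressed druggable protein and its seed partners."""

    protein: str
    seed_partners: tuple[str, ...]
    drugs: tuple[tuple[str, str], ...]  # (drug_id, drug_name)
    called_in: tuple[tuple[str, bool], ...]
    degree: int


@dataclass(frozen=True)
class BridgingNode:
    """A druggable over-expressed protein adjacent to >= 2 distinct seeds."""

    protein: str
    seed_partners: tuple[str, ...]
    drugs: tuple[tuple[str, str], ...]


def select_upregulated(graph: nx.Graph, comparison: str, alpha: float | None = None) -> set[str]:
    """Protein nodes significantly over-expressed for a comparison.

    With ``alpha=None`` the stored gene-level ``called`` flag (any-probe rule)
    is used; with an explicit ``alpha`` the node's best-probe q is
    re-thresholded (``q < alpha`` and positive fold change), which makes the
    selection monotone in alpha. Drug nodes are never selected.
    """
    if comparison not in comparisons_of(graph):
        raise ValueError(f"unknown comparison {comparison!r}; "
                         f"annotated: {comparisons_of(graph)}")
    selected = set()
    for node, data in graph.nodes(data=True):
        if data["node_type"] != PROTEIN:
            continue
        if alpha is None:
            if data.get(f"{comparison}.called", False):
                selected.add(node)
        else:
            q = data.get(f"{comparison}.q", float("nan"))
            lfc = data.get(f"{comparison}.lfc", float("nan"))
            if data.get(f"{comparison}.measured", False) and q < alpha and lfc > 0:
                selected.add(node)
    return selected


def expand_one_step(graph: nx.Graph, nodeset: Iterable[str], induced: bool = True,
                    name: str = "") -> SubnetworkResult:
    """One-step neighbourhood expansion of an over-expressed node set.

    The expanded node set is the input plus all direct neighbours -- both
    neighbouring proteins and any drugs targeting the input proteins. With
    ``induced=True`` (default) all edges among the expanded set are kept;
    otherwise only edges incident to the input set (star semantics).
    """
    nodeset = set(nodeset)
    stray = [n for n in nodeset
             if n not in graph or graph.nodes[n]["node_type"] != PROTEIN]
    if stray:
        raise ValueError(f"expand_one_step: input nodes not protein nodes of the "
                         f"network: {sorted(stray)[:5]}")
    if not nodeset:
        logger.warning("expand_one_step[%s]: empty input node set; empty subnetwork", name)
        return SubnetworkResult(name=name, graph=nx.Graph(), provenance={})
    expanded = set(nodeset)
    for node in nodeset:
        expanded.update(graph.neighbors(node))
    if induced:
        sub = graph.subgraph(expanded).copy()
    else:
        sub = nx.Graph()
        sub.graph.update(graph.graph)
        for node in expanded:
            sub.add_node(node, **graph.nodes[node])
        for u, v, data in graph.edges(expanded, data=True):
            if u in nodeset or v in nodeset:
                sub.add_edge(u, v, **data)
    provenance = {}
    for node in sub.nodes:
        if node in nodeset:
            provenance[node] = OVEREXPRESSED
        elif sub.nodes[node]["node_type"] == DRUG:
            provenance[node] = DRUG_PROV
        else:
            provenance[node] = NEIGHBOR
    return SubnetworkResult(name=name, graph=sub, provenance=provenance)


def build_refined_common(graph: nx.Graph, common_genes: Iterable[str],
                         induced: bool = True, name: str = "common") -> SubnetworkResult:
    """Refined common network: commonly over-expressed proteins plus direct interactors."""
    present = {protein_id(g.upper()) for g in common_genes} & set(graph.nodes)
    present = {n for n in present if graph.nodes[n]["node_type"] == PROTEIN}
    if not present:
        logger.warning("build_refined_common: no common gene present in the network")
        return SubnetworkResult(name=name, graph=nx.Graph(), provenance={})
    return expand_one_step(graph, present, induced=induced, name=name)


def report_druggable(sub: SubnetworkResult, seeds: set[str]) -> list[DruggableTarget]:
    """Report every over-expressed protein with at least one drug-target edge.

    Seed partners are the seed proteins adjacent (by PPI) to the protein in
    the sub-network, sorted; rows are ordered by descending seed-partner
    count, then symbol.
    """
    seeds = {s.upper() for s in seeds}
    graph = sub.graph
    rows = []
    for node, prov in sub.provenance.items():
        if prov != OVEREXPRESSED:
            continue
        drugs = []
        partners = []
        for nbr in graph.neighbors(node):
            data = graph.nodes[nbr]
            etype = graph.edges[node, nbr].get("edge_type")
            if data["node_type"] == DRUG and etype == DRUG_TARGET:
                drugs.append((symbol_of(nbr), data.get("name", "")))
            elif data["node_type"] == PROTEIN and etype == PPI and symbol_of(nbr) in seeds:
                partners.append(symbol_of(nbr))
        if not drugs:
            continue
        comps = comparisons_of(graph)
        called_in = tuple(
            (c, bool(graph.nodes[node].get(f"{c}.called", False))) for c in comps
        )
        rows.append(
            DruggableTarget(
                protein=symbol_of(node),
                seed_partners=tuple(sorted(partners)),
                drugs=tuple(sorted(drugs)),
                called_in=called_in,
                degree=graph.degree(node),
            )
        )
    rows.sort(key=lambda r: (-len(r.seed_partners), r.protein))
    return rows


def find_bridging(sub: SubnetworkResult, seeds: set[str],
                  min_partners: int = 2) -> list[BridgingNode]:
    """Bridging nodes: druggable over-expressed proteins with >= ``min_partners`` seeds.

    Operationalizes the observation that a druggable protein interacting with
    several distinct seed (CIS) proteins connects otherwise separate regions
    of the network.
    """
    if min_partners < 2:
        raise ValueError(f"min_partners must be >= 2, got {min_partners}")
    rows = report_druggable(sub, seeds)
    bridging = [
        BridgingNode(protein=r.protein, seed_partners=r.seed_partners, drugs=r.drugs)
        for r in rows
        if len(r.seed_partners) >= min_partners
    ]
    bridging.sort(key=lambda b: (-len(b.seed_partners), b.protein))
    return bridging


def rank_targets(rows: list[DruggableTarget],
                 call_sets: Mapping[str, GeneCallSet]) -> list[DruggableTarget]:
    """Prioritize druggable targets for follow-up.

    Stable sort key: number of subgroups in which the gene is called
    (descending), seed-partner count (descending), sub-network degree
    (descending), then symbol.
    """
    if not rows:
        raise ValueError("rank_targets requires a non-empty row list")

    def n_called(row: DruggableTarget) -> int:
        return sum(row.protein in cs.called for cs in call_sets.values())

    return sorted(rows, key=lambda r: (-n_called(r), -len(r.seed_partners),
                                       -r.degree, r.protein))
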