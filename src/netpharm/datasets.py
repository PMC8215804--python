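"""Worked medulloblastoma example: CIS seed genes and their druggable partners.

A small, fully enumerated network used in the documentation, tests and
acceptance checks: six seed (CIS) proteins, ten over-expressed druggable
interactors, thirteen PPI edges. TUBB interacts with three seeds and CDK6
with two, making them the example's bridging nodes. The drug table pairs
ixabepilone with TUBB (DrugBank id DB04845); the remaining drug records are
synthetic placeholders (ids prefixed ``DBSYN``) kept deliberately generic.
"""

from __future__ import annotations

import networkx as nx
import pandas as pd

from .discovery import SubnetworkResult, build_refined_common, find_bridging, report_druggable
from .expression import GeneCallSet
from .netbuild import annotate_de, attach_drugs, build_base_network

SEEDS: tuple[str, ...] = ("CDKN2A", "ZEB1", "MAP3K1", "TJP1", "PTN", "PPP2R5E")

#: 13 PPI edges: (druggable protein, seed partner)
EDGES: tuple[tuple[str, str], ...] = (
    ("CDK6", "CDKN2A"), ("CDK6", "ZEB1"),
    ("TUBB", "CDKN2A"), ("TUBB", "MAP3K1"), ("TUBB", "TJP1"),
    ("AURKA", "CDKN2A"), ("SNRPA", "CDKN2A"), ("CDK4", "CDKN2A"),
    ("CAD", "MAP3K1"), ("SLC1A5", "MAP3K1"),
    ("CHEK2", "PPP2R5E"), ("P4HB", "PTN"), ("PTPRS", "PTN"),
)

DRUGGABLE: tuple[str, ...] = tuple(sorted({u for u, _ in EDGES}))

#: expected protein -> seed-partner mapping
PARTNERS: dict[str, tuple[str, ...]] = {
    "AURKA": ("CDKN2A",),
    "CAD": ("MAP3K1",),
    "CDK4": ("CDKN2A",),
    "CDK6": ("CDKN2A", "ZEB1"),
    "CHEK2": ("PPP2R5E",),
    "P4HB": ("PTN",),
    "PTPRS": ("PTN",),
    "SLC1A5": ("MAP3K1",),
    "SNRPA": ("CDKN2A",),
    "TUBB": ("CDKN2A", "MAP3K1", "TJP1"),
}

BRIDGING: tuple[str, ...] = ("TUBB", "CDK6")  # 3 and 2 seed partners

_DRUG_ROWS: tuple[tuple[str, str, str], ...] = (
    ("DB04845", "ixabepilone", "TUBB"),
    ("DBSYN01", "aurka-inhibitor", "AURKA"),
    ("DBSYN02", "cdk4/6-inhibitor", "CDK4"),
    ("DBSYN02", "cdk4/6-inhibitor", "CDK6"),
    ("DBSYN03", "cad-inhibitor", "CAD"),
    ("DBSYN04", "chek2-inhibitor", "CHEK2"),
    ("DBSYN05", "p4hb-inhibitor", "P4HB"),
    ("DBSYN06", "ptprs-binder", "PTPRS"),
    ("DBSYN07", "slc1a5-blocker", "SLC1A5"),
    ("DBSYN08", "snrpa-binder", "SNRPA"),
)

COMPARISONS: tuple[str, ...] = ("SHH", "Gp3", "Gp4")


def ppi_table() -> pd.DataFrame:
    return pd.DataFrame(sorted(tuple(sorted(e)) for e in EDGES),
                        columns=["protein_a", "protein_b"])


def drug_table() -> pd.DataFrame:
    return pd.DataFrame(_DRUG_ROWS, columns=["drug_id", "drug_name", "target_symbol"])


def call_sets(comparisons: tuple[str, ...] = COMPARISONS) -> dict[str, GeneCallSet]:
    """Synthetic gene-level calls marking all ten druggable proteins over-expressed."""
    best = pd.DataFrame(
        {
            "probe_id": [f"{g}_p1" for g in DRUGGABLE],
            "lfc": 1.5, "t": 8.0, "p": 1e-5, "q": 1e-3, "called": True,
        },
        index=pd.Index(DRUGGABLE, name="gene_symbol"),
    )
    return {c: GeneCallSet(comparison=c, called=set(DRUGGABLE), best=best.copy())
            for c in comparisons}


def base_network() -> nx.Graph:
    return build_base_network(set(SEEDS), ppi_table())


def annotated_network() -> nx.Graph:
    graph = base_network()
    attach_drugs(graph, drug_table())
    annotate_de(graph, call_sets())
    return graph


def common_subnetwork() -> SubnetworkResult:
    return build_refined_common(annotated_network(), set(DRUGGABLE))


def analysis() -> dict:
    """Run the full discovery stage on the example; returns graph + reports."""
    graph = annotated_network()
    sub = common_subnetwork()
    rows = report_druggable(sub, set(SEEDS))
    bridges = find_bridging(sub, set(SEEDS))
    return {"base": base_network(), "network": graph, "subnetwork": sub,
            "druggable": rows, "bridging": bridges}
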