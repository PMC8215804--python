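"""End-to-end pipeline: normalize -> DE -> calls -> network -> discovery -> reports.

Stages run in a fixed order; any failure aborts with the stage name and the
underlying cause. A JSON run manifest records the tool version, input
checksums, parameters and per-stage counts so two runs of the same
configuration can be diffed (byte-identical outputs, manifests identical
modulo the timestamp).
"""

from __future__ import annotations

import datetime
import logging
from contextlib import contextmanager
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__, io
from .config import ComparisonSpec, RunConfig, StageError
from .discovery import (
    SubnetworkResult,
    build_refined_common,
    expand_one_step,
    find_bridging,
    rank_targets,
    report_druggable,
    select_upregulated,
)
from .expression import GeneCallSet, call_overexpressed, intersect_common, moderated_ttest, normalize
from .netbuild import annotate_de, attach_drugs, build_base_network, connected_components, map_seeds

logger = logging.getLogger("netpharm.pipeline")


@dataclass
class PipelineResult:
    manifest: dict
    out_dir: Path
    call_sets: dict[str, GeneCallSet] = field(default_factory=dict)
    common: set[str] = field(default_factory=set)
    subnetworks: dict[str, SubnetworkResult] = field(default_factory=dict)
    druggable: list = field(default_factory=list)
    bridging: list = field(default_factory=list)


@contextmanager
def _stage(name: str):
    logger.info("stage %s: start", name)
    try:
        yield
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001 - rewrap with stage context
        raise StageError(name, exc) from exc
    logger.info("stage %s: done", name)


def default_comparisons(annotation: pd.DataFrame,
                        normal_prefix: str = "normal") -> list[ComparisonSpec]:
    """One contrast per tumour group versus all pooled normal groups."""
    groups = list(dict.fromkeys(annotation["group"]))
    normals = tuple(g for g in groups if g.startswith(normal_prefix))
    if not normals:
        raise ValueError("no normal reference groups found in the annotation")
    return [ComparisonSpec(name=g, case=(g,), reference=normals)
            for g in groups if g not in normals]


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute the full analysis and write all reports under ``config.out_dir``."""
    config.validate_paths()
    out = Path(config.out_dir)
    (out / "de").mkdir(parents=True, exist_ok=True)
    (out / "calls").mkdir(exist_ok=True)
    (out / "networks").mkdir(exist_ok=True)
    counts: dict = {}

    with _stage("read_inputs"):
        matrix = io.read_matrix(config.expression)
        annotation = io.read_table(config.annotation, "annotation")
        probe_map = io.read_table(config.probe_map, "probe_map")
        orthologs = io.read_table(config.orthologs, "orthologs")
        ppi = io.read_table(config.ppi, "ppi")
        drugs = io.read_table(config.drugs, "drugs")
        cis = io.read_gene_list(config.cis_genes)
        counts["probes"] = int(matrix.shape[0])
        counts["samples"] = int(matrix.shape[1])

    with _stage("normalize"):
        for mode in config.normalize_steps:
            matrix = normalize(matrix, mode=mode)

    comparisons = config.comparisons or default_comparisons(annotation)

    call_sets: dict[str, GeneCallSet] = {}
    counts["genes_called"] = {}
    with _stage("differential_expression"):
        for spec in comparisons:
            de = moderated_ttest(matrix, annotation, spec)
            de.to_csv(out / "de" / f"{spec.name}.tsv", sep="\t",
                      float_format="%.6g", lineterminator="\n")
            cs = call_overexpressed(de, probe_map, alpha=config.alpha,
                                    min_lfc=config.min_lfc)
            call_sets[spec.name] = cs
            cs.best.to_csv(out / "calls" / f"{spec.name}.tsv", sep="\t",
                           float_format="%.6g", lineterminator="\n")
            counts["genes_called"][spec.name] = len(cs.called)

    with _stage("intersect_common"):
        common = intersect_common(list(call_sets.values())) if len(call_sets) >= 2 \
            else set(next(iter(call_sets.values())).called)
        io.write_gene_list(common, out / "common_genes.txt")
        counts["common_genes"] = len(common)

    with _stage("build_network"):
        seeds, unmapped = map_seeds(cis, orthologs)
        graph = build_base_network(seeds, ppi,
                                   include_neighbor_edges=config.include_neighbor_edges)
        attach_drugs(graph, drugs)
        annotate_de(graph, call_sets)
        counts["seeds_mapped"] = len(seeds)
        counts["seeds_unmapped"] = len(unmapped)
        counts["network"] = {"nodes": graph.number_of_nodes(),
                             "edges": graph.number_of_edges(),
                             "components": len(connected_components(graph))}
        io.write_graphml(graph, out / "networks" / "network.graphml")
        io.write_sif(graph, out / "networks" / "network.sif")
        io.write_node_table(graph, out / "networks" / "network_nodes.tsv")

    subnetworks: dict[str, SubnetworkResult] = {}
    counts["subnetworks"] = {}
    with _stage("subnetworks"):
        for spec in comparisons:
            up = select_upregulated(graph, spec.name)
            sub = expand_one_step(graph, up, induced=config.induced_expansion,
                                  name=spec.name)
            subnetworks[spec.name] = sub
            _write_subnetwork(sub, out / "networks")
            counts["subnetworks"][spec.name] = {
                "nodes": sub.graph.number_of_nodes(),
                "edges": sub.graph.number_of_edges()}
        sub_common = build_refined_common(graph, common,
                                          induced=config.induced_expansion)
        subnetworks["common"] = sub_common
        _write_subnetwork(sub_common, out / "networks")
        counts["subnetworks"]["common"] = {
            "nodes": sub_common.graph.number_of_nodes(),
            "edges": sub_common.graph.number_of_edges()}

    with _stage("reports"):
        druggable = report_druggable(sub_common, seeds)
        bridging = find_bridging(sub_common, seeds)
        ranked = rank_targets(druggable, call_sets) if druggable else []
        _write_druggable(druggable, out / "druggable_targets.tsv")
        _write_bridging(bridging, out / "bridging_nodes.tsv")
        _write_druggable(ranked, out / "ranked_targets.tsv")
        counts["druggable_rows"] = len(druggable)
        counts["bridging_rows"] = len(bridging)

    with _stage("manifest"):
        manifest = {
            "tool": "netpharm",
            "version": __version__,
            "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
            "inputs": {name: io.sha256_of(path)
                       for name, path in config.input_paths().items()},
            "parameters": {
                "alpha": config.alpha,
                "min_lfc": config.min_lfc,
                "normalize_steps": list(config.normalize_steps),
                "include_neighbor_edges": config.include_neighbor_edges,
                "induced_expansion": config.induced_expansion,
                "rng_seed": config.rng_seed,
                "comparisons": [
                    {"name": c.name, "case": list(c.case), "reference": list(c.reference)}
                    for c in comparisons],
            },
            "counts": counts,
        }
        io.write_manifest(manifest, out / "manifest.json")

    return PipelineResult(manifest=manifest, out_dir=out, call_sets=call_sets,
                          common=common, subnetworks=subnetworks,
                          druggable=druggable, bridging=bridging)


def _write_subnetwork(sub: SubnetworkResult, out_dir: Path) -> None:
    stem = f"subnet_{sub.name}"
    io.write_graphml(sub.graph, out_dir / f"{stem}.graphml")
    io.write_sif(sub.graph, out_dir / f"{stem}.sif")
    graph = sub.graph.copy()
    for node, prov in sub.provenance.items():
        graph.nodes[node]["provenance"] = prov
    io.write_node_table(graph, out_dir / f"{stem}_nodes.tsv")


def _write_druggable(rows, path: Path) -> None:
    records = [
        {
            "protein": r.protein,
            "seed_partners": ";".join(r.seed_partners),
            "drugs": ";".join(f"{i}:{n}" for i, n in r.drugs),
            **{f"called_{c}": flag for c, flag in r.called_in},
            "degree": r.degree,
        }
        for r in rows
    ]
    columns = list(records[0]) if records else [
        "protein", "seed_partners", "drugs", "degree"]
    pd.DataFrame(records, columns=columns).to_csv(
        path, sep="\t", index=False, lineterminator="\n")


def _write_bridging(rows, path: Path) -> None:
    records = [
        {
            "protein": r.protein,
            "n_seed_partners": len(r.seed_partners),
            "seed_partners": ";".join(r.seed_partners),
            "drugs": ";".join(f"{i}:{n}" for i, n in r.drugs),
        }
        for r in rows
    ]
    pd.DataFrame(records, columns=["protein", "n_seed_partners",
                                   "seed_partners", "drugs"]).to_csv(
        path, sep="\t", index=False, lineterminator="\n")
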