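"""Synthetic pipeline inputs with planted, recoverable structure.

Generates the five input tables the pipeline consumes -- probe-level
expression with sample groups, a probe->gene map, a mouse->human ortholog
table with the seed (CIS) gene list, a PPI edge list and a drug->target
table -- together with a :class:`SyntheticTruth` recording which genes were
planted over-expressed in which tumour subgroup and which druggable genes
were wired to two or more seeds (the planted bridging targets). Every
artifact is drawn from its own RNG sub-stream of one root seed, so e.g.
changing the probe count never perturbs the graph.

Model choices: the background PPI is Erdos-Renyi at a configured mean
degree with deterministic seed attachment and bridging wiring overlaid;
expression is i.i.d. Gaussian on the log2 scale with equal variance across
groups, a per-probe baseline level, and a fixed +effect_lfc shift added to
every probe of a planted gene in that tumour group's samples. Neither
Affymetrix intensity distributions nor real PPI degree distributions are
imitated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .config import ConfigError

__all__ = ["GeneratorConfig", "SyntheticTruth", "SyntheticData", "simulate",
           "generate_universe", "generate_ppi", "generate_drug_targets",
           "generate_expression", "write_inputs"]

# fixed sub-stream tags (root_seed, tag) -> independent generator per artifact
_STREAM_UNIVERSE = 11
_STREAM_PLANT = 13
_STREAM_PPI = 17
_STREAM_DRUGS = 19
_STREAM_EXPR = 23

FLOAT_FORMAT = "%.6f"


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic cohort + network generator.

    Defaults are the standard study conditions used throughout the test
    suite: three tumour subgroups and two pooled normal groups of 12 samples
    each, a +1.5 log2 planted effect against noise SD 0.7, up to 3 probes
    per gene, and a 500-gene universe with 30 seeds.
    """

    n_genes: int = 500
    n_seeds: int = 30
    mean_degree: float = 3.0
    n_drugs: int = 60
    targets_per_drug: int = 2
    groups: tuple[tuple[str, int], ...] = (
        ("SHH", 12), ("Gp3", 12), ("Gp4", 12),
        ("normal_fetal", 12), ("normal_adult", 12),
    )
    normal_groups: tuple[str, ...] = ("normal_fetal", "normal_adult")
    planted_per_group: Mapping[str, frozenset[str]] = field(default_factory=dict)
    planted_bridging: frozenset[str] = frozenset()
    n_planted_common: int = 20
    n_planted_specific: int = 10
    n_planted_bridging: int = 8
    effect_lfc: float = 1.5
    noise_sd: float = 0.7
    probes_per_gene_max: int = 3
    ortholog_one_to_many: float = 0.1
    baseline_mean: float = 7.0
    baseline_sd: float = 1.0
    rng_seed: int = 0

    def __post_init__(self):
        if self.n_genes <= 0:
            raise ConfigError("n_genes must be positive")
        if not 0 < self.n_seeds < self.n_genes:
            raise ConfigError(
                f"n_seeds must satisfy 0 < n_seeds < n_genes (got {self.n_seeds}, "
                f"n_genes={self.n_genes})")
        if self.mean_degree < 0:
            raise ConfigError("mean_degree must be >= 0")
        if self.n_drugs < 0 or self.targets_per_drug < 1:
            raise ConfigError("need n_drugs >= 0 and targets_per_drug >= 1")
        if self.noise_sd <= 0:
            raise ConfigError("noise_sd must be > 0")
        if self.probes_per_gene_max < 1:
            raise ConfigError("probes_per_gene_max must be >= 1")
        if not 0.0 <= self.ortholog_one_to_many <= 1.0:
            raise ConfigError("ortholog_one_to_many must be in [0, 1]")
        labels = [g for g, _ in self.groups]
        if len(labels) != len(set(labels)):
            raise ConfigError("group labels must be unique")
        if not self.groups:
            raise ConfigError("at least one group required")
        if not set(self.normal_groups) & set(labels):
            raise ConfigError("at least one normal group must be present")
        if not self.tumour_groups:
            raise ConfigError("at least one tumour group must be present")

    @property
    def tumour_groups(self) -> tuple[str, ...]:
        return tuple(g for g, _ in self.groups if g not in self.normal_groups)


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth planted by the generator.

    ``planted_bridging`` is derived from the realized artifacts: planted
    common genes that received a drug and are adjacent to at least two
    distinct seeds in the emitted PPI.
    """

    planted_overexpressed: Mapping[str, frozenset[str]]
    planted_common: frozenset[str]
    planted_bridging: frozenset[str]


@dataclass
class SyntheticData:
    """All generated inputs plus the planted truth."""

    universe: list[str]
    seeds: list[str]
    orthologs: pd.DataFrame
    ppi: pd.DataFrame
    drugs: pd.DataFrame
    expression: pd.DataFrame
    annotation: pd.DataFrame
    probe_map: pd.DataFrame
    truth: SyntheticTruth


def _rng(config: GeneratorConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.rng_seed % (2**31), stream])


def generate_universe(config: GeneratorConfig) -> tuple[list[str], list[str], pd.DataFrame]:
    """Gene universe, seed subset and mouse->human ortholog table.

    Human symbols are synthetic (``GN00001`` ...); the mouse symbol is the
    title-cased human symbol. A configured fraction of mouse symbols is made
    one-to-many by letting two human genes share one mouse symbol.
    """
    rng = _rng(config, _STREAM_UNIVERSE)
    universe = [f"GN{i + 1:05d}" for i in range(config.n_genes)]
    seeds = sorted(rng.choice(universe, size=config.n_seeds, replace=False))
    mouse = [h.capitalize() for h in universe]
    n_shared = int(round(config.ortholog_one_to_many * config.n_genes))
    if n_shared:
        idx = rng.choice(config.n_genes, size=min(2 * n_shared, config.n_genes), replace=False)
        for a, b in zip(idx[:n_shared], idx[n_shared:2 * n_shared]):
            mouse[b] = mouse[a]
    orthologs = pd.DataFrame({"mouse_symbol": mouse, "human_symbol": universe})
    return universe, seeds, orthologs


def generate_ppi(universe: list[str], seeds: list[str], config: GeneratorConfig,
                 bridging: frozenset[str] = frozenset()) -> pd.DataFrame:
    """Undirected PPI edge table: Erdos-Renyi background plus forced wiring.

    Every seed gets degree >= 1; every requested bridging gene is wired to
    two distinct seeds. Output is self-loop-free, duplicate-free and sorted.
    """
    if not set(seeds) <= set(universe):
        raise ConfigError("seeds must be a subset of the universe")
    if bridging and len(seeds) < 2:
        raise ConfigError("bridging wiring requires at least 2 seeds")
    if not set(bridging) <= set(universe):
        raise ConfigError("bridging genes must be in the universe")
    rng = _rng(config, _STREAM_PPI)
    n = len(universe)
    edges: set[tuple[str, str]] = set()
    p = min(1.0, config.mean_degree / max(n - 1, 1))
    if p > 0 and n > 1:
        iu, ju = np.triu_indices(n, k=1)
        hit = rng.random(iu.size) < p
        for i, j in zip(iu[hit], ju[hit]):
            edges.add((universe[i], universe[j]))
    index = {g: k for k, g in enumerate(universe)}
    degree = np.zeros(n, dtype=int)
    for u, v in edges:
        degree[index[u]] += 1
        degree[index[v]] += 1
    # deterministic seed attachment: every seed participates in >= 1 edge
    for s in seeds:
        if degree[index[s]] == 0:
            partner = s
            while partner == s:
                partner = universe[int(rng.integers(n))]
            edge = tuple(sorted((s, partner)))
            if edge not in edges:
                edges.add(edge)
                degree[index[edge[0]]] += 1
                degree[index[edge[1]]] += 1
    # bridging wiring: each bridging gene adjacent to 2 distinct seeds
    for g in sorted(bridging):
        candidates = [s for s in seeds if s != g]
        chosen = rng.choice(candidates, size=2, replace=False)
        for s in chosen:
            edges.add(tuple(sorted((g, s))))
    table = pd.DataFrame(sorted(edges), columns=["protein_a", "protein_b"])
    return table


def generate_drug_targets(universe: list[str], config: GeneratorConfig,
                          bridging: frozenset[str] = frozenset()) -> pd.DataFrame:
    """Drug->target table; every requested bridging gene receives >= 1 drug."""
    if not universe:
        raise ConfigError("empty gene universe")
    rng = _rng(config, _STREAM_DRUGS)
    rows: list[tuple[str, str, str]] = []
    ids = [f"DBS{i + 1:05d}" for i in range(config.n_drugs)]
    names = [f"drug{i + 1:03d}" for i in range(config.n_drugs)]
    k = min(config.targets_per_drug, len(universe))
    for drug, name in zip(ids, names):
        for target in sorted(rng.choice(universe, size=k, replace=False)):
            rows.append((drug, name, target))
    covered = {t for _, _, t in rows}
    uncovered = sorted(set(bridging) - covered)
    if uncovered and not ids:
        raise ConfigError("bridging genes require drugs but n_drugs == 0")
    for g in uncovered:
        i = int(rng.integers(len(ids)))
        rows.append((ids[i], names[i], g))
    table = (pd.DataFrame(rows, columns=["drug_id", "drug_name", "target_symbol"])
             .drop_duplicates(["drug_id", "target_symbol"])
             .sort_values(["drug_id", "target_symbol"], kind="mergesort")
             .reset_index(drop=True))
    return table


def generate_expression(
    universe: list[str], config: GeneratorConfig,
    planted_per_group: Mapping[str, frozenset[str]],
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Probe-level expression matrix, sample annotation and probe map.

    Each gene gets 1..probes_per_gene_max probes; values are a per-probe
    baseline plus i.i.d. N(0, noise_sd) noise; planted genes get
    +effect_lfc on every probe in their tumour group's samples. Normal
    groups are never shifted.
    """
    for group, genes in planted_per_group.items():
        missing = set(genes) - set(universe)
        if missing:
            raise ConfigError(f"planted gene(s) not in universe for {group}: "
                              f"{sorted(missing)[:5]}")
        if group in config.normal_groups:
            raise ConfigError(f"cannot plant over-expression in normal group {group!r}")
    rng = _rng(config, _STREAM_EXPR)
    n_probes_per_gene = rng.integers(1, config.probes_per_gene_max + 1, size=len(universe))
    probe_ids, probe_gene = [], []
    for gene, k in zip(universe, n_probes_per_gene):
        for j in range(int(k)):
            probe_ids.append(f"{gene}_p{j + 1}")
            probe_gene.append(gene)
    probe_map = pd.DataFrame({"probe_id": probe_ids, "gene_symbol": probe_gene})

    samples, sample_group = [], []
    for group, n in config.groups:
        for i in range(n):
            samples.append(f"{group}_{i + 1:02d}")
            sample_group.append(group)
    annotation = pd.DataFrame({"sample_id": samples, "group": sample_group})

    n_probes, n_samples = len(probe_ids), len(samples)
    baseline = rng.normal(config.baseline_mean, config.baseline_sd, size=n_probes)
    values = baseline[:, None] + rng.normal(0.0, config.noise_sd, size=(n_probes, n_samples))
    gene_idx = pd.Index(probe_gene)
    group_arr = np.asarray(sample_group)
    for group, genes in planted_per_group.items():
        rows = gene_idx.isin(genes)
        cols = group_arr == group
        values[np.ix_(rows, cols)] += config.effect_lfc
    matrix = pd.DataFrame(values, index=pd.Index(probe_ids, name="probe_id"),
                          columns=samples)
    return matrix, annotation, probe_map


def _auto_plant(config: GeneratorConfig, universe: list[str], seeds: list[str]
                ) -> tuple[dict[str, frozenset[str]], frozenset[str]]:
    """Pick planted gene sets when the config does not list them explicitly."""
    rng = _rng(config, _STREAM_PLANT)
    candidates = [g for g in universe if g not in set(seeds)]
    n_specific_total = config.n_planted_specific * len(config.tumour_groups)
    need = config.n_planted_common + n_specific_total
    if need > len(candidates):
        raise ConfigError(f"not enough non-seed genes to plant {need} (have {len(candidates)})")
    if config.n_planted_bridging > config.n_planted_common:
        raise ConfigError("n_planted_bridging cannot exceed n_planted_common")
    picked = list(rng.choice(candidates, size=need, replace=False))
    common = frozenset(picked[:config.n_planted_common])
    bridging = frozenset(sorted(common)[:config.n_planted_bridging])
    planted: dict[str, frozenset[str]] = {}
    offset = config.n_planted_common
    for group in config.tumour_groups:
        specific = picked[offset:offset + config.n_planted_specific]
        offset += config.n_planted_specific
        planted[group] = common | frozenset(specific)
    return planted, bridging


def simulate(config: GeneratorConfig) -> SyntheticData:
    """Generate the full set of pipeline inputs plus the planted truth."""
    universe, seeds, orthologs = generate_universe(config)
    if config.planted_per_group:
        planted = {g: frozenset(s) for g, s in config.planted_per_group.items()}
        bridging_req = frozenset(config.planted_bridging)
    else:
        planted, bridging_req = _auto_plant(config, universe, seeds)
    ppi = generate_ppi(universe, seeds, config, bridging=bridging_req)
    drugs = generate_drug_targets(universe, config, bridging=bridging_req)
    matrix, annotation, probe_map = generate_expression(universe, config, planted)

    tumour_planted = {g: frozenset(planted.get(g, frozenset()))
                      for g in config.tumour_groups}
    common = frozenset.intersection(*tumour_planted.values()) if tumour_planted else frozenset()
    # realized bridging truth: drugged AND adjacent to >= 2 seeds in the emitted PPI
    seed_set = set(seeds)
    seed_neighbors: dict[str, set[str]] = {}
    for u, v in ppi.itertuples(index=False):
        if v in seed_set:
            seed_neighbors.setdefault(u, set()).add(v)
        if u in seed_set:
            seed_neighbors.setdefault(v, set()).add(u)
    drugged = set(drugs["target_symbol"])
    bridging = frozenset(
        g for g in common
        if g in drugged and len(seed_neighbors.get(g, ())) >= 2
    )
    truth = SyntheticTruth(
        planted_overexpressed={g: s for g, s in tumour_planted.items()},
        planted_common=common,
        planted_bridging=bridging,
    )
    return SyntheticData(universe=universe, seeds=seeds, orthologs=orthologs,
                         ppi=ppi, drugs=drugs, expression=matrix,
                         annotation=annotation, probe_map=probe_map, truth=truth)


def write_inputs(data: SyntheticData, out_dir: str | Path) -> dict[str, Path]:
    """Write every artifact as TSV (plus the CIS list and truth table).

    The CIS list is written as *mouse* symbols (one per line) so a pipeline
    run exercises the ortholog-mapping step.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": out / "expression.tsv",
        "annotation": out / "annotation.tsv",
        "probe_map": out / "probe_map.tsv",
        "orthologs": out / "orthologs.tsv",
        "ppi": out / "ppi.tsv",
        "drugs": out / "drugs.tsv",
        "cis_genes": out / "cis_genes.txt",
        "truth": out / "truth.tsv",
    }
    data.expression.to_csv(paths["expression"], sep="\t", float_format=FLOAT_FORMAT,
                           lineterminator="\n")
    data.annotation.to_csv(paths["annotation"], sep="\t", index=False, lineterminator="\n")
    data.probe_map.to_csv(paths["probe_map"], sep="\t", index=False, lineterminator="\n")
    data.orthologs.to_csv(paths["orthologs"], sep="\t", index=False, lineterminator="\n")
    data.ppi.to_csv(paths["ppi"], sep="\t", index=False, lineterminator="\n")
    data.drugs.to_csv(paths["drugs"], sep="\t", index=False, lineterminator="\n")

    mouse_of = data.orthologs.groupby("human_symbol")["mouse_symbol"].agg(sorted)
    cis = sorted({m for s in data.seeds for m in mouse_of.get(s, [])})
    paths["cis_genes"].write_text("\n".join(cis) + "\n")

    rows = [("common", g) for g in sorted(data.truth.planted_common)]
    rows += [("bridging", g) for g in sorted(data.truth.planted_bridging)]
    for group in sorted(data.truth.planted_overexpressed):
        rows += [(group, g) for g in sorted(data.truth.planted_overexpressed[group])]
    pd.DataFrame(rows, columns=["set", "gene_symbol"]).to_csv(
        paths["truth"], sep="\t", index=False, lineterminator="\n")
    return paths
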