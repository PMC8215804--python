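import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from netpharm import datasets
from netpharm.synthetic import GeneratorConfig, simulate

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def table1():
    """The worked medulloblastoma example: network, sub-network and reports."""
    return datasets.analysis()


@pytest.fixture(scope="session")
def small_sim():
    """A small synthetic dataset shared across read-only tests."""
    config = GeneratorConfig(
        n_genes=120, n_seeds=10, mean_degree=2.0, n_drugs=15,
        targets_per_drug=2, probes_per_gene_max=2,
        groups=(("SHH", 6), ("Gp3", 6), ("normal_fetal", 6)),
        normal_groups=("normal_fetal",),
        n_planted_common=6, n_planted_specific=3, n_planted_bridging=3,
        rng_seed=42,
    )
    return config, simulate(config)


def random_network(rng: np.random.Generator, n_max: int = 100):
    """A random typed protein/drug network for oracle-equivalence tests."""
    import networkx as nx

    n = int(rng.integers(2, n_max + 1))
    p = float(rng.uniform(0.0, 0.12))
    graph = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
    graph = nx.relabel_nodes(graph, {i: f"P:G{i:03d}" for i in range(n)})
    for _, data in graph.nodes(data=True):
        data["node_type"] = "protein"
        data["is_seed"] = False
    nx.set_edge_attributes(graph, "ppi", "edge_type")
    proteins = sorted(graph.nodes)
    n_seeds = int(rng.integers(1, max(2, n // 4) + 1))
    seeds = set(rng.choice(proteins, size=n_seeds, replace=False))
    for s in seeds:
        graph.nodes[s]["is_seed"] = True
    n_drugs = int(rng.integers(0, 6))
    for k in range(n_drugs):
        target = proteins[int(rng.integers(len(proteins)))]
        node = f"D:DR{k:02d}"
        graph.add_node(node, node_type="drug", is_seed=False, name=f"drug{k}")
        graph.add_edge(node, target, edge_type="drug_target")
    return graph, {s.split(":", 1)[1] for s in seeds}
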