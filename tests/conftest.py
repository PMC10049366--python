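import networkx as nx
import numpy as np
import pytest

import ppiclust as pc


def random_graph(rng: np.random.Generator, n_max: int = 30) -> nx.Graph:
    """Connected Erdos-Renyi-ish graph with string node names."""
    n = int(rng.integers(4, n_max + 1))
    p = float(rng.uniform(0.1, 0.5))
    g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
    # stitch components together so BFS reaches everything
    comps = [sorted(c) for c in nx.connected_components(g)]
    for a, b in zip(comps, comps[1:]):
        g.add_edge(a[0], b[0])
    return nx.relabel_nodes(g, {i: f"n{i:02d}" for i in g.nodes})


def make_network(patient_id, seeds, imputed=(), edges=()):
    """Hand-build a SampleNetwork for unit tests."""
    return pc.SampleNetwork(
        patient_id=patient_id,
        seed_nodes=frozenset(seeds),
        imputed_nodes=frozenset(imputed),
        edges=frozenset(frozenset(e) for e in edges),
        k_seeds=len(seeds),
    )


@pytest.fixture(scope="session")
def planted_cohort() -> pc.SyntheticCohort:
    """Small planted two-module cohort shared across tests.

    20 cases / 60 controls, 1000-node background, one 50-gene module per
    group at effect size 3, k = 50 seeds.
    """
    cfg = pc.SimulationConfig(
        n_cases=20, n_controls=60, n_background_nodes=1000,
        modules=(pc.ModuleSpec("CASEMOD", 50, "case", 3.0),
                 pc.ModuleSpec("CTRLMOD", 50, "control", 3.0)),
        k_seeds=50, seed=7,
    )
    return pc.simulate_cohort(cfg)


@pytest.fixture()
def path6() -> nx.Graph:
    """Path graph 1-2-3-4-5-6 used for the separation fixture."""
    g = nx.path_graph(6)
    return nx.relabel_nodes(g, {i: str(i + 1) for i in g.nodes})
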