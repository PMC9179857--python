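import networkx as nx
import numpy as np
import pandas as pd
import pytest

import netmark as nm


def relabel(graph: nx.Graph) -> nx.Graph:
    return nx.relabel_nodes(graph, {v: f"n{v}" for v in graph.nodes()})


@pytest.fixture(scope="session")
def star5() -> nx.Graph:
    return relabel(nx.star_graph(4))


@pytest.fixture(scope="session")
def fixture_graphs() -> dict[str, nx.Graph]:
    return {
        "star": relabel(nx.star_graph(4)),
        "cycle": relabel(nx.cycle_graph(6)),
        "complete": relabel(nx.complete_graph(5)),
        "petersen": relabel(nx.petersen_graph()),
        "path": relabel(nx.path_graph(7)),
        "two_components": relabel(
            nx.disjoint_union(nx.cycle_graph(4), nx.path_graph(3))
        ),
    }


def random_graphs(n_graphs: int, max_nodes: int = 30, seed: int = 0):
    """Connected-ish Erdos-Renyi graphs of varying density (may be disconnected)."""
    rng = np.random.default_rng(seed)
    graphs = []
    for i in range(n_graphs):
        n = int(rng.integers(5, max_nodes + 1))
        p = float(rng.uniform(0.08, 0.5))
        g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31 - 1)))
        graphs.append(relabel(g))
    return graphs


@pytest.fixture(scope="session")
def default_run(tmp_path_factory):
    """One full synthetic pipeline run at the shipped default configuration."""
    out = tmp_path_factory.mktemp("pipeline_default")
    config = nm.default_config()
    manifest = nm.run_pipeline(config, out_dir=out)
    return manifest, out


@pytest.fixture(scope="session")
def small_sim() -> nm.SimulationResult:
    """A compact benchmark instance shared by unit tests."""
    return nm.simulate(
        nm.SyntheticConfig(
            n_nodes=400, module_size=15, n_biomarkers=8,
            n_cases=60, n_controls=60, seed=5,
        )
    )


@pytest.fixture()
def labeled_features():
    """Synthetic 11-column feature matrix with a planted two-feature AND rule."""
    from netmark.topology import FEATURE_NAMES

    def build(seed: int, rule: bool = True, n: int = 44,
              c1: float = -0.6, c2: float = -0.6):
        rng = np.random.default_rng(seed)
        X = pd.DataFrame(
            rng.normal(size=(n, 11)),
            columns=list(FEATURE_NAMES),
            index=[f"n{i:03d}" for i in range(n)],
        )
        if rule:
            lab = (X["clustering_coefficient"] > c1) & (
                X["betweenness_centrality"] > c2
            )
        else:
            lab = pd.Series(
                rng.permutation([True] * (n // 2) + [False] * (n - n // 2)),
                index=X.index,
            )
        frame = pd.DataFrame(
            {
                "label": np.where(lab, "biomarker", "non_biomarker"),
                "partition": "train",
            },
            index=X.index,
        )
        return X, nm.LabeledSet(frame)

    return build
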