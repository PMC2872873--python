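import networkx as nx
import numpy as np
import pandas as pd
import pytest

from modsubnet import (
    ExpressionDataset,
    ModuleSpec,
    SyntheticSpec,
    generate_expression,
    generate_network,
    weight_network,
)


@pytest.fixture
def toy_dataset() -> ExpressionDataset:
    """6 genes x 8 samples, two age groups, deterministic values."""
    rng = np.random.default_rng(42)
    genes = [f"g{i}" for i in range(6)]
    samples = [f"s{i}" for i in range(8)]
    vals = rng.standard_normal((6, 8))
    vals = (vals - vals.mean(1, keepdims=True)) / vals.std(1, ddof=0, keepdims=True)
    ages = pd.Series([4.0] * 4 + [10.0] * 4, index=samples, name="age")
    return ExpressionDataset(pd.DataFrame(vals, index=genes, columns=samples), ages)


@pytest.fixture
def toy_network(toy_dataset) -> nx.Graph:
    """Weighted path + triangle over the toy genes."""
    g = nx.Graph()
    g.add_edges_from(
        [("g0", "g1"), ("g1", "g2"), ("g2", "g0"), ("g2", "g3"), ("g3", "g4"), ("g4", "g5")]
    )
    return weight_network(g, toy_dataset)


@pytest.fixture
def small_planted():
    """One 8-gene planted module in a 60-node background, with expression."""
    spec = SyntheticSpec(
        n_background_nodes=60,
        background_edge_prob=0.03,
        modules=[ModuleSpec(size=8)],
        rng_seed=7,
    )
    g, membership = generate_network(spec)
    d = generate_expression(spec, g, membership)
    return spec, g, membership, d


def random_weighted_graph(n, p, rng):
    """ER graph with uniform(0,1) weights (shared helper for oracle tests)."""
    g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
    g = nx.relabel_nodes(g, {i: f"n{i:03d}" for i in g.nodes})
    for _, _, data in g.edges(data=True):
        data["weight"] = float(rng.random())
    return g
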