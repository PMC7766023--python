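import numpy as np
import pytest

from topicsbm.bigraph import BipartiteGraph
from topicsbm.synthetic import SyntheticConfig, generate_dataset


def random_tiny_graph(rng, max_side=4, max_mult=3):
    """Random bipartite multigraph small enough for exhaustive enumeration."""
    ng = int(rng.integers(2, max_side + 1))
    ns = int(rng.integers(2, max_side + 1))
    dense = rng.integers(0, max_mult + 1, size=(ng, ns))
    if dense.sum() == 0:
        dense[0, 0] = 1
    gi, sj = np.nonzero(dense)
    return BipartiteGraph([f"g{i}" for i in range(ng)],
                          [f"s{j}" for j in range(ns)],
                          gi, sj, dense[gi, sj])


@pytest.fixture(scope="session")
def tiny_graph_suite():
    rng = np.random.default_rng(42)
    return [random_tiny_graph(rng) for _ in range(20)]


@pytest.fixture(scope="session")
def small_dataset():
    """Small planted dataset shared across read-only tests."""
    cfg = SyntheticConfig(n_samples=60, n_genes=120, n_clusters=2, n_topics=3,
                          depth_mean=400.0, seed=11)
    expr, truth = generate_dataset(cfg)
    return cfg, expr, truth
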