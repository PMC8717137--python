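from datetime import datetime

import numpy as np
import pytest

from ohcnet.synth import SynthConfig, generate_forum


@pytest.fixture(scope="session")
def small_config() -> SynthConfig:
    return SynthConfig(
        n_users=120,
        n_threads=250,
        span=(datetime(2018, 1, 1), datetime(2020, 6, 1)),
        replies_mean=6.0,
        tokens_per_post=8,
        vocab_size=80,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_forum(small_config):
    return generate_forum(small_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240915)


def random_digraph(n_nodes: int, p: float, seed: int):
    """Seeded Erdos-Renyi digraph used as oracle input across test modules."""
    import networkx as nx

    rng = np.random.default_rng(seed)
    g = nx.DiGraph()
    g.add_nodes_from(range(n_nodes))
    mask = rng.random((n_nodes, n_nodes)) < p
    np.fill_diagonal(mask, False)
    src, dst = np.nonzero(mask)
    g.add_edges_from(zip(src.tolist(), dst.tolist()))
    return g
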