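import numpy as np
import pytest

from neuroperc import Connectome, EPDConfig, simulate_epd


@pytest.fixture
def f4_connectome() -> Connectome:
    """Four-node worked example: node c has initial degree 2 and the
    increasing-length attack gives P = 1, 1, 3/4, 2/4, 1/4."""
    return Connectome.from_edge_records(
        [
            ("a", "c", 1.0, 2.0),
            ("b", "c", 2.0, 1.0),
            ("a", "b", 3.0, 4.0),
            ("b", "d", 4.0, 3.0),
        ]
    )


@pytest.fixture
def triangle() -> Connectome:
    return Connectome.from_edge_records(
        [("a", "b", 1.0, 1.0), ("b", "c", 2.0, 1.0), ("a", "c", 3.0, 1.0)]
    )


@pytest.fixture(scope="session")
def small_epd():
    """One reduced-scale EPD run (120 nodes, final <k> = 20) shared across tests."""
    config = EPDConfig(N=120, k_final=20.0, seed=7)
    connectome, trajectory = simulate_epd(config)
    return config, connectome, trajectory


def random_connectome(rng: np.random.Generator, n: int, m: int) -> Connectome:
    """Random simple weighted graph for round-trip / oracle tests."""
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    chosen = rng.choice(len(pairs), size=min(m, len(pairs)), replace=False)
    records = []
    for idx in chosen:
        i, j = pairs[idx]
        records.append(
            (
                f"v{i}",
                f"v{j}",
                float(rng.uniform(0.1, 100.0)),
                float(rng.uniform(1.0, 50.0)),
            )
        )
    labels = [f"v{i}" for i in range(n)]
    conn = Connectome.from_edge_records(records)
    # keep isolated labels too so node sets are predictable
    missing = [lab for lab in labels if lab not in conn.node_ids]
    return Connectome(
        node_ids=conn.node_ids + missing,
        edges=conn.edges,
    )
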