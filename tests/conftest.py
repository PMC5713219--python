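import numpy as np
import pytest

from allopath import (
    ContactMap,
    PlantedModel,
    build_graph,
    make_chain,
    plant_path_graph,
    sample_correlated_trajectory,
    select_calpha,
)

PLANTED_PAIRS = [(2, 7, 0.5), (3, 11, -0.9), (4, 15, 0.3), (5, 18, -0.5), (8, 12, 0.9)]


@pytest.fixture(scope="session")
def planted_corr():
    corr = np.eye(20)
    for i, j, rho in PLANTED_PAIRS:
        corr[i, j] = corr[j, i] = rho
    return corr


@pytest.fixture(scope="session")
def planted_trajectory(planted_corr):
    """20k-frame correlated trajectory with known fluctuation structure."""
    model = PlantedModel(
        reference=make_chain(20, "helix"),
        target_corr=planted_corr,
        amplitude=1.0,
        n_frames=20000,
        seed=1,
    )
    return sample_correlated_trajectory(model)


@pytest.fixture(scope="session")
def calpha(planted_trajectory):
    return select_calpha(planted_trajectory.topology)


@pytest.fixture
def diamond_graph():
    """4-node diamond: two source-to-sink branches with |X| 0.9 and 0.5."""
    corr, contacts = plant_path_graph(
        4, [(0, 1, 0.9), (1, 3, 0.9), (0, 2, 0.5), (2, 3, 0.5)]
    )
    return build_graph(corr, ContactMap(values=contacts, cutoff=8.0, occupancy=1.0))


def random_graph(rng: np.random.Generator, n_nodes: int):
    """Connected random residue graph with |X| weights in (0.05, 1]."""
    while True:
        n_extra = int(rng.integers(0, n_nodes * (n_nodes - 1) // 2))
        edges = {(i - 1, i) for i in range(1, n_nodes)}  # spanning chain
        for _ in range(n_extra):
            i, j = sorted(rng.choice(n_nodes, size=2, replace=False))
            edges.add((int(i), int(j)))
        weighted = [
            (i, j, float(rng.uniform(0.05, 1.0))) for i, j in sorted(edges)
        ]
        corr, contacts = plant_path_graph(n_nodes, weighted)
        return build_graph(
            corr, ContactMap(values=contacts, cutoff=8.0, occupancy=1.0)
        )
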