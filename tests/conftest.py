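import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from braingraph.network import BinaryNetwork
from braingraph.synthetic import CohortSpec, CovarianceSpec, simulate_cohort


def net_from_edges(n: int, edges, sparsity: float = 0.5) -> BinaryNetwork:
    """Build a BinaryNetwork from an explicit edge list (test helper)."""
    adj = np.zeros((n, n), dtype=np.int8)
    for i, j in edges:
        adj[i, j] = adj[j, i] = 1
    return BinaryNetwork(adjacency=adj, sparsity=sparsity)


def random_net(n: int, p: float, seed: int) -> BinaryNetwork:
    """Erdos-Renyi-style random binary network (at least one edge)."""
    rng = np.random.default_rng(seed)
    while True:
        upper = rng.random((n, n)) < p
        adj = np.triu(upper, 1).astype(np.int8)
        adj |= adj.T
        if adj.sum() >= 2:
            return BinaryNetwork(adjacency=adj, sparsity=max(p, 1e-3))


@pytest.fixture(scope="session")
def small_cohort():
    """A light 24-ROI cohort (6 cases / 6 controls) shared across tests."""
    spec = CohortSpec(
        covariance=CovarianceSpec(n_rois=24, n_modules=3),
        n_per_group=(6, 6),
        n_timepoints=120,
        implanted_component=tuple((i, i + 1) for i in range(4)),
        duration_link=(2, 0.025),
        seed=11,
    )
    return spec, simulate_cohort(spec)
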