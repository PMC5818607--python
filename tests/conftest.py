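"""Shared fixtures: tiny deterministic graphs and synthetic cohorts."""

import numpy as np
import pytest

from mklconn import (
    ScaleSet,
    StructuralConnectome,
    SyntheticCohortSpec,
    build_kernel_bank,
    build_laplacian,
    default_scale_set,
    generate_cohort,
)


def random_connected_sc(n: int, seed: int, density: float = 0.5) -> StructuralConnectome:
    """Random weighted graph, redrawn until connected (a ring guarantees it)."""
    rng = np.random.default_rng(seed)
    W = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    mask = rng.random(iu[0].size) < density
    W[iu] = rng.lognormal(0.0, 0.5, iu[0].size) * mask
    W = W + W.T
    # overlay a weighted ring so the graph is always connected
    for i in range(n):
        j = (i + 1) % n
        if W[i, j] == 0:
            W[i, j] = W[j, i] = 0.1
    return StructuralConnectome.from_weights(W, subject_id=f"rand{seed}")


@pytest.fixture
def k2_sc():
    return StructuralConnectome.from_weights([[0.0, 1.0], [1.0, 0.0]])


@pytest.fixture
def ring_sc():
    n = 8
    W = np.zeros((n, n))
    for i in range(n):
        W[i, (i + 1) % n] = W[(i + 1) % n, i] = 1.0
    return StructuralConnectome.from_weights(W)


@pytest.fixture
def small_spec():
    return build_laplacian(random_connected_sc(10, seed=3))


@pytest.fixture(scope="session")
def noiseless_cohort():
    """15 subjects, n=12, m=3, exact forward-model FCs (no noise)."""
    spec = SyntheticCohortSpec(n=12, p=15, m=3, fc_noise_sd=0.0,
                               pi_sparsity=0.1, seed=7)
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def noisy_cohort():
    """15 subjects, n=20, m=4, sparse ground truth, mild FC noise."""
    spec = SyntheticCohortSpec(n=20, p=15, m=4, fc_noise_sd=0.01,
                               pi_sparsity=0.05, seed=11)
    return generate_cohort(spec)
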