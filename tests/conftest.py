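"""Shared fixtures: small synthetic networks and cohorts."""

import numpy as np
import pytest
from hypothesis import settings

from tauspread.connectome import BrainNetwork, RegionTable

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture
def two_node_network() -> BrainNetwork:
    regions = RegionTable(("A", "B"), ("left", "right"), np.array([True, True]))
    return BrainNetwork.from_adjacency(regions, np.array([[0.0, 1.0], [1.0, 0.0]]))


@pytest.fixture
def triangle_network() -> BrainNetwork:
    """3-node triangle with weights 1, 2, 3."""
    regions = RegionTable(("A", "B", "C"), ("left", "left", "right"),
                          np.array([True, True, True]))
    A = np.array([[0.0, 1.0, 3.0], [1.0, 0.0, 2.0], [3.0, 2.0, 0.0]])
    return BrainNetwork.from_adjacency(regions, A)


def make_random_network(n: int, seed: int, p: float = 0.5,
                        w_lo: float = 0.05, w_hi: float = 0.5) -> BrainNetwork:
    """Random weighted graph used across dynamics and inference tests."""
    rng = np.random.default_rng(seed)
    half = n // 2
    names = tuple(f"lh-r{i}" if i < half else f"rh-r{i}" for i in range(n))
    hemis = tuple("left" if i < half else "right" for i in range(n))
    regions = RegionTable(names, hemis, np.ones(n, dtype=bool))
    A = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                A[i, j] = A[j, i] = rng.uniform(w_lo, w_hi)
    return BrainNetwork.from_adjacency(regions, A)


@pytest.fixture
def small_random_network() -> BrainNetwork:
    return make_random_network(10, seed=5)
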