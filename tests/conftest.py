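import numpy as np
import pandas as pd
import pytest

from ndm import (
    Connectome,
    RegionTable,
    SyntheticSpec,
    synth_atrophy,
    synth_connectome,
)


def make_regions(labels):
    return RegionTable.from_labels(labels)


@pytest.fixture
def two_node():
    regions = make_regions(["lh_a", "rh_a"])
    return Connectome(np.array([[0.0, 2.0], [2.0, 0.0]]), regions)


@pytest.fixture
def k3():
    """Complete graph on 3 nodes, unit weights (one midline node)."""
    regions = make_regions(["lh_a", "rh_a", "mid"])
    w = np.ones((3, 3)) - np.eye(3)
    return Connectome(w, regions)


def random_connectome(rng, n=10, density=0.4):
    """Small connected random weighted bilateral graph for property tests."""
    half = n // 2
    labels = [f"lh_r{i}" for i in range(half)] + [f"rh_r{i}" for i in range(half)]
    while True:
        w = np.triu((rng.random((n, n)) < density) * rng.random((n, n)), k=1)
        w = w + w.T
        for i in range(half):
            w[i, i + half] = w[i + half, i] = 0.5 + rng.random()
        try:
            return Connectome(w, make_regions(labels))
        except Exception:
            continue


@pytest.fixture(scope="session")
def study82():
    """One deterministic 82-region synthetic study shared across tests."""
    spec = SyntheticSpec(rng_seed=20240917, seed_pair=11, t_star=12.0, noise_sigma=0.05)
    c = synth_connectome(spec)
    amap, truth = synth_atrophy(spec, c)
    return spec, c, amap, truth
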