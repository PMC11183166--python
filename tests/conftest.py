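"""Shared fixtures: small seeded cohorts and simple graphs."""

import numpy as np
import pytest

import morphnet as mn


@pytest.fixture(scope="session")
def small_cohort():
    """A quick 6-vs-6, 12-region cohort with no group effect."""
    cfg = mn.CohortConfig(
        n_per_group=6, n_regions=12, voxels_per_region=(80, 160),
        n_communities=4, seed=11,
    )
    subjects, clinical = mn.generate_cohort(cfg)
    return cfg, subjects, clinical


@pytest.fixture(scope="session")
def effect_cohort():
    """A 10-vs-10, 20-region cohort with a strong planted effect."""
    cfg = mn.CohortConfig(
        n_per_group=10, n_regions=20, voxels_per_region=(100, 250),
        n_communities=5, effect_nodes=(1, 6, 11), effect_size=2.5, seed=23,
    )
    subjects, clinical = mn.generate_cohort(cfg)
    return cfg, subjects, clinical


@pytest.fixture(scope="session")
def small_similarity(small_cohort):
    """Similarity matrices (KLDs) for the small cohort."""
    _, subjects, _ = small_cohort
    return [mn.build_similarity_matrix(s) for s in subjects]


def random_graph(n, p, seed):
    """Erdos-Renyi helper used by oracle comparisons."""
    rng = np.random.default_rng(seed)
    a = (rng.random((n, n)) < p).astype(np.uint8)
    a = np.triu(a, 1)
    a = a | a.T
    return mn.BinaryGraph(adjacency=a)
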