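import numpy as np
import pytest

from sigprog.io import ExpressionMatrix, ReferenceProfile, ReferenceSet


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_profile(treatment_id, ranks, universe=None):
    """Build a ReferenceProfile from a probe->signed_rank mapping."""
    if universe is None:
        universe = tuple(sorted(ranks))
    return ReferenceProfile(
        treatment_id, tuple(universe), np.array([ranks[p] for p in universe])
    )


def random_profile(name, n, rng):
    universe = tuple(f"G{i:03d}" for i in range(n))
    mags = rng.permutation(n) + 1
    signs = rng.integers(0, 2, size=n) * 2 - 1
    return ReferenceProfile(name, universe, mags * signs)


def random_set(name, n, n_rep, rng):
    profiles = [random_profile(f"{name}_{r}", n, rng) for r in range(n_rep)]
    return ReferenceSet(name, profiles)


@pytest.fixture
def small_matrix():
    """3 probes x 4 samples, two complete pairs."""
    return ExpressionMatrix(
        probe_ids=["P1", "P2", "P3"],
        sample_ids=["s1c", "s1t", "s2c", "s2t"],
        values=np.array([[6.0, 7.0, 6.2, 7.1], [8.0, 8.0, 8.1, 8.0], [5.0, 4.0, 5.1, 4.2]]),
        condition=["control", "treatment", "control", "treatment"],
        pair_id=["p1", "p1", "p2", "p2"],
    )
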