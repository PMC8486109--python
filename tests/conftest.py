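"""Shared fixtures: toy geometries and reusable (session-scoped) MCMC runs."""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import betasimm as bs

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def toy4():
    """Default 4-source centroid toy (sources at +-10 per mil, SD 1)."""
    return bs.make_centroid_toy()


@pytest.fixture(scope="session")
def toy4_ordinary(toy4):
    space, data = toy4
    return bs.sample_ordinary(data, space, bs.ModelSpec(),
                              n_iter=60_000, n_chains=4, seed=101,
                              n_keep=60_000)


@pytest.fixture(scope="session")
def toy4_beta1000(toy4):
    space, data = toy4
    return bs.sample_beta(data, space, bs.ModelSpec(beta=1000.0),
                          n_iter=30_000, n_chains=4, seed=102, n_keep=60_000)


@pytest.fixture(scope="session")
def toy3():
    """3-source centroid toy (identified up to the usual simplex coupling)."""
    return bs.make_centroid_toy(bs.ToySpec(n_sources=3))


@pytest.fixture(scope="session")
def toy3_ordinary(toy3):
    space, data = toy3
    return bs.sample_ordinary(data, space, bs.ModelSpec(),
                              n_iter=80_000, n_chains=4, seed=103,
                              n_keep=60_000)


@pytest.fixture(scope="session")
def triangle():
    """Well-conditioned, affinely independent 3-source mixing space."""
    return bs.MixingSpace(["A", "B", "C"], ["d13C", "d15N"],
                          [[0, 0], [10, 0], [0, 10]], np.ones((3, 2)))


def make_draws(p_draws, beta=1.0, scale_draws=None, seed=0):
    """Hand-built PosteriorDraws for diagnostics tests."""
    p_draws = np.asarray(p_draws, dtype=float)
    M, K = p_draws.shape
    if scale_draws is None:
        scale_draws = np.ones((M, 1))
    names = tuple("ABCDEFGH"[:K])
    return bs.PosteriorDraws(
        p_draws=p_draws, scale_draws=np.asarray(scale_draws, dtype=float),
        beta=beta, n_chains=1, seed=seed, source_names=names,
        scale_names=("eps_1",), chain_index=np.zeros(M, dtype=int))
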