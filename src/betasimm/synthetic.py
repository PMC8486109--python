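"""Synthetic mixing-space generators for testing and demonstration.

The central fixture is the "centroid toy": K sources placed at equal angles
on a circle in a two-isotope plane, with a consumer sitting exactly at the
centroid of the fractionation-corrected source means.  With four sources
this is the canonical underdetermined geometry — a one-dimensional family of
proportion vectors reproduces the consumer exactly — so the ordinary
posterior is wide while the exact-fit ridge is sharply constrained, which is
precisely the situation the tempered-posterior diagnostic is built to
expose.  A collinear-source generator provides the other classic degenerate
geometry, and a forward simulator produces consumers from known proportions
for parameter-recovery tests.
"""

from __future__ import annotations

import string
from dataclasses import dataclass

import numpy as np

from .model import MixingSpace, MixtureData

__all__ = ["ToySpec", "make_centroid_toy", "simulate_consumers",
           "make_collinear_space", "write_toy_fixtures"]


@dataclass(frozen=True)
class ToySpec:
    """Configuration of the centroid toy.

    Defaults place four sources at (+-spread, 0) and (0, +-spread) in a
    two-isotope plane with spread = 10 per mil and a common source SD of
    1 per mil, zero TEFs, and a single consumer exactly at the centroid.
    """

    n_sources: int = 4
    spread: float = 10.0
    source_sd: float = 1.0
    tef_zero: bool = True
    consumer_at_centroid: bool = True
    n_consumers: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.n_sources < 3:
            raise ValueError("the toy needs at least three sources")
        if not self.spread > 0:
            raise ValueError("spread must be positive")
        if self.source_sd < 0:
            raise ValueError("source_sd must be non-negative")
        if self.n_consumers < 1:
            raise ValueError("n_consumers must be at least 1")


def _source_labels(n: int) -> list[str]:
    letters = string.ascii_uppercase
    return [f"Source {letters[i % 26]}{'' if i < 26 else i // 26}"
            for i in range(n)]


def make_centroid_toy(spec: ToySpec = ToySpec()) -> tuple[MixingSpace, MixtureData]:
    """Build the centroid toy mixing space and its consumer data.

    Sources sit at equal angles on a circle of radius ``spread``; every
    source has SD ``source_sd`` on both isotopes.  With ``tef_zero`` unset, a
    nominal TEF of 1 per mil (SD 0.1) is applied to every source so that
    fractionation handling is exercised; the consumer is then placed at the
    centroid of the *corrected* means, keeping the geometry intact.
    """
    K = spec.n_sources
    ang = 2 * np.pi * np.arange(K) / K
    mean = spec.spread * np.column_stack([np.cos(ang), np.sin(ang)])
    mean = np.round(mean, 12)  # clean up exact axis positions
    sd = np.full((K, 2), float(spec.source_sd))
    if spec.tef_zero:
        tef_mean = np.zeros((K, 2))
        tef_sd = np.zeros((K, 2))
    else:
        tef_mean = np.ones((K, 2))
        tef_sd = np.full((K, 2), 0.1)
    space = MixingSpace(_source_labels(K), ["d13C", "d15N"],
                        mean, sd, tef_mean, tef_sd)
    centroid = space.corrected_mean.mean(axis=0)
    if spec.consumer_at_centroid:
        values = np.tile(centroid, (spec.n_consumers, 1))
        data = MixtureData(values)
    else:
        data = simulate_consumers(space, np.full(K, 1.0 / K), spec.n_consumers,
                                  resid_sd=np.zeros(2), seed=spec.seed)
    return space, data


def simulate_consumers(space: MixingSpace, p_true, n: int, resid_sd,
                       seed: int = 0) -> MixtureData:
    """Draw consumers from the marginalized generative model.

    Each consumer value on isotope j is normal with mean
    ``sum_k p_k (source + TEF mean)`` and variance
    ``sum_k p_k^2 (source SD^2 + TEF SD^2) + resid_sd_j^2``.
    """
    p = np.asarray(p_true, dtype=float)
    if p.shape != (space.n_sources,):
        raise ValueError("p_true length must match the number of sources")
    if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("p_true must lie on the simplex")
    if n < 1:
        raise ValueError("n must be at least 1")
    resid_sd = np.broadcast_to(np.asarray(resid_sd, dtype=float),
                               (space.n_isotopes,))
    mean = p @ space.corrected_mean
    var = (p**2) @ space.pooled_var + resid_sd**2
    rng = np.random.default_rng(seed)
    values = mean + np.sqrt(var) * rng.standard_normal((n, space.n_isotopes))
    return MixtureData(values)


def make_collinear_space(n_sources: int = 3, seed: int = 0) -> MixingSpace:
    """Sources equally spaced on a line in the two-isotope plane.

    The classic problematic geometry: any interior source is isotopically
    indistinguishable from a mixture of its neighbours, so its contribution
    is underdetermined no matter how precise the data.  The line's
    orientation is drawn from ``seed``; spacing is 5 per mil along the line
    and every source has SD 1 per mil.
    """
    if n_sources < 3:
        raise ValueError("need at least three collinear sources")
    rng = np.random.default_rng(seed)
    theta = rng.uniform(0, np.pi)
    direction = np.array([np.cos(theta), np.sin(theta)])
    offsets = 5.0 * (np.arange(n_sources) - (n_sources - 1) / 2)
    mean = offsets[:, None] * direction[None, :]
    sd = np.ones((n_sources, 2))
    return MixingSpace(_source_labels(n_sources), ["d13C", "d15N"],
                       mean, sd, np.zeros_like(mean), np.zeros_like(mean))


def write_toy_fixtures(directory, spec: ToySpec = ToySpec()):
    """Write the toy's three CSV inputs (mixtures, sources, TEFs).

    The files use the exact dialect the command-line reader expects, so
    they double as format documentation.  Returns the three paths.
    """
    from . import io as simm_io

    space, data = make_centroid_toy(spec)
    return simm_io.write_fixture_csvs(directory, space, data)
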