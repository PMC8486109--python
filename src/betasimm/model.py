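"""Core data model and log-densities for stable isotope mixing models.

A stable isotope mixing model (SIMM) infers the proportional contribution
``p`` of K food sources to a consumer ("mixture") from J isotope ratios.
Each source carries an isotopic signature (mean and SD per isotope) and a
trophic enrichment factor (TEF, mean and SD) that shifts the signature for
consumer metabolism.  The marginalized likelihood treats each consumer value
on isotope j as normal with

    mean_j     = sum_k p_k (source_mean_kj + tef_mean_kj)
    variance_j = sum_k p_k^2 (source_sd_kj^2 + tef_sd_kj^2) + error term

where the error term is either an additive residual variance ``eps_j^2``
(SIAR-style residual parameterization) or a multiplicative factor ``xi_j``
applied to the process variance (Stock-style parameterization).

The tempered ("beta-dependent") posterior raises both the likelihood and the
prior to a power beta; beta = 1 is the ordinary posterior and large beta
concentrates the distribution onto the set of joint posterior peaks, which is
how underdetermination is diagnosed downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import gammaln

__all__ = [
    "MixingSpace",
    "MixtureData",
    "ModelSpec",
    "ParamState",
    "DegenerateVarianceError",
    "marginal_loglik_siar",
    "marginal_loglik_stock",
    "log_prior",
    "log_beta_posterior",
]

ERROR_MODELS = ("siar_residual", "stock_multiplicative")


class DegenerateVarianceError(ValueError):
    """Raised when the model variance is non-positive on some isotope."""


def _as_matrix(x, name: str, shape: tuple[int, int]) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.shape != shape:
        raise ValueError(f"{name} must have shape {shape}, got {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite entries")
    return arr


@dataclass(frozen=True)
class MixingSpace:
    """Isotopic mixing space: per-source signature and TEF means/SDs.

    Parameters
    ----------
    source_names : K labels.
    isotope_names : J labels.
    source_mean, source_sd : (K, J) arrays of source isotope values, per mil.
    tef_mean, tef_sd : (K, J) arrays of trophic enrichment factors, per mil.
    """

    source_names: tuple[str, ...]
    isotope_names: tuple[str, ...]
    source_mean: np.ndarray
    source_sd: np.ndarray
    tef_mean: np.ndarray
    tef_sd: np.ndarray

    def __init__(self, source_names, isotope_names, source_mean, source_sd,
                 tef_mean=None, tef_sd=None):
        source_names = tuple(str(s) for s in source_names)
        isotope_names = tuple(str(s) for s in isotope_names)
        K, J = len(source_names), len(isotope_names)
        if K < 2:
            raise ValueError("a mixing space needs at least two sources")
        if J < 1:
            raise ValueError("a mixing space needs at least one isotope")
        if len(set(source_names)) != K:
            raise ValueError("duplicate source names")
        shape = (K, J)
        source_mean = _as_matrix(source_mean, "source_mean", shape)
        source_sd = _as_matrix(source_sd, "source_sd", shape)
        tef_mean = _as_matrix(
            np.zeros(shape) if tef_mean is None else tef_mean, "tef_mean", shape)
        tef_sd = _as_matrix(
            np.zeros(shape) if tef_sd is None else tef_sd, "tef_sd", shape)
        for nm, sd in (("source_sd", source_sd), ("tef_sd", tef_sd)):
            if np.any(sd < 0):
                raise ValueError(f"{nm} has negative entries")
        for nm, val in (("source_mean", source_mean), ("source_sd", source_sd),
                        ("tef_mean", tef_mean), ("tef_sd", tef_sd)):
            val.setflags(write=False)
            object.__setattr__(self, nm, val)
        object.__setattr__(self, "source_names", source_names)
        object.__setattr__(self, "isotope_names", isotope_names)

    @property
    def n_sources(self) -> int:
        return len(self.source_names)

    @property
    def n_isotopes(self) -> int:
        return len(self.isotope_names)

    @property
    def corrected_mean(self) -> np.ndarray:
        """Fractionation-corrected source means (source + TEF), (K, J)."""
        return self.source_mean + self.tef_mean

    @property
    def pooled_var(self) -> np.ndarray:
        """Per-source process variance (source SD^2 + TEF SD^2), (K, J)."""
        return self.source_sd**2 + self.tef_sd**2


@dataclass(frozen=True)
class MixtureData:
    """Consumer (mixture) isotope measurements: (N, J) values, per mil."""

    values: np.ndarray
    consumer_ids: tuple[str, ...]

    def __init__(self, values, consumer_ids=None):
        values = np.atleast_2d(np.asarray(values, dtype=float))
        if values.ndim != 2 or values.shape[0] < 1:
            raise ValueError("values must be a non-empty N x J matrix")
        if not np.all(np.isfinite(values)):
            raise ValueError("consumer values contain non-finite entries")
        if consumer_ids is None:
            consumer_ids = tuple(f"consumer_{i + 1}" for i in range(values.shape[0]))
        else:
            consumer_ids = tuple(str(s) for s in consumer_ids)
            if len(consumer_ids) != values.shape[0]:
                raise ValueError("consumer_ids length does not match values")
        values.setflags(write=False)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "consumer_ids", consumer_ids)

    @property
    def n_consumers(self) -> int:
        return self.values.shape[0]

    @property
    def n_isotopes(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class ModelSpec:
    """Error parameterization, priors, and the tempering exponent beta.

    ``dirichlet_alpha`` is the concentration vector of the Dirichlet prior on
    the proportions (flat by default).  Nuisance scales get Uniform(0,
    ``scale_prior_upper``) priors: residual SDs eps_j under ``siar_residual``
    (per mil), multiplicative variance factors xi_j under
    ``stock_multiplicative`` (dimensionless).
    """

    error_model: str = "siar_residual"
    dirichlet_alpha: np.ndarray | None = None
    scale_prior_upper: float = 20.0
    beta: float = 1.0

    def __post_init__(self):
        if self.error_model not in ERROR_MODELS:
            raise ValueError(
                f"error_model must be one of {ERROR_MODELS}, got {self.error_model!r}")
        if not (self.beta > 0 and np.isfinite(self.beta)):
            raise ValueError("beta must be positive and finite")
        if not (self.scale_prior_upper > 0):
            raise ValueError("scale_prior_upper must be positive")
        if self.dirichlet_alpha is not None:
            alpha = np.asarray(self.dirichlet_alpha, dtype=float)
            if alpha.ndim != 1 or np.any(alpha <= 0):
                raise ValueError("dirichlet_alpha must be a 1-D positive vector")
            alpha.setflags(write=False)
            object.__setattr__(self, "dirichlet_alpha", alpha)

    def alpha_for(self, n_sources: int) -> np.ndarray:
        """Resolve the Dirichlet concentration vector for K sources."""
        if self.dirichlet_alpha is None:
            return np.ones(n_sources)
        if len(self.dirichlet_alpha) != n_sources:
            raise ValueError(
                f"dirichlet_alpha has length {len(self.dirichlet_alpha)}, "
                f"expected {n_sources}")
        return self.dirichlet_alpha

    def with_beta(self, beta: float) -> "ModelSpec":
        return ModelSpec(self.error_model, self.dirichlet_alpha,
                         self.scale_prior_upper, beta)


@dataclass(frozen=True)
class ParamState:
    """One point of the parameter space: proportions p and nuisance scales."""

    p: np.ndarray
    scales: np.ndarray

    def __init__(self, p, scales):
        p = np.asarray(p, dtype=float)
        scales = np.atleast_1d(np.asarray(scales, dtype=float))
        if p.ndim != 1 or len(p) < 1:
            raise ValueError("p must be a 1-D vector")
        if np.any(p < 0) or np.any(p > 1):
            raise ValueError("p entries must lie in [0, 1]")
        if abs(p.sum() - 1.0) > 1e-12:
            raise ValueError(f"p must sum to 1 (got {p.sum()!r})")
        if np.any(scales <= 0) or not np.all(np.isfinite(scales)):
            raise ValueError("scales must be positive and finite")
        p.setflags(write=False)
        scales.setflags(write=False)
        object.__setattr__(self, "p", p)
        object.__setattr__(self, "scales", scales)


def _check_shapes(state: ParamState, data: MixtureData, space: MixingSpace) -> None:
    if len(state.p) != space.n_sources:
        raise ValueError("state.p length does not match number of sources")
    if len(state.scales) != space.n_isotopes:
        raise ValueError("state.scales length does not match number of isotopes")
    if data.n_isotopes != space.n_isotopes:
        raise ValueError("consumer data and mixing space disagree on isotopes")


def _normal_logpdf_sum(data: MixtureData, mean: np.ndarray, var: np.ndarray,
                       space: MixingSpace) -> float:
    bad = np.flatnonzero(var <= 0)
    if bad.size:
        iso = space.isotope_names[bad[0]]
        raise DegenerateVarianceError(
            f"model variance is non-positive on isotope {iso!r}; "
            "all SDs are zero and the error term cannot absorb it")
    resid2 = (data.values - mean) ** 2
    return float(-0.5 * np.sum(np.log(2.0 * np.pi * var) + resid2 / var))


def marginal_loglik_siar(state: ParamState, data: MixtureData,
                         space: MixingSpace) -> float:
    """Marginalized log-likelihood with additive residual SDs eps_j.

    Each observation on isotope j is normal with mean
    ``sum_k p_k (source_mean + tef_mean)_kj`` and variance
    ``sum_k p_k^2 (source_sd^2 + tef_sd^2)_kj + eps_j^2``.
    """
    _check_shapes(state, data, space)
    mean = state.p @ space.corrected_mean
    var = (state.p**2) @ space.pooled_var + state.scales**2
    return _normal_logpdf_sum(data, mean, var, space)


def marginal_loglik_stock(state: ParamState, data: MixtureData,
                          space: MixingSpace) -> float:
    """Marginalized log-likelihood with multiplicative variance factors xi_j.

    Same mean as :func:`marginal_loglik_siar`; the variance is
    ``xi_j * sum_k p_k^2 (source_sd^2 + tef_sd^2)_kj``.  Zero process variance
    cannot be absorbed by the multiplicative factor and is rejected.
    """
    _check_shapes(state, data, space)
    mean = state.p @ space.corrected_mean
    proc = (state.p**2) @ space.pooled_var
    return _normal_logpdf_sum(data, mean, proc * state.scales, space)


def _log_dirichlet(p: np.ndarray, alpha: np.ndarray) -> float:
    if np.any(p <= 0):
        # boundary: density is zero unless flat in that coordinate
        if np.all(alpha[p <= 0] == 1.0):
            p = np.where(p <= 0, 1.0, p)  # (alpha-1) ln p term vanishes
        else:
            return -np.inf
    lognorm = gammaln(alpha.sum()) - gammaln(alpha).sum()
    return float(lognorm + np.sum((alpha - 1.0) * np.log(p)))


def log_prior(state: ParamState, spec: ModelSpec) -> float:
    """Log prior: Dirichlet(alpha) on p, Uniform(0, upper) on each scale."""
    alpha = spec.alpha_for(len(state.p))
    if np.any(state.scales > spec.scale_prior_upper):
        return -np.inf
    return _log_dirichlet(state.p, alpha) \
        - len(state.scales) * np.log(spec.scale_prior_upper)


def log_beta_posterior(state: ParamState, data: MixtureData, space: MixingSpace,
                       spec: ModelSpec) -> float:
    """Unnormalized log of the tempered posterior: beta * (loglik + logprior).

    Both the likelihood and the prior are exponentiated; beta = 1 gives the
    ordinary unnormalized log posterior.
    """
    lp = log_prior(state, spec)
    if lp == -np.inf:
        return -np.inf
    if spec.error_model == "siar_residual":
        ll = marginal_loglik_siar(state, data, space)
    else:
        ll = marginal_loglik_stock(state, data, space)
    return spec.beta * (ll + lp)


# ---------------------------------------------------------------------------
# Vectorized internals used by the samplers (many states at once).

def _loglik_many(P: np.ndarray, S: np.ndarray, data: MixtureData,
                 space: MixingSpace, error_model: str,
                 suffstats=None) -> np.ndarray:
    """Log-likelihood for a batch: P (M, K) proportions, S (M, J) scales."""
    if suffstats is None:
        suffstats = precompute_suffstats(data)
    n, sx, sxx = suffstats
    mean = P @ space.corrected_mean            # (M, J)
    proc = (P**2) @ space.pooled_var           # (M, J)
    if error_model == "siar_residual":
        var = proc + S**2
    else:
        var = proc * S
    ssr = sxx - 2.0 * mean * sx + n * mean**2  # (M, J)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = -0.5 * np.sum(n * np.log(2.0 * np.pi * var) + ssr / var, axis=1)
    out[np.any(var <= 0, axis=1)] = -np.inf
    return out


def precompute_suffstats(data: MixtureData):
    """Per-isotope sufficient statistics (N, sum x, sum x^2) for the normal."""
    x = data.values
    return x.shape[0], x.sum(axis=0), (x**2).sum(axis=0)


def _logprior_many(P: np.ndarray, S: np.ndarray, spec: ModelSpec) -> np.ndarray:
    alpha = spec.alpha_for(P.shape[1])
    lognorm = gammaln(alpha.sum()) - gammaln(alpha).sum() \
        - S.shape[1] * np.log(spec.scale_prior_upper)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = lognorm + ((alpha - 1.0) * np.log(P)).sum(axis=1)
    out[np.any(S > spec.scale_prior_upper, axis=1) | np.any(S <= 0, axis=1)] = -np.inf
    return out
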