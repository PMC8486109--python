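"""MCMC and validation samplers for ordinary and tempered SIMM posteriors.

The working sampler is an adaptive random-walk Metropolis on transformed
coordinates: additive-log-ratio (ALR) for the simplex of proportions and log
for the positive nuisance scales.  The transform keeps the chain away from
boundary pathologies, which matters at large tempering exponents where the
target concentrates on thin ridges.  During warm-up the proposal covariance
is estimated from the pooled chain history and rescaled toward a ~25%
acceptance rate; after warm-up the proposal is frozen so the chain is a
proper Markov chain.

Large tempering exponents (beta ~ 1000) are reached along a geometric ladder
of increasing beta, each rung warm-started from the previous one.  An
importance-resampling route to the same tempered target is provided as an
independent cross-check, and a brute-force simplex-grid oracle serves as
ground truth on small problems.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .model import (
    DegenerateVarianceError,
    MixingSpace,
    MixtureData,
    ModelSpec,
    _loglik_many,
    _logprior_many,
    precompute_suffstats,
)

__all__ = [
    "PosteriorDraws",
    "sample_ordinary",
    "sample_beta",
    "importance_resample",
    "grid_posterior",
    "default_ladder",
]

RHAT_THRESHOLD = 1.05
_TARGET_ACCEPT = 0.25


@dataclass
class PosteriorDraws:
    """Tagged posterior sample: proportions, nuisance scales, and metadata."""

    p_draws: np.ndarray           # (M, K), rows on the simplex
    scale_draws: np.ndarray       # (M, J), positive
    beta: float
    n_chains: int
    seed: int
    source_names: tuple[str, ...]
    scale_names: tuple[str, ...]
    chain_index: np.ndarray       # (M,) which chain each row came from
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.p_draws.ndim != 2 or self.p_draws.shape[0] < 1:
            raise ValueError("p_draws must be a non-empty M x K matrix")
        if np.max(np.abs(self.p_draws.sum(axis=1) - 1.0)) > 1e-9:
            raise ValueError("p_draws rows must lie on the simplex")
        if not self.beta > 0:
            raise ValueError("beta must be positive")

    @property
    def n_draws(self) -> int:
        return self.p_draws.shape[0]

    def marginal(self, source: str) -> np.ndarray:
        """Draws of one source's proportion (fraction in [0, 1])."""
        return self.p_draws[:, self.source_names.index(source)]

    def to_frame(self) -> pd.DataFrame:
        """Flat one-row-per-draw table (sources + scales + chain index)."""
        df = pd.DataFrame(self.p_draws, columns=list(self.source_names))
        for j, nm in enumerate(self.scale_names):
            df[nm] = self.scale_draws[:, j]
        df["chain"] = self.chain_index
        return df


# ---------------------------------------------------------------------------
# coordinate transforms

def _alr(p: np.ndarray) -> np.ndarray:
    """Additive log-ratio transform, last component as reference."""
    return np.log(p[..., :-1]) - np.log(p[..., -1:])


def _alr_inv(y: np.ndarray) -> np.ndarray:
    z = np.concatenate([y, np.zeros(y.shape[:-1] + (1,))], axis=-1)
    z -= z.max(axis=-1, keepdims=True)
    ez = np.exp(z)
    return ez / ez.sum(axis=-1, keepdims=True)


def _make_logpost(data: MixtureData, space: MixingSpace, spec: ModelSpec,
                  beta: float) -> Callable[[np.ndarray], np.ndarray]:
    """Tempered log target on transformed coordinates x = (alr(p), log scales).

    Includes the Jacobians of both transforms (which are *not* tempered:
    tempering acts on the density of (p, scales), the change of variables is
    exact).
    """
    K, J = space.n_sources, space.n_isotopes
    ss = precompute_suffstats(data)
    if spec.error_model == "stock_multiplicative":
        if np.any(np.all(space.pooled_var == 0, axis=0)):
            j = int(np.flatnonzero(np.all(space.pooled_var == 0, axis=0))[0])
            raise DegenerateVarianceError(
                f"isotope {space.isotope_names[j]!r} has zero process variance; "
                "the multiplicative error model cannot absorb it")

    def logpost(x: np.ndarray) -> np.ndarray:
        with np.errstate(over="ignore", divide="ignore", invalid="ignore"):
            P = _alr_inv(x[:, : K - 1])
            S = np.exp(np.minimum(x[:, K - 1:], 350.0))
            ll = _loglik_many(P, S, data, space, spec.error_model, ss)
            lp = _logprior_many(P, S, spec)
            jac = np.log(P).sum(axis=1) + x[:, K - 1:].sum(axis=1)
            out = beta * (ll + lp) + jac
        out[~np.isfinite(out)] = -np.inf
        return out

    return logpost


# ---------------------------------------------------------------------------
# adaptive random-walk Metropolis core

def _rwm(logpost, x0: np.ndarray, n_iter: int, rng: np.random.Generator,
         chol0: np.ndarray, log_step0: float, adapt_frac: float = 0.5,
         collect: bool = True, thin: int = 1):
    """Vectorized-over-chains adaptive RWM.

    Adapts a pooled empirical proposal covariance and a scalar step size
    during the first ``adapt_frac`` of iterations, then freezes the proposal.
    Returns (kept draws (C, m, D), final x, final logpost, final chol,
    final log_step, post-warm-up acceptance rate per chain).
    """
    C, D = x0.shape
    x = x0.copy()
    lp = logpost(x)
    n_warm = int(n_iter * adapt_frac)
    chol = chol0.copy()
    log_step = log_step0
    # pooled running moments for covariance adaptation
    n_acc = 0
    s1 = np.zeros(D)
    s2 = np.zeros((D, D))
    kept = [] if collect else None
    accepted = np.zeros(C)
    n_post = 0
    for it in range(n_iter):
        step = math.exp(log_step)
        prop = x + step * (rng.standard_normal((C, D)) @ chol.T)
        lp_prop = logpost(prop)
        logu = np.log(rng.random(C))
        acc = logu < lp_prop - lp
        x[acc] = prop[acc]
        lp[acc] = lp_prop[acc]
        if it < n_warm:
            rate = acc.mean()
            log_step += min(0.1, 3.0 / math.sqrt(it + 1)) * (rate - _TARGET_ACCEPT)
            n_acc += C
            s1 += x.sum(axis=0)
            s2 += x.T @ x
            if (it + 1) % 200 == 0 and n_acc > 10 * D:
                mean = s1 / n_acc
                cov = s2 / n_acc - np.outer(mean, mean)
                cov += 1e-10 * np.eye(D)
                try:
                    chol = np.linalg.cholesky(cov)
                except np.linalg.LinAlgError:
                    pass
        else:
            accepted += acc
            n_post += 1
            if collect and (it - n_warm) % thin == 0:
                kept.append(x.copy())
    draws = None
    if collect:
        # (m, C, D) -> (C, m, D)
        draws = np.swapaxes(np.array(kept), 0, 1) if kept else \
            np.empty((C, 0, D))
    acc_rate = accepted / max(n_post, 1)
    return draws, x, lp, chol, log_step, acc_rate


def _split_rhat(chains: np.ndarray) -> float:
    """Split-chain potential scale reduction factor for one parameter.

    ``chains`` has shape (C, m); each chain is split in half, giving 2C
    sequences whose between/within variance ratio is summarized.
    """
    import arviz as az

    C, m = chains.shape
    half = m // 2
    if half < 2:
        return np.nan
    split = np.concatenate([chains[:, :half], chains[:, half:2 * half]], axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(az.rhat(split))


def _init_states(space: MixingSpace, spec: ModelSpec, n_chains: int,
                 rng: np.random.Generator) -> np.ndarray:
    K, J = space.n_sources, space.n_isotopes
    alpha = spec.alpha_for(K)
    p0 = rng.dirichlet(np.maximum(alpha, 1.0), size=n_chains)
    p0 = np.clip(p0, 1e-6, None)
    p0 /= p0.sum(axis=1, keepdims=True)
    # moderate starting scales, well inside the prior support
    s0 = spec.scale_prior_upper * rng.uniform(0.02, 0.2, size=(n_chains, J))
    if spec.error_model == "stock_multiplicative":
        s0 = rng.uniform(0.5, 2.0, size=(n_chains, J))
    return np.concatenate([_alr(p0), np.log(s0)], axis=1)


def _scale_names(space: MixingSpace, spec: ModelSpec) -> tuple[str, ...]:
    tag = "eps" if spec.error_model == "siar_residual" else "xi"
    return tuple(f"{tag}_{iso}" for iso in space.isotope_names)


def _finalize(draws_xcd: np.ndarray, beta: float, space: MixingSpace,
              spec: ModelSpec, n_chains: int, seed: int, acc_rate,
              ladder=None, extra_warnings=()) -> PosteriorDraws:
    K = space.n_sources
    C, m, D = draws_xcd.shape
    P = _alr_inv(draws_xcd[:, :, : K - 1])
    S = np.exp(draws_xcd[:, :, K - 1:])
    names = list(space.source_names) + list(_scale_names(space, spec))
    rhat = {}
    for i, nm in enumerate(names):
        series = P[:, :, i] if i < K else S[:, :, i - K]
        rhat[nm] = _split_rhat(series)
    warns = list(extra_warnings)
    bad = [nm for nm, r in rhat.items() if np.isfinite(r) and r > RHAT_THRESHOLD]
    if bad:
        warns.append(
            f"split-chain R-hat above {RHAT_THRESHOLD} for: {', '.join(bad)}; "
            "consider more iterations")
    diag = {
        "rhat": rhat,
        "accept_rate": [float(a) for a in np.atleast_1d(acc_rate)],
        "warnings": warns,
        "ladder": list(ladder) if ladder is not None else None,
    }
    chain_index = np.repeat(np.arange(C), m)
    return PosteriorDraws(
        p_draws=P.reshape(C * m, K),
        scale_draws=S.reshape(C * m, S.shape[2]),
        beta=float(beta), n_chains=n_chains, seed=seed,
        source_names=tuple(space.source_names),
        scale_names=_scale_names(space, spec),
        chain_index=chain_index, diagnostics=diag)


def _proposal_seed(space: MixingSpace, spec: ModelSpec) -> np.ndarray:
    D = space.n_sources - 1 + space.n_isotopes
    return 0.3 * np.eye(D)


def sample_ordinary(data: MixtureData, space: MixingSpace, spec: ModelSpec,
                    n_iter: int = 100_000, n_chains: int = 4, seed: int = 0,
                    n_keep: int = 10_000) -> PosteriorDraws:
    """Sample the ordinary (beta = 1) posterior.

    The first half of each chain is discarded as warm-up (during which the
    proposal adapts); the rest is thinned so at most ``n_keep`` draws are
    retained across chains.  ``spec.beta`` is ignored: the draws target the
    ordinary posterior by construction.
    """
    if n_iter < 1000:
        raise ValueError("n_iter must be at least 1000")
    rng = np.random.default_rng(seed)
    logpost = _make_logpost(data, space, spec, beta=1.0)
    x0 = _init_states(space, spec, n_chains, rng)
    n_post = n_iter - n_iter // 2
    thin = max(1, math.ceil(n_post * n_chains / n_keep))
    draws, *_, acc = _rwm(logpost, x0, n_iter, rng,
                          _proposal_seed(space, spec), 0.0, thin=thin)
    return _finalize(draws, 1.0, space, spec, n_chains, seed, acc)


def default_ladder(beta: float) -> list[float]:
    """Geometric tempering ladder from 1 to beta (about 2 rungs per decade)."""
    if beta <= 1:
        return [float(beta)]
    n = max(2, int(round(2 * math.log10(beta))) + 1)
    return [float(b) for b in np.geomspace(1.0, beta, n)]


def sample_beta(data: MixtureData, space: MixingSpace, spec: ModelSpec,
                n_iter: int = 100_000, n_chains: int = 4, seed: int = 0,
                ladder: Sequence[float] | None = None,
                n_keep: int = 10_000) -> PosteriorDraws:
    """Sample the tempered (beta-dependent) posterior at ``spec.beta``.

    The chain is warm-started along a ladder of increasing beta; only the
    final rung's post-warm-up draws are returned.  Proposal adaptation
    happens during each rung's warm-up only.
    """
    if spec.beta < 1:
        raise ValueError("sample_beta requires spec.beta >= 1")
    if n_iter < 1000:
        raise ValueError("n_iter must be at least 1000")
    if ladder is None:
        ladder = default_ladder(spec.beta)
    ladder = [float(b) for b in ladder]
    if ladder[0] != 1.0 and spec.beta != 1.0:
        raise ValueError("ladder must start at beta = 1")
    if ladder[-1] != spec.beta:
        raise ValueError("ladder must end at spec.beta")
    if any(b2 <= b1 for b1, b2 in zip(ladder, ladder[1:])):
        raise ValueError("ladder must be strictly increasing")

    rng = np.random.default_rng(seed)
    x = _init_states(space, spec, n_chains, rng)
    chol = _proposal_seed(space, spec)
    log_step = 0.0
    n_rung = max(2000, n_iter // 10)
    for b in ladder[:-1]:
        logpost = _make_logpost(data, space, spec, beta=b)
        _, x, _, chol, log_step, _ = _rwm(
            logpost, x, n_rung, rng, chol, log_step, adapt_frac=1.0,
            collect=False)
    logpost = _make_logpost(data, space, spec, beta=ladder[-1])
    n_post = n_iter - n_iter // 2
    thin = max(1, math.ceil(n_post * n_chains / n_keep))
    draws, _, _, _, _, acc = _rwm(logpost, x, n_iter, rng, chol, log_step,
                                  thin=thin)
    if np.mean(acc) < 0.01:
        raise RuntimeError(
            f"acceptance rate collapsed to {np.mean(acc):.2%} at beta = "
            f"{ladder[-1]:g}; use a longer tempering ladder")
    return _finalize(draws, ladder[-1], space, spec, n_chains, seed, acc,
                     ladder=ladder)


def importance_resample(draws: PosteriorDraws, target_beta: float,
                        data: MixtureData, space: MixingSpace, spec: ModelSpec,
                        seed: int = 0) -> PosteriorDraws:
    """Reweight draws from beta to ``target_beta`` and resample.

    Weights are proportional to ``exp((target_beta - beta) * (loglik +
    logprior))``; the importance-sampling effective sample size
    ``(sum w)^2 / sum w^2`` is reported in the diagnostics.  A small ESS
    (< 50) triggers a warning that a staged ladder should be used instead.
    """
    if target_beta < draws.beta:
        raise ValueError("target_beta must be >= the draws' beta")
    ss = precompute_suffstats(data)
    ll = _loglik_many(draws.p_draws, draws.scale_draws, data, space,
                      spec.error_model, ss)
    lp = _logprior_many(draws.p_draws, draws.scale_draws, spec)
    logw = (target_beta - draws.beta) * (ll + lp)
    logw -= logsumexp(logw)
    w = np.exp(logw)
    ess = float(1.0 / np.sum(w**2))
    warns = []
    if ess < 50:
        msg = (f"importance-sampling ESS = {ess:.1f} < 50 when moving beta "
               f"{draws.beta:g} -> {target_beta:g}; use a staged ladder "
               "(smaller beta increments) instead")
        warnings.warn(msg, RuntimeWarning)
        warns.append(msg)
    rng = np.random.default_rng(seed)
    idx = rng.choice(draws.n_draws, size=draws.n_draws, replace=True, p=w)
    diag = {"ess": ess, "warnings": warns, "resampled_from_beta": draws.beta}
    return PosteriorDraws(
        p_draws=draws.p_draws[idx], scale_draws=draws.scale_draws[idx],
        beta=float(target_beta), n_chains=draws.n_chains, seed=seed,
        source_names=draws.source_names, scale_names=draws.scale_names,
        chain_index=draws.chain_index[idx], diagnostics=diag)


# ---------------------------------------------------------------------------
# brute-force grid oracle

def _simplex_grid(K: int, m: int) -> np.ndarray:
    """All points of the simplex lattice {i/m} with K parts summing to m."""
    if K == 1:
        return np.array([[m]])
    out = []
    for i in range(m + 1):
        rest = _simplex_grid(K - 1, m - i)
        out.append(np.concatenate(
            [np.full((rest.shape[0], 1), i), rest], axis=1))
    return np.concatenate(out, axis=0)


def grid_posterior(data: MixtureData, space: MixingSpace, spec: ModelSpec,
                   grid_step: float = 0.01,
                   scales: Sequence[float] | None = None,
                   n_scale_grid: int = 64) -> pd.DataFrame:
    """Brute-force tempered posterior on a regular simplex grid.

    With ``scales`` given, the nuisance scales are held fixed at those values
    and the grid covers the proportions only.  With ``scales=None`` the
    nuisance scales are integrated out numerically on a midpoint grid of
    ``n_scale_grid`` points over their Uniform(0, upper) prior support (only
    practical for one or two isotopes), which makes the result directly
    comparable to the MCMC p-marginals.

    Returns a DataFrame with one simplex point per row (columns = source
    names) and a ``probability`` column summing to one.
    """
    K, J = space.n_sources, space.n_isotopes
    if K > 4:
        raise ValueError("grid oracle supports at most 4 sources")
    if grid_step < 0.01:
        raise ValueError("grid_step must be >= 0.01 (grid size guard)")
    m = int(round(1.0 / grid_step))
    P = _simplex_grid(K, m) / m
    ss = precompute_suffstats(data)
    n, sx, sxx = ss
    mean = P @ space.corrected_mean       # (G, J)
    proc = (P**2) @ space.pooled_var      # (G, J)
    ssr = sxx - 2.0 * mean * sx + n * mean**2

    def iso_term(var_j, ssr_j):
        with np.errstate(divide="ignore", invalid="ignore"):
            t = -0.5 * (n * np.log(2.0 * np.pi * var_j) + ssr_j / var_j)
        return np.where(var_j > 0, t, -np.inf)

    if scales is not None:
        scales = np.asarray(scales, dtype=float)
        if scales.shape != (J,):
            raise ValueError(f"scales must have length {J}")
        if spec.error_model == "siar_residual":
            var = proc + scales**2
        else:
            var = proc * scales
        ll = np.zeros(len(P))
        for j in range(J):
            ll += iso_term(var[:, j], ssr[:, j])
    else:
        if J > 2:
            raise ValueError(
                "numerical scale marginalization supports at most 2 isotopes; "
                "pass fixed scales for larger problems")
        upper = spec.scale_prior_upper
        grid = (np.arange(n_scale_grid) + 0.5) / n_scale_grid * upper
        ll = np.zeros(len(P))
        for j in range(J):
            if spec.error_model == "siar_residual":
                var = proc[:, j, None] + grid[None, :] ** 2
            else:
                var = proc[:, j, None] * grid[None, :]
            t = iso_term(var, ssr[:, j, None])     # (G, n_scale_grid)
            # tempered per-isotope likelihood, marginalized over the scale
            ll += logsumexp(spec.beta * t, axis=1) / spec.beta \
                + np.log(upper / n_scale_grid) / spec.beta

    with np.errstate(divide="ignore", invalid="ignore"):
        lprior = _logprior_many(
            np.clip(P, 1e-300, None), np.full((len(P), J), 1e-6), spec)
    logpost = spec.beta * (ll + lprior)
    logpost[~np.isfinite(logpost)] = -np.inf
    prob = np.exp(logpost - logsumexp(logpost))
    prob /= prob.sum()
    df = pd.DataFrame(P, columns=list(space.source_names))
    df["probability"] = prob
    return df
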