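"""Underdetermination diagnostics and report assembly.

The central diagnostic is the width of the 95% highest-density interval of
each source's proportion under the tempered posterior at large beta (the
"BDP" and its width "delta BDP", in percentage points).  A near-zero width
means the joint posterior peak pins that source's contribution down; a wide
interval means many proportion vectors explain the data equally well.  The
conventional summaries (posterior medians, equal-tailed credible intervals,
and the mean determination coefficient r2 between source marginals) are
assembled alongside it.

Two exact-geometry oracles are provided: the per-source min/max over the
exact-fit mixing polytope (linear programming), and a finite-beta analytic
interval along a one-dimensional exact-fit ridge, which is the theoretical
counterpart of the sampled BDP for a point consumer.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linprog

from .model import MixingSpace
from .samplers import PosteriorDraws

__all__ = [
    "DiagnosticsReport",
    "SourceSummary",
    "hdi",
    "bdp_report",
    "mean_determination",
    "summarize",
    "feasible_range",
    "ridge_bdp_analytic",
    "full_report",
    "FLAG_THRESHOLD",
]

FLAG_THRESHOLD = 10.0  # delta BDP (percentage points) above which a source is flagged


class InsufficientSamplesError(ValueError):
    pass


class UndefinedCorrelationError(ValueError):
    pass


def hdi(samples, mass: float = 0.95) -> tuple[float, float]:
    """Shortest contiguous interval containing ``mass`` of the samples.

    The estimator sorts the samples and slides a window of
    ``ceil(mass * M)`` observations; the shortest window wins, ties broken
    by the earliest (lowest lower endpoint) window.  Both endpoints are
    attained sample values, so the estimator is deterministic and
    shift/scale-equivariant.
    """
    x = np.sort(np.asarray(samples, dtype=float))
    M = len(x)
    if M < 100:
        raise InsufficientSamplesError(
            f"need at least 100 samples for an HDI, got {M}")
    if not 0.0 < mass < 1.0:
        raise ValueError("mass must lie strictly between 0 and 1")
    w = int(np.ceil(mass * M))
    if w >= M:
        return float(x[0]), float(x[-1])
    widths = x[w - 1:] - x[: M - w + 1]
    i = int(np.argmin(widths))  # argmin takes the first minimum: earliest window
    return float(x[i]), float(x[i + w - 1])


def bdp_report(beta_draws: PosteriorDraws, mass: float = 0.95) -> pd.DataFrame:
    """Per-source tempered-posterior HDI (the BDP) and width, in percent."""
    if beta_draws.beta < 500:
        warnings.warn(
            f"BDP requested at beta = {beta_draws.beta:g}; the diagnostic is "
            "meant for large beta (> 500), where it no longer depends much "
            "on beta", RuntimeWarning)
    rows = []
    for k, name in enumerate(beta_draws.source_names):
        lo, hi = hdi(beta_draws.p_draws[:, k], mass)
        rows.append({"source": name, "bdp_lo": 100 * lo, "bdp_hi": 100 * hi,
                     "delta_bdp": 100 * hi - 100 * lo})
    return pd.DataFrame(rows).set_index("source")


def mean_determination(draws: PosteriorDraws) -> pd.Series:
    """Mean determination coefficient r2 per source.

    For source k, the average over the other sources k' of the squared
    Pearson correlation between the posterior draws of p_k and p_k'.  Values
    near one indicate that a source's estimate is (anti)determined by the
    others — a classic, if blunt, underdetermination signal.  Meant for
    ordinary (beta = 1) draws.
    """
    P = draws.p_draws
    K = P.shape[1]
    if K < 2:
        raise ValueError("mean determination needs at least two sources")
    sd = P.std(axis=0)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        raise UndefinedCorrelationError(
            f"source {draws.source_names[dead[0]]!r} has zero-variance draws; "
            "its correlations are undefined")
    r2 = np.corrcoef(P.T) ** 2
    np.fill_diagonal(r2, np.nan)
    vals = np.nanmean(r2, axis=1)
    return pd.Series(vals, index=list(draws.source_names), name="mean_r2")


def summarize(draws: PosteriorDraws, mass: float = 0.95) -> pd.DataFrame:
    """Per-source median and equal-tailed credible interval, in percent."""
    lo_q, hi_q = (1 - mass) / 2, 1 - (1 - mass) / 2
    q = np.quantile(draws.p_draws, [0.5, lo_q, hi_q], axis=0) * 100
    return pd.DataFrame(
        {"median": q[0], "ci_lo": q[1], "ci_hi": q[2]},
        index=list(draws.source_names))


@dataclass(frozen=True)
class FeasibleRange:
    """Per-source min/max proportions over the exact-fit mixing polytope."""

    feasible: bool
    intervals: pd.DataFrame | None  # columns lo, hi (fractions), or None

    def __bool__(self) -> bool:
        return self.feasible


def feasible_range(space: MixingSpace, consumer_point) -> FeasibleRange:
    """Extreme feasible proportions of each source for a point consumer.

    Solves, per source k, min/max p_k subject to p on the simplex and the
    fractionation-corrected mixture mean equalling ``consumer_point`` on
    every isotope.  A consumer outside the mixing polytope yields an
    explicit infeasible result rather than an exception.
    """
    x = np.asarray(consumer_point, dtype=float)
    if x.shape != (space.n_isotopes,):
        raise ValueError(
            f"consumer_point must have {space.n_isotopes} entries")
    K = space.n_sources
    A_eq = np.vstack([space.corrected_mean.T, np.ones(K)])
    b_eq = np.concatenate([x, [1.0]])
    lo = np.empty(K)
    hi = np.empty(K)
    for k in range(K):
        c = np.zeros(K)
        c[k] = 1.0
        for sign, out in ((1.0, lo), (-1.0, hi)):
            res = linprog(sign * c, A_eq=A_eq, b_eq=b_eq, bounds=(0, 1),
                          method="highs")
            if res.status == 2:  # infeasible
                return FeasibleRange(False, None)
            if not res.success:
                raise RuntimeError(f"LP solver failed: {res.message}")
            out[k] = sign * res.fun
    df = pd.DataFrame({"lo": np.clip(lo, 0, 1), "hi": np.clip(hi, 0, 1)},
                      index=list(space.source_names))
    return FeasibleRange(True, df)


def _ridge_segment(space: MixingSpace, x: np.ndarray):
    """Parametrize the exact-fit set {p : simplex, corrected mean = x}.

    Returns (p0, v, t_lo, t_hi) with p(t) = p0 + t v, or None if the set is
    empty or a single point (v = 0).  Only one-dimensional exact-fit sets
    are supported.
    """
    fr = feasible_range(space, x)
    if not fr:
        return None
    A = np.vstack([space.corrected_mean.T, np.ones(space.n_sources)])
    _, s, vt = np.linalg.svd(A)
    tol = max(A.shape) * np.finfo(float).eps * (s[0] if len(s) else 1.0)
    null_dim = space.n_sources - np.sum(s > tol)
    if null_dim == 0:
        p0 = np.linalg.lstsq(A, np.concatenate([x, [1.0]]), rcond=None)[0]
        return p0, np.zeros_like(p0), 0.0, 0.0
    if null_dim > 1:
        raise ValueError(
            "the exact-fit set has dimension > 1; the analytic ridge "
            "interval supports only one-dimensional ridges")
    v = vt[-1]
    p0 = np.linalg.lstsq(A, np.concatenate([x, [1.0]]), rcond=None)[0]
    # bounds 0 <= p0 + t v <= 1 per coordinate
    t_lo, t_hi = -np.inf, np.inf
    for k in range(len(v)):
        if abs(v[k]) < 1e-14:
            continue
        a = (0.0 - p0[k]) / v[k]
        b = (1.0 - p0[k]) / v[k]
        t_lo = max(t_lo, min(a, b))
        t_hi = min(t_hi, max(a, b))
    return p0, v, t_lo, t_hi


def ridge_bdp_analytic(space: MixingSpace, consumer_point, beta: float,
                       mass: float = 0.95, n_grid: int = 40001) -> pd.DataFrame:
    """Finite-beta analytic BDP along a one-dimensional exact-fit ridge.

    For a single consumer exactly inside the mixing polytope, with the
    residual-error model and flat priors, integrating the tempered posterior
    over the residual scales and (by Laplace approximation) over the
    directions transverse to the ridge leaves a one-dimensional density
    along the ridge proportional to

        prod_j s_j(t) ** ((2 - beta) / 2),   s_j(t) = sum_k p_k(t)^2 w_kj,

    where ``w_kj`` is the pooled process variance (source SD^2 + TEF SD^2)
    of source k on isotope j.  The density is evaluated on a fine grid of
    the ridge parameter and the highest-density ``mass`` interval mapped to
    each source's proportion.  This is the theoretical value the sampled
    BDP should approach for a point consumer.
    """
    x = np.asarray(consumer_point, dtype=float)
    seg = _ridge_segment(space, x)
    if seg is None:
        raise ValueError("consumer point is outside the mixing polytope")
    p0, v, t_lo, t_hi = seg
    names = list(space.source_names)
    if np.allclose(v, 0) or t_hi - t_lo < 1e-12:
        p = np.clip(p0, 0, 1)
        return pd.DataFrame({"bdp_lo": 100 * p, "bdp_hi": 100 * p,
                             "delta_bdp": np.zeros_like(p)}, index=names)
    w = space.pooled_var
    if np.any(np.all(w == 0, axis=0)):
        raise ValueError("analytic ridge interval needs nonzero process "
                         "variance on every isotope")
    t = np.linspace(t_lo, t_hi, n_grid)
    P = p0[None, :] + t[:, None] * v[None, :]      # (G, K)
    s = np.clip(P, 0, None) ** 2 @ w               # (G, J)
    with np.errstate(divide="ignore"):
        logf = ((2.0 - beta) / 2.0) * np.log(s).sum(axis=1)
    logf -= logf.max()
    f = np.exp(logf)
    f /= f.sum()
    # discrete HDI on the grid: smallest set of consecutive cells with >= mass
    order = np.argsort(f)[::-1]
    csum = np.cumsum(f[order])
    n_in = int(np.searchsorted(csum, mass) + 1)
    members = np.sort(order[:n_in])
    t_sel = t[members]
    rows = {}
    for k, name in enumerate(names):
        pk = np.clip(p0[k] + t_sel * v[k], 0, 1)
        rows[name] = (100 * pk.min(), 100 * pk.max())
    df = pd.DataFrame.from_dict(rows, orient="index",
                                columns=["bdp_lo", "bdp_hi"])
    df["delta_bdp"] = df["bdp_hi"] - df["bdp_lo"]
    return df


@dataclass
class SourceSummary:
    source: str
    median: float
    ci: tuple[float, float]
    mean_r2: float
    bdp: tuple[float, float]
    delta_bdp: float
    flagged: bool


@dataclass
class DiagnosticsReport:
    """Machine-readable per-source summary table plus run metadata."""

    sources: list[SourceSummary]
    meta: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "sources": [
                {"source": s.source, "median": s.median,
                 "ci": list(s.ci), "mean_r2": s.mean_r2,
                 "bdp": list(s.bdp), "delta_bdp": s.delta_bdp,
                 "flagged": s.flagged}
                for s in self.sources
            ],
            "meta": self.meta,
        }

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent, sort_keys=True)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"median": [s.median for s in self.sources],
             "ci_lo": [s.ci[0] for s in self.sources],
             "ci_hi": [s.ci[1] for s in self.sources],
             "mean_r2": [s.mean_r2 for s in self.sources],
             "bdp_lo": [s.bdp[0] for s in self.sources],
             "bdp_hi": [s.bdp[1] for s in self.sources],
             "delta_bdp": [s.delta_bdp for s in self.sources],
             "flagged": [s.flagged for s in self.sources]},
            index=[s.source for s in self.sources])

    def to_text(self) -> str:
        """Rendered table: medians, 95% CI, mean r2, BDP, delta BDP."""
        lines = [f"{'source':<22}{'median':>8}  {'95% CI':>14}  "
                 f"{'r2':>6}  {'BDP':>14}  {'dBDP':>6}"]
        for s in self.sources:
            flag = " *" if s.flagged else ""
            lines.append(
                f"{s.source:<22}{s.median:>8.1f}  "
                f"[{s.ci[0]:>5.1f},{s.ci[1]:>6.1f}]  {s.mean_r2:>6.3f}  "
                f"[{s.bdp[0]:>5.1f},{s.bdp[1]:>6.1f}]  {s.delta_bdp:>6.1f}"
                f"{flag}")
        if any(s.flagged for s in self.sources):
            lines.append("* delta BDP >= 10 percentage points: seriously "
                         "underdetermined; consider more isotope elements")
        return "\n".join(lines)


def full_report(ordinary: PosteriorDraws, tempered: PosteriorDraws,
                mass: float = 0.95) -> DiagnosticsReport:
    """Assemble the standard report from ordinary and tempered draws.

    Medians, credible intervals and mean determination coefficients come
    from the ordinary (beta = 1) draws; the BDP and its width come from the
    tempered draws.  Sources whose delta BDP reaches 10 percentage points
    are flagged as seriously underdetermined.
    """
    if ordinary.source_names != tempered.source_names:
        raise ValueError("ordinary and tempered draws disagree on sources")
    if ordinary.beta != 1.0:
        raise ValueError("the 'ordinary' draws must target beta = 1")
    summ = summarize(ordinary, mass)
    r2 = mean_determination(ordinary)
    bdp = bdp_report(tempered, mass)
    sources = []
    for name in ordinary.source_names:
        delta = float(bdp.loc[name, "delta_bdp"])
        sources.append(SourceSummary(
            source=name,
            median=float(summ.loc[name, "median"]),
            ci=(float(summ.loc[name, "ci_lo"]), float(summ.loc[name, "ci_hi"])),
            mean_r2=float(r2[name]),
            bdp=(float(bdp.loc[name, "bdp_lo"]), float(bdp.loc[name, "bdp_hi"])),
            delta_bdp=delta,
            flagged=delta >= FLAG_THRESHOLD))
    meta = {
        "beta": tempered.beta,
        "hdi_mass": mass,
        "ordinary_draws": ordinary.n_draws,
        "tempered_draws": tempered.n_draws,
        "ordinary_seed": ordinary.seed,
        "tempered_seed": tempered.seed,
        "n_chains": ordinary.n_chains,
    }
    return DiagnosticsReport(sources=sources, meta=meta)
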