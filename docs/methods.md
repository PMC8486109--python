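# Methods

## Model

A stable isotope mixing model infers the proportions **p** = (p₁, …, p_K) of
K sources in a consumer's diet from J isotope ratios. The likelihood is the
source/TEF-marginalized normal form: consumer value x_ij on isotope j is

    x_ij ~ N( Σ_k p_k (μ_kj + c_kj),  v_j(p) )

with μ the source means, c the trophic-enrichment (TEF) means, and a
variance that folds the source and TEF variances into the observation:

- additive-residual parameterization (`siar_residual`):
  v_j = Σ_k p_k² (ω_kj² + τ_kj²) + ε_j²
- multiplicative parameterization (`stock_multiplicative`):
  v_j = ξ_j · Σ_k p_k² (ω_kj² + τ_kj²)

ω and τ are the source and TEF standard deviations; ε_j (per mil) and ξ_j
(dimensionless) are per-isotope nuisance scales. The marginalized form is
used, rather than latent per-source draws, because it makes the
β-exponentiation below unambiguous.

Priors: Dirichlet(α) on **p** with α = (1, …, 1) by default, and
Uniform(0, `scale_prior_upper`) on every nuisance scale with default 20
(per mil for ε, unitless for ξ) — the vague defaults of the mainstream SIMM
ecosystem. Nuisance scales are part of θ and are therefore tempered along
with everything else.

## The β-dependent posterior

The underdetermination diagnostic samples

    p_β(θ | X) ∝ [ p(X | θ) π(θ) ]^β ,

the ordinary posterior raised to a power β (default 1000) and renormalized.
As β grows, mass concentrates on the set of joint posterior peaks; the 95%
highest-density interval of each source's marginal under p_β (the BDP) and
its width in percentage points (ΔBDP) measure how large that peak set is in
each coordinate. ΔBDP ≈ 0 means the joint peak pins the contribution down;
ΔBDP ≥ 10 points is flagged as serious underdetermination. Both likelihood
and prior are exponentiated; the change-of-variables Jacobians used by the
sampler are not (they are part of the parametrization, not the density
being tempered).

Two analytic companions exist for point consumers:

- `feasible_range`: per-source min/max of p_k over the exact-fit polytope
  {p on the simplex : Σ_k p_k (μ + c)_kj = x_j ∀j}, solved by linear
  programming (HiGHS). This is the geometric identifiability bound and does
  not depend on β.
- `ridge_bdp_analytic`: for a one-dimensional exact-fit ridge, integrating
  p_β over the residual scales and (by Laplace approximation) over the
  directions transverse to the ridge leaves the one-dimensional density
  f(t) ∝ Π_j s_j(t)^((2−β)/2) with s_j(t) = Σ_k p_k(t)² (ω² + τ²)_kj. The
  95% HDI of this density, mapped through the linear ridge parametrization,
  is the theoretical value the sampled BDP approaches for a point consumer.

Two limits deserve care, because they do not commute:

- **β → ∞ at fixed SDs.** The BDP does *not* converge to the feasible
  polytope range: the variance term Σ p_k² varies along the ridge, so p_β
  keeps concentrating toward the minimum-variance point and ΔBDP shrinks
  like β^(−1/2) (on the centroid toy: 3.1, 2.2, 1.6 points at β = 500,
  1000, 2000). β = 1000 is therefore a convention, not an asymptote; the
  same β should be used when comparing ΔBDPs across analyses.
- **SDs → 0 at fixed β.** With all process SDs exactly zero and free
  residual scales, the tempered density on an exact-fit ridge scales as
  Π_j ε_j^(1−β), which is not integrable at ε = 0 for β ≥ 2: the tempered
  posterior is improper and chains stall in the ε → 0 funnel. The same
  applies to the multiplicative model whenever a consumer sits exactly on
  the ridge (weight ∝ ξ^(−β/2)). Zero-SD geometries are fine for the LP
  oracle but not for tempered sampling; the multiplicative error model is
  intended for data with residual scatter.

## Sampler

Adaptive random-walk Metropolis on transformed coordinates: additive
log-ratio for the simplex, log for the positive scales (D = K−1+J
dimensions), which keeps the chain off the boundaries that large β makes
pathological. During warm-up (the first half of each chain) the proposal
covariance is re-estimated every 200 iterations from the pooled chain
history and a global step size is tuned toward ~25% acceptance; after
warm-up the proposal is frozen so the retained draws come from a proper
Markov chain. Four chains by default, vectorized jointly; draws are thinned
to a requested retention budget (default 10 000 across chains).

Large β is reached along a geometric ladder (about two rungs per decade,
e.g. 1, 3.16, 10, …, 1000), each rung warm-started from the last with a
short adaptation run (max(2000, n_iter/10) iterations); only the final
rung's post-warm-up draws are kept. An acceptance rate below 1% at the
final rung raises an error advising a longer ladder. Split-chain R̂ is
computed per parameter (via ArviZ) and reported — above 1.05 it is recorded
as a warning, not a failure, so exploratory runs still return their draws.

`importance_resample` provides the second route to a tempered target:
reweight existing draws by exp((β′−β)(log L + log π)) and resample. It is
trustworthy only for moderate β gaps from already-concentrated draws (the
importance-sampling ESS is reported; below 50 it warns to use a staged
ladder). Resampling a β = 1 sample all the way to β = 1000, even in stages,
degenerates to a handful of atoms because the ordinary draws never cover
the tempered typical set — this is a property of sampling-importance-
resampling without rejuvenation, not a tuning issue. The route-agreement
check in the test suite therefore resamples β = 250 MCMC draws to β = 1000,
where both routes agree to within a tenth of a percentage point.

`grid_posterior` is the brute-force oracle: it enumerates the simplex
lattice (K ≤ 4, step ≥ 0.01), evaluates the tempered density at every
point, and either holds the nuisance scales fixed or integrates them out on
a midpoint grid over their prior support (J ≤ 2). The scale-marginalized
mode is what the MCMC marginals are validated against (total-variation
distance < 0.05 on three-source toys).

## Conventional summaries

Alongside the BDP the package reports, from ordinary (β = 1) draws:
posterior medians and equal-tailed 95% credible intervals (the conventional
report; the BDP alone is an HDI, matching its definition), and the mean
determination coefficient r̄² — for source k the average over k′ ≠ k of the
squared Pearson correlation between the p_k and p_k′ draws. The pairwise
reading is used because a multiple-regression R² of one proportion on all
the others is identically 1 under the simplex constraint, which would make
the statistic useless; with K = 2 it is identically 1 anyway, and for flat
Dirichlet draws it is 1/(K−1)² (1/9 at K = 4).

The HDI estimator is the shortest contiguous window over sorted samples
(⌈0.95·M⌉ observations, ties broken by the earliest window), requiring at
least 100 samples; it is deterministic and shift/scale-equivariant.

## Synthetic fixtures and what they show

`make_centroid_toy` builds the canonical underdetermined geometry: K
sources (default 4) at equal angles on a circle of radius `spread`
(default 10‰) in a two-isotope plane, common source SD 1‰, zero TEFs, one
consumer exactly at the centroid of the corrected means. The defaults were
fixed once, from the published figure of this geometry (small SD bars
relative to the source spread, a single consumer); every parameter is
overridable. `make_collinear_space` places sources on a line — the other
classic degenerate geometry — and `simulate_consumers` draws consumers from
the marginalized generative model for parameter-recovery tests.

What passing tests on these fixtures do **not** show: the toys have exact
centroid/collinear symmetry, a single point consumer (mostly), and normal
errors matched to the fitted model, so they exercise the geometry of
underdetermination, not robustness to model misspecification, outliers,
isotopic covariance, or concentration dependence (all out of scope). The
ordinary-posterior summary values (medians, CI, r̄²) on the centroid toy
are sensitive to the ratio of source spread to the residual-scale prior
bound — a diffuse large-ε component flattens the likelihood and dilutes
r̄² — so those numbers characterize this configuration, not underdetermined
systems in general. The BDP at large β is insensitive to that prior bound
(the tempered posterior drives ε → 0), which is rather the point of the
diagnostic.

## Numerical choices

- Proportions live in [0, 1] internally; all reports convert to percent and
  round only at presentation (one decimal in rendered tables, full
  precision in JSON).
- Simplex closure is enforced to 1e-9 on emitted draws; LP equality
  feasibility uses the HiGHS defaults (~1e-9).
- The analytic ridge interval uses a 40 001-point grid along the ridge and
  a greedy highest-density cell selection; the ridge direction comes from
  the SVD null space of the stacked mean/sum constraints and endpoint
  vertices from the LP.
- Problem sizes in the shipped tests and acceptance script (30 000–80 000
  iterations, 4 chains, 40 000–60 000 retained draws) were chosen so HDI
  endpoints are stable to well under half a percentage point on the toys.
- Degenerate inputs fail loudly: non-positive model variance names the
  offending isotope; zero-variance marginals make r̄² an explicit error;
  a consumer outside the mixing polytope is an explicit infeasible result,
  not an exception.

## Known limitations

- Per-consumer proportion vectors, hierarchical structures, concentration
  dependence and isotopic covariance between elements are not modelled.
- The sampler is random-walk Metropolis: adequate for the K ≤ 6, J ≤ 3
  problems SIMMs usually pose, but slow mixing is possible on long flat
  ridges (watch the reported R̂; raise iterations or chains).
- Informative-prior elicitation is left to the user: the diagnostic tells
  you *that* the data cannot identify a contribution, not which external
  information would.
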