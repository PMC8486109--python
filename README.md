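# betasimm

Bayesian stable isotope mixing models (SIMMs) with a tempered-posterior
diagnostic for **underdetermination** — the situation where many different
source-contribution vectors explain the same consumer isotope data equally
well, so the usual posterior medians and credible intervals quietly stop
meaning what they appear to mean.

The package is for ecologists (and geochemists, archaeologists, …) who fit
SIMMs to estimate the proportional contributions *p₁, …, p_K* of *K* food
sources to a consumer from *J* isotope ratios, and who want a quantitative
answer to "is this system actually identified?" before reporting or re-using
point estimates.

## The model and the diagnostic

Consumer value *x_ij* on isotope *j* is modelled as normal with

- mean  Σₖ pₖ (μₖⱼ + cₖⱼ)  — source means μ plus trophic-enrichment (TEF)
  means c,
- variance  Σₖ pₖ² (ωₖⱼ² + τₖⱼ²) + εⱼ²  — source and TEF variances, plus an
  additive residual εⱼ (the SIAR-style parameterization), or alternatively
  ξⱼ · Σₖ pₖ² (ωₖⱼ² + τₖⱼ²) with a multiplicative factor ξⱼ (Stock-style).

With a Dirichlet(1,…,1) prior on **p** and Uniform(0, 20‰) priors on the
nuisance scales, the ordinary posterior is p(θ|X) ∝ p(X|θ) π(θ). The
diagnostic samples, in addition, the **β-dependent posterior**

  p_β(θ|X) ∝ p(X|θ)^β π(θ)^β,   β ≫ 1 (default 1000),

which concentrates on the set of joint posterior peaks. For each source, the
95% highest-density interval of its marginal under p_β is the **BDP**, and
its width in percentage points is **ΔBDP**: near zero when the contribution
is pinned down by the joint peak, wide when an exact-fit ridge of
alternative diets survives tempering. ΔBDP ≥ 10 points flags serious
underdetermination. Exact-geometry companions are provided: the per-source
min/max over the mixing polytope (linear programming) and a finite-β
analytic interval along one-dimensional exact-fit ridges.

## Worked example

The bundled "centroid toy" places four sources at (±10‰, 0) and (0, ±10‰)
in a two-isotope plane (SD 1‰ each, zero TEF) and one consumer exactly at
their centroid — the canonical underdetermined geometry: any mixture with
p_A = p_C, p_B = p_D, p_A + p_B = ½ fits the consumer exactly.

```python
import betasimm as bs

space, data = bs.make_centroid_toy()
spec = bs.ModelSpec()

# exact geometry: each source's feasible range over the mixing polytope
print(bs.feasible_range(space, data.values[0]).intervals)
#            lo   hi
# Source A  0.0  0.5   (… identical for B, C, D)

# finite-beta analytic interval along the exact-fit ridge
print(bs.ridge_bdp_analytic(space, data.values[0], beta=1000.0).round(2))
#           bdp_lo  bdp_hi  delta_bdp
# Source A    23.9    26.1       2.19  (…)

ordinary = bs.sample_ordinary(data, space, spec, n_iter=60_000, seed=1)
tempered = bs.sample_beta(data, space, spec.with_beta(1000.0),
                          n_iter=30_000, seed=2)
print(bs.full_report(ordinary, tempered).to_text())
```

which prints (one run, seed as shown):

```
source                  median          95% CI      r2             BDP    dBDP
Source A                  21.4  [  1.1,  67.8]   0.127  [ 24.0,  26.1]     2.2
Source B                  22.1  [  0.9,  67.0]   0.129  [ 23.9,  26.1]     2.1
Source C                  22.0  [  1.0,  67.6]   0.131  [ 24.0,  26.2]     2.2
Source D                  22.3  [  1.3,  66.7]   0.126  [ 23.8,  26.0]     2.2
```

Reading: the ordinary posterior is wide (each source could be 1–68% of the
diet) yet the BDP is a narrow band around 25% — every joint posterior peak
sits near the symmetric diet, and the width that remains (ΔBDP ≈ 2.2
points) quantifies the residual underdetermination of the exact-fit ridge.
No source is flagged (all ΔBDP < 10).

The same pipeline runs from the shell on CSV inputs
(`source, mean_d13C, sd_d13C, …` for sources and TEFs; one isotope column
per consumer row for mixtures):

```
betasimm simulate --out fixtures/
betasimm run --mixtures fixtures/mixtures.csv --sources fixtures/sources.csv \
             --tefs fixtures/tefs.csv --beta 1000 --seed 1 --out results/
betasimm oracle --mixtures fixtures/mixtures.csv --sources fixtures/sources.csv
```

`run` writes `report.json` (machine-readable report) and `run_log.json`
(seed, tempering ladder, acceptance rates, split-chain R̂ — everything
needed to reproduce the run). Published field datasets (e.g. the Brent
geese data often used to benchmark SIMMs) can be analysed by exporting
their consumer/source/TEF tables to the CSV layout above; no external data
ships with the package.

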