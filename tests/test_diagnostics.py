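"""HDI, summaries, determination coefficients, and geometry oracles."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

import betasimm as bs
from betasimm.diagnostics import (FLAG_THRESHOLD, InsufficientSamplesError,
                                  UndefinedCorrelationError)
from tests.conftest import make_draws


class TestHdi:
    def test_degenerate_distribution_zero_width(self):
        lo, hi = bs.hdi(np.full(200, 3.7))
        assert (lo, hi) == (3.7, 3.7)

    def test_uniform_grid_window(self):
        x = np.linspace(0, 1, 10_000)
        lo, hi = bs.hdi(x, 0.95)
        assert hi - lo == pytest.approx(0.95, abs=1.5e-4)

    def test_normal_draws_match_closed_form_quantiles(self):
        rng = np.random.default_rng(1)
        lo, hi = bs.hdi(rng.standard_normal(1_000_000), 0.95)
        assert lo == pytest.approx(-1.96, abs=0.02)
        assert hi == pytest.approx(1.96, abs=0.02)

    def test_too_few_samples_rejected(self):
        with pytest.raises(InsufficientSamplesError):
            bs.hdi(np.arange(99))

    @given(samples=hnp.arrays(np.float64, st.integers(100, 400),
                              elements=st.floats(-50, 50)),
           a=st.floats(0.1, 10), b=st.floats(-5, 5))
    def test_shift_scale_equivariance(self, samples, a, b):
        lo, hi = bs.hdi(samples)
        lo2, hi2 = bs.hdi(a * samples + b)
        assert lo2 == pytest.approx(a * lo + b, rel=1e-9, abs=1e-9)
        assert hi2 == pytest.approx(a * hi + b, rel=1e-9, abs=1e-9)

    @given(samples=hnp.arrays(np.float64, st.integers(100, 400),
                              elements=st.floats(-50, 50)),
           mass=st.floats(0.5, 0.99))
    def test_endpoints_are_attained_and_ordered(self, samples, mass):
        lo, hi = bs.hdi(samples, mass)
        assert lo <= hi
        assert lo in samples and hi in samples


class TestBdpReport:
    def test_point_mass_draws_zero_width(self):
        p = np.tile([0.2, 0.3, 0.5], (500, 1))
        rep = bs.bdp_report(make_draws(p, beta=1000.0))
        assert np.allclose(rep["delta_bdp"], 0.0)
        assert np.allclose(rep["bdp_lo"], [20, 30, 50])

    def test_intervals_inside_percent_bounds(self, toy4_beta1000):
        rep = bs.bdp_report(toy4_beta1000)
        assert (rep["bdp_lo"] >= 0).all() and (rep["bdp_hi"] <= 100).all()
        assert np.allclose(rep["delta_bdp"],
                           rep["bdp_hi"] - rep["bdp_lo"])

    def test_low_beta_warns(self):
        rng = np.random.default_rng(0)
        p1 = rng.uniform(0, 1, 300)
        with pytest.warns(RuntimeWarning, match="beta"):
            bs.bdp_report(make_draws(np.column_stack([p1, 1 - p1]), beta=10.0))


class TestMeanDetermination:
    def test_two_sources_perfectly_anticorrelated(self):
        rng = np.random.default_rng(2)
        p1 = rng.uniform(0, 1, 1000)
        r2 = bs.mean_determination(make_draws(np.column_stack([p1, 1 - p1])))
        assert np.allclose(r2, 1.0)

    def test_symmetric_dirichlet_one_ninth(self):
        # pairwise correlation of Dirichlet(1,1,1,1) components is -1/3
        rng = np.random.default_rng(3)
        p = rng.dirichlet(np.ones(4), size=200_000)
        r2 = bs.mean_determination(make_draws(p))
        assert np.allclose(r2, 1.0 / 9.0, atol=0.01)

    def test_zero_variance_marginal_rejected(self):
        p = np.tile([0.25, 0.25, 0.25, 0.25], (500, 1))
        with pytest.raises(UndefinedCorrelationError, match="A"):
            bs.mean_determination(make_draws(p))

    def test_values_in_unit_interval(self, toy4_ordinary):
        r2 = bs.mean_determination(toy4_ordinary)
        assert ((r2 >= 0) & (r2 <= 1)).all()


class TestSummarize:
    def test_constant_draws(self):
        p = np.tile([0.2, 0.8], (500, 1))
        s = bs.summarize(make_draws(p))
        assert np.allclose(s["median"], [20, 80])
        assert np.allclose(s["ci_lo"], s["ci_hi"])

    def test_uniform_marginal_quantiles(self):
        rng = np.random.default_rng(4)
        p1 = rng.uniform(0, 1, 100_000)
        s = bs.summarize(make_draws(np.column_stack([p1, 1 - p1])))
        assert s.loc["A", "median"] == pytest.approx(50, abs=0.5)
        assert s.loc["A", "ci_lo"] == pytest.approx(2.5, abs=0.3)
        assert s.loc["A", "ci_hi"] == pytest.approx(97.5, abs=0.3)


class TestFeasibleRange:
    def test_square_geometry_exact(self):
        space = bs.MixingSpace(["A", "B", "C", "D"], ["x", "y"],
                               [[-1, 1], [1, 1], [1, -1], [-1, -1]],
                               np.zeros((4, 2)))
        fr = bs.feasible_range(space, [0.0, 0.0])
        assert fr.feasible
        assert np.allclose(fr.intervals["lo"], 0.0, atol=1e-9)
        assert np.allclose(fr.intervals["hi"], 0.5, atol=1e-9)

    def test_vertex_consumer_unique_solution(self, triangle):
        fr = bs.feasible_range(triangle, triangle.corrected_mean[1])
        assert np.allclose(fr.intervals.loc["B"], [1.0, 1.0], atol=1e-9)
        assert np.allclose(fr.intervals.loc["A"], [0.0, 0.0], atol=1e-9)
        assert np.allclose(fr.intervals.loc["C"], [0.0, 0.0], atol=1e-9)

    def test_outside_polytope_is_explicit_not_exception(self, triangle):
        fr = bs.feasible_range(triangle, [100.0, 100.0])
        assert not fr.feasible and fr.intervals is None

    def test_interior_consumer_of_triangle_is_identified(self, triangle):
        fr = bs.feasible_range(triangle, [3.0, 2.0])
        width = fr.intervals["hi"] - fr.intervals["lo"]
        assert np.all(width < 1e-9)

    def test_collinear_middle_source_fully_undetermined(self):
        space = bs.make_collinear_space(3, seed=5)
        fr = bs.feasible_range(space, space.corrected_mean[1])
        assert np.allclose(fr.intervals.iloc[1], [0.0, 1.0], atol=1e-9)
        assert np.allclose(fr.intervals.iloc[0], [0.0, 0.5], atol=1e-9)
        assert np.allclose(fr.intervals.iloc[2], [0.0, 0.5], atol=1e-9)


class TestRidgeAnalytic:
    def test_centroid_toy_interval(self, toy4):
        space, data = toy4
        df = bs.ridge_bdp_analytic(space, data.values[0], beta=1000.0)
        # frozen from the closed-form ridge density s(t)^(2-beta) on this
        # symmetric geometry (Gaussian curvature check: sd = 1/sqrt(32*998))
        assert np.allclose(df["bdp_lo"], 23.90, atol=0.05)
        assert np.allclose(df["bdp_hi"], 26.10, atol=0.05)

    def test_analytic_interval_inside_feasible_range(self, toy4):
        space, data = toy4
        df = bs.ridge_bdp_analytic(space, data.values[0], beta=1000.0)
        fr = bs.feasible_range(space, data.values[0]).intervals
        assert (df["bdp_lo"] / 100 >= fr["lo"] - 1e-9).all()
        assert (df["bdp_hi"] / 100 <= fr["hi"] + 1e-9).all()

    def test_identified_point_zero_width(self, triangle):
        df = bs.ridge_bdp_analytic(triangle, [3.0, 2.0], beta=1000.0)
        assert np.allclose(df["delta_bdp"], 0.0, atol=1e-6)

    def test_width_shrinks_with_beta(self, toy4):
        space, data = toy4
        widths = [bs.ridge_bdp_analytic(space, data.values[0],
                                        beta=b)["delta_bdp"].iloc[0]
                  for b in (100.0, 1000.0, 10_000.0)]
        assert widths[0] > widths[1] > widths[2]


class TestFullReport:
    def test_toy_report_assembles_and_no_flags(self, toy4_ordinary,
                                               toy4_beta1000):
        rep = bs.full_report(toy4_ordinary, toy4_beta1000)
        assert len(rep.sources) == 4
        frame = rep.to_frame()
        assert not frame["flagged"].any()
        assert np.allclose(frame["delta_bdp"],
                           frame["bdp_hi"] - frame["bdp_lo"])
        text = rep.to_text()
        assert "Source A" in text and "BDP" in text

    def test_wide_bdp_flagged_narrow_not(self):
        rng = np.random.default_rng(6)
        # source A spans [29.1, 38.3]% (width 9.2 -> unflagged);
        # source B spans ~[0, 40]% (width >= 10 -> flagged)
        a = rng.uniform(0.291, 0.383, 5000)
        b = rng.uniform(0.0, 0.40, 5000)
        rest = 1 - a - b
        tempered = make_draws(np.column_stack([a, b, rest]), beta=1000.0)
        ordinary = make_draws(
            rng.dirichlet(np.ones(3), 5000), beta=1.0)
        rep = bs.full_report(ordinary, tempered)
        frame = rep.to_frame()
        assert frame.loc["A", "delta_bdp"] < FLAG_THRESHOLD
        assert not frame.loc["A", "flagged"]
        assert frame.loc["B", "flagged"]

    def test_point_mass_zero_width_everywhere(self):
        p = np.tile([0.1, 0.9], (500, 1)) + 0.0
        p[::2] += 1e-9  # avoid zero-variance correlation failure
        p /= p.sum(axis=1, keepdims=True)
        d1 = make_draws(p, beta=1.0)
        d2 = make_draws(p, beta=1000.0)
        rep = bs.full_report(d1, d2).to_frame()
        assert np.allclose(rep["delta_bdp"], 0.0, atol=1e-5)
        assert np.allclose(rep["ci_hi"] - rep["ci_lo"], 0.0, atol=1e-5)

    def test_mismatched_sources_rejected(self, toy4_ordinary):
        rng = np.random.default_rng(7)
        other = make_draws(rng.dirichlet(np.ones(3), 500), beta=1000.0)
        with pytest.raises(ValueError):
            bs.full_report(toy4_ordinary, other)

    def test_nonunit_ordinary_beta_rejected(self, toy4_beta1000):
        with pytest.raises(ValueError):
            bs.full_report(toy4_beta1000, toy4_beta1000)

    def test_wider_source_sd_never_shrinks_credible_interval(self):
        """Inflating all source SDs by a common factor leaves the ordinary
        95% CI at least as wide (monotonicity spot-check).  Run with a tight
        residual prior so the likelihood, not the residual scale, controls
        the interval."""
        widths = []
        for fac in (1.0, 3.0):
            space, data = bs.make_centroid_toy(
                bs.ToySpec(source_sd=1.0 * fac))
            d = bs.sample_ordinary(data, space,
                                   bs.ModelSpec(scale_prior_upper=1.0),
                                   n_iter=20_000, n_chains=4, seed=33,
                                   n_keep=40_000)
            s = bs.summarize(d)
            widths.append(float((s["ci_hi"] - s["ci_lo"]).mean()))
        assert widths[1] >= widths[0] - 1.0  # Monte-Carlo slack, 1 point
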