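import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import lstsq_gamma_fit
from conftest import make_counts
from moranselect.inference import (
    GammaPrior,
    SigmaGrid,
    analyse_locus,
    choose_grid,
    fit_gamma_surface,
    log_posterior_at,
    summarize,
)
from moranselect.moran_core import EmissionModel, locus_loglik
from moranselect.simulator import base_scenario, simulate_locus


class TestGammaSurfaceFit:
    def test_exact_recovery(self):
        x = np.array([0.5, 1.0, 1.5, 2.0, 2.5])
        y = 2.0 + (2.0 - 1.0) * np.log(x) - 3.0 * x
        gp = fit_gamma_surface(SigmaGrid(points=x - 1.0, log_post=y))
        assert gp.alpha == pytest.approx(2.0, abs=1e-8)
        assert gp.beta == pytest.approx(3.0, abs=1e-8)
        assert gp.c == pytest.approx(2.0, abs=1e-8)
        fitted = gp.c + (gp.alpha - 1.0) * np.log(x) - gp.beta * x
        assert np.allclose(fitted, y, atol=1e-8)

    def test_exponential_special_case_alpha_one(self):
        x = np.array([0.6, 0.9, 1.2, 1.5, 1.9])
        y = 1.3 - 2.2 * x  # no log term
        gp = fit_gamma_surface(SigmaGrid(points=x - 1.0, log_post=y))
        assert gp.alpha == pytest.approx(1.0, abs=1e-8)
        assert gp.beta == pytest.approx(2.2, abs=1e-8)

    def test_constant_shift_moves_only_c(self):
        x = np.array([0.8, 0.9, 1.0, 1.1, 1.2])
        y = -3.0 + 4.0 * np.log(x) - 2.0 * x
        g0 = fit_gamma_surface(SigmaGrid(points=x - 1.0, log_post=y))
        g1 = fit_gamma_surface(SigmaGrid(points=x - 1.0, log_post=y + 123.0))
        assert g1.alpha == pytest.approx(g0.alpha, abs=1e-8)
        assert g1.beta == pytest.approx(g0.beta, abs=1e-8)
        assert g1.c - g0.c == pytest.approx(123.0, abs=1e-7)

    def test_degenerate_fit_flagged_not_raised(self):
        x = np.array([0.8, 0.9, 1.0, 1.1, 1.2])
        gp = fit_gamma_surface(SigmaGrid(points=x - 1.0, log_post=5.0 * x))
        assert gp.degenerate

    def test_requires_log_post(self):
        with pytest.raises(ValueError, match="log-posterior"):
            fit_gamma_surface(SigmaGrid(points=np.array([-0.1, 0.0, 0.1])))

    @given(
        st.floats(0.5, 50.0),
        st.floats(0.5, 50.0),
        st.floats(-100.0, 100.0),
    )
    @settings(max_examples=100, deadline=None)
    def test_recovers_arbitrary_gamma(self, alpha, beta, c):
        x = np.linspace(0.7, 1.4, 5)
        y = c + (alpha - 1.0) * np.log(x) - beta * x
        gp = fit_gamma_surface(SigmaGrid(points=x - 1.0, log_post=y))
        assert gp.alpha == pytest.approx(alpha, rel=1e-7, abs=1e-7)
        assert gp.beta == pytest.approx(beta, rel=1e-7, abs=1e-7)

    @given(st.lists(st.floats(-200.0, 0.0), min_size=5, max_size=5))
    @settings(max_examples=100, deadline=None)
    def test_closed_form_equals_generic_least_squares(self, ys):
        sig = np.array([-0.1, -0.05, 0.0, 0.05, 0.1])
        grid = SigmaGrid(points=sig, log_post=np.asarray(ys))
        gp = fit_gamma_surface(grid)
        alpha, beta, c = lstsq_gamma_fit(sig, ys)
        assert gp.alpha == pytest.approx(alpha, rel=1e-8, abs=1e-8)
        assert gp.beta == pytest.approx(beta, rel=1e-8, abs=1e-8)
        assert gp.c == pytest.approx(c, rel=1e-8, abs=1e-8)


class TestSummarize:
    def test_even_odds(self):
        # alpha = 1: F(1) = 1 - exp(-beta) = 0.5 at beta = log 2
        _, _, log_bf, sat = summarize(1.0, math.log(2.0))
        assert log_bf == pytest.approx(0.0, abs=1e-12) and not sat

    def test_paper_threshold_anchor(self):
        # F(1) = 0.01 -> log(0.99/0.01) ~= 4.6
        _, _, log_bf, _ = summarize(1.0, -math.log(0.99))
        assert log_bf == pytest.approx(math.log(99.0), abs=1e-10)
        assert round(log_bf, 1) == 4.6

    def test_gamma_moments(self):
        mean_sigma, var_sigma, _, _ = summarize(2.0, 3.0)
        assert mean_sigma == pytest.approx(2.0 / 3.0 - 1.0)
        assert var_sigma == pytest.approx(2.0 / 9.0)

    def test_saturation_clamped_and_flagged(self):
        _, _, log_bf, sat = summarize(1.0, 1e6)
        assert log_bf == -709.0 and sat

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError):
            summarize(-1.0, 2.0)


class TestLogPosterior:
    def test_zero_information_posterior_is_prior(self):
        counts = make_counts([[0, 0]], [[0, 0]], [0.0, 1.0])
        prior = GammaPrior()
        for s in (-0.3, 0.0, 0.25):
            assert log_posterior_at(s, counts, 8, prior=prior) == pytest.approx(
                prior.logpdf(s), abs=1e-12
            )

    def test_prior_nearly_flat_relative_to_likelihood(self):
        # default prior varies far less over the scanned range than the
        # likelihood of even a modest selected locus
        prior = GammaPrior()
        sig = np.linspace(0.01, 1.0, 25)
        prior_span = np.ptp([prior.logpdf(s) for s in sig])
        _, lc = simulate_locus(base_scenario(p0=0.5, scaled_sigma=10.0, Ne=50, seed=7), 0)
        ll_span = np.ptp([locus_loglik(lc, s, 50) for s in sig])
        assert prior_span < 0.1 * ll_span

    def test_sigma_domain_enforced(self):
        counts = make_counts([[1]], [[2]], [0.0])
        with pytest.raises(ValueError):
            log_posterior_at(-1.5, counts, 4)


class TestChooseGrid:
    def test_flat_likelihood_fallback_centred_on_zero(self):
        counts = make_counts([[0, 0]], [[0, 0]], [0.0, 1.0])
        grid = choose_grid(counts, 6)
        step = 1.0 / 20
        assert np.allclose(grid.points, np.array([-2, -1, 0, 1, 2]) * step)

    def test_boundary_argmax_clamped(self):
        # strongly rising trajectory pushes the argmax to the scan edge
        N, C = 20, 40
        counts = make_counts([[2, 38]], [[C, C]], [0.0, 1.0])
        grid = choose_grid(counts, N, coarse_range=(-0.5, 0.1))
        assert grid.points[-1] == pytest.approx(0.1)
        assert len(grid.points) == 5

    def test_grid_brackets_true_sigma(self):
        # scaled selection 10 at Ne=100: true sigma = 0.1
        hits = 0
        for i in range(100):
            scn = base_scenario(p0=0.5, scaled_sigma=10.0, Ne=100, seed=123)
            _, lc = simulate_locus(scn, i)
            grid = choose_grid(lc, 100)
            hits += grid.points[0] < 0.1 < grid.points[-1]
        assert hits >= 95


class TestAnalyseLocus:
    def test_constant_locus_filtered(self, constant_counts):
        res = analyse_locus(constant_counts, 10)
        assert res.filtered
        assert res.mean_sigma is None and res.log_bf is None

    def test_selected_locus_yields_positive_estimate(self):
        scn = base_scenario(p0=0.5, scaled_sigma=10.0, Ne=100, seed=5)
        _, lc = simulate_locus(scn, 0)
        res = analyse_locus(lc, 100)
        assert not res.filtered and not res.degenerate
        assert res.alpha > 0 and res.beta > 0
        assert -0.5 < res.mean_sigma < 0.5

    def test_logbf_monotone_in_replication(self):
        # duplicating a replicate in which the selected allele visibly rose
        # should (statistically) never lower the log BF
        Ne = 100
        scn = base_scenario(p0=0.5, scaled_sigma=10.0, Ne=Ne, seed=31)
        violations = both = 0
        for i in range(100):
            _, lc = simulate_locus(scn, i)
            f = lc.frequencies()
            rise = np.nan_to_num(f[:, -1] - f[:, 0], nan=-9.0)
            r = int(np.argmax(rise))
            extra = make_counts(
                np.vstack([lc.counts, lc.counts[r : r + 1]]),
                np.vstack([lc.coverage, lc.coverage[r : r + 1]]),
                lc.generations,
            )
            r5 = analyse_locus(lc, Ne)
            r6 = analyse_locus(extra, Ne)
            if r5.log_bf is not None and r6.log_bf is not None:
                both += 1
                violations += r6.log_bf < r5.log_bf
        assert both >= 80
        assert violations / both < 0.10
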