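"""Ordinary and segmented logistic fits, initializer and profile oracle."""

import numpy as np
import pytest
from scipy.special import expit, logit

import atlasthresh as at
from atlasthresh.errors import DegenerateResponseError, InvalidInitializerError
from atlasthresh.segmented import SegmentedFailure, SegmentedFit

from conftest import make_outcome_arrays


def _logistic_xy(seed, n=300, b0=-2.0, b1=0.04):
    rng = np.random.default_rng(seed)
    x = rng.uniform(0, 100, n)
    y = (rng.random(n) < expit(b0 + b1 * x)).astype(float)
    return x, y


class TestFitLogistic:
    def test_degenerate_all_ones(self):
        with pytest.raises(DegenerateResponseError):
            at.fit_logistic(np.arange(10.0), np.ones(10))

    def test_degenerate_all_zeros(self):
        with pytest.raises(DegenerateResponseError):
            at.fit_logistic(np.arange(10.0), np.zeros(10))

    def test_constant_covariate(self):
        y = np.array([1.0, 0.0, 1.0, 1.0])
        fit = at.fit_logistic(np.full(4, 55.0), y)
        assert fit.slope == 0.0
        assert fit.intercept == pytest.approx(float(logit(0.75)))
        assert fit.aic == pytest.approx(-2 * fit.loglik + 4)

    def test_matches_statsmodels(self):
        import statsmodels.api as sm

        x, y = _logistic_xy(1)
        fit = at.fit_logistic(x, y)
        ref = sm.GLM(y, sm.add_constant(x), family=sm.families.Binomial()).fit()
        assert fit.intercept == pytest.approx(ref.params[0], abs=1e-8)
        assert fit.slope == pytest.approx(ref.params[1], abs=1e-10)
        assert fit.loglik == pytest.approx(ref.llf, abs=1e-8)

    def test_loglik_at_grid_search_maximum(self):
        # 30-point set: IRLS likelihood must not fall below a dense
        # two-parameter grid-search maximum
        x, y = _logistic_xy(2, n=30)
        fit = at.fit_logistic(x, y)

        def ll(b0, b1):
            eta = b0 + b1 * x
            return float(np.sum(y * eta - np.logaddexp(0, eta)))

        best = -np.inf
        b0g = np.linspace(fit.intercept - 1, fit.intercept + 1, 81)
        b1g = np.linspace(fit.slope - 0.02, fit.slope + 0.02, 81)
        for b0 in b0g:
            for b1 in b1g:
                best = max(best, ll(b0, b1))
        assert fit.loglik >= best - 1e-6
        assert abs(fit.loglik - best) < 1e-3

    def test_fitted_probabilities_in_unit_interval(self):
        x, y = _logistic_xy(3)
        fit = at.fit_logistic(x, y)
        assert np.all((fit.fitted > 0) & (fit.fitted < 1))


class TestLoessInitialPsi:
    def test_sharp_step_localized(self):
        spec = at.SpeciesResponseSpec("SHARP", 60.0, -4.0, 0.0, 3.0)
        for seed in range(5):
            x, y = make_outcome_arrays(500, seed, spec, cover_mean=50.0,
                                       cover_concentration=2.0)
            assert abs(at.loess_initial_psi(x, y) - 60.0) <= 10.0

    def test_small_sample_falls_back_to_median(self):
        x = np.array([10.0, 20.0, 30.0, 40.0, 50.0])
        y = np.array([0.0, 0.0, 1.0, 1.0, 1.0])
        with pytest.warns(UserWarning):
            assert at.loess_initial_psi(x, y) == 30.0

    def test_flat_response_returns_interior_value(self, flat_spec):
        x, y = make_outcome_arrays(300, 17, flat_spec)
        psi0 = at.loess_initial_psi(x, y)
        assert x.min() < psi0 < x.max()


class TestFitSegmented:
    def test_invalid_initializer(self):
        x, y = _logistic_xy(4)
        with pytest.raises(InvalidInitializerError):
            at.fit_segmented(x, y, x.max() + 5.0)

    def test_recovers_known_breakpoint(self, strong_threshold_spec):
        x, y = make_outcome_arrays(1500, 21, strong_threshold_spec)
        fit = at.fit_segmented(x, y, at.loess_initial_psi(x, y))
        assert fit.converged
        assert abs(fit.psi - 60.0) <= 2 * fit.psi_se
        assert fit.slope_change > 0.2
        assert x.min() < fit.psi < x.max()
        assert fit.aic == pytest.approx(-2 * fit.loglik + 8)

    def test_nesting_over_logistic(self, strong_threshold_spec):
        for seed in range(5):
            x, y = make_outcome_arrays(400, 40 + seed, strong_threshold_spec)
            log_fit = at.fit_logistic(x, y)
            seg = at.fit_segmented(x, y, at.loess_initial_psi(x, y))
            if seg.converged:
                assert seg.loglik >= log_fit.loglik - 1e-8

    def test_complement_symmetry_exact(self, moderate_threshold_spec):
        x, y = make_outcome_arrays(800, 13, moderate_threshold_spec)
        psi0 = at.loess_initial_psi(x, y)
        f = at.fit_segmented(x, y, psi0)
        g = at.fit_segmented(x, 1.0 - y, psi0)
        assert g.psi == f.psi
        assert g.psi_se == f.psi_se
        assert g.loglik == f.loglik
        assert g.intercept == -f.intercept
        assert g.slope_below == -f.slope_below
        assert g.slope_change == -f.slope_change


class TestFitSegmentedGrid:
    def test_matches_single_start_on_clean_data(self, strong_threshold_spec):
        x, y = make_outcome_arrays(800, 8, strong_threshold_spec)
        single = at.fit_segmented(x, y, at.loess_initial_psi(x, y))
        grid = at.fit_segmented_grid(x, y)
        assert isinstance(grid, SegmentedFit)
        assert grid.psi == pytest.approx(single.psi, abs=1e-6)

    def test_near_degenerate_response_is_handled(self):
        # species persistent in all but a few blocks: no crash, and the
        # threshold model is never selected for it
        rng = np.random.default_rng(0)
        x = rng.uniform(0, 100, 200)
        y = np.ones(200)
        y[[5, 50, 150]] = 0.0
        log_fit = at.fit_logistic(x, y)
        seg = at.fit_segmented_grid(x, y)
        comp = at.compare_models(log_fit, seg, x=x, y=y)
        assert comp.selected != "threshold"

    def test_degenerate_response_propagates(self):
        with pytest.raises(DegenerateResponseError):
            at.fit_segmented_grid(np.arange(20.0), np.ones(20))


class TestProfilePsiOracle:
    def test_agrees_with_iterative_fit(self, strong_threshold_spec):
        x, y = make_outcome_arrays(600, 5, strong_threshold_spec)
        fit = at.fit_segmented(x, y, at.loess_initial_psi(x, y))
        grid = np.arange(np.floor(x.min()) + 1, np.ceil(x.max()) - 1, 0.25)
        best, curve = at.profile_psi_oracle(x, y, grid)
        assert abs(best - fit.psi) <= 0.5
        assert np.nanmax(curve) <= fit.loglik + 1e-4

    def test_curve_aligned_with_grid(self, strong_threshold_spec):
        x, y = make_outcome_arrays(300, 6, strong_threshold_spec)
        grid = np.array([x.min() - 5.0, 50.0, 60.0, x.max() + 5.0])
        _, curve = at.profile_psi_oracle(x, y, grid)
        assert curve.shape == grid.shape
        assert np.isnan(curve[0]) and np.isnan(curve[-1])
        assert np.isfinite(curve[1:3]).all()
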