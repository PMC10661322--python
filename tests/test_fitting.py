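"""Logistic MLE, bootstrap SDs, failure accounting and histogram fits."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from randstep import (
    LevelGrid,
    RandomStepSampler,
    ResponseTally,
    SimulatedObserver,
    bootstrap_sds,
    failure_rate,
    fit_gaussian_offset,
    fit_logistic,
    fit_trials,
    logistic_probability,
    run_block,
)
from conftest import brute_force_loglik_max


def _logistic_tally(levels, pse, slope, n_per_level, seed):
    rng = np.random.default_rng(seed)
    levels = np.asarray(levels, float)
    p = logistic_probability(levels, pse, slope)
    ups = rng.binomial(n_per_level, p)
    return ResponseTally(tuple(levels), tuple([n_per_level] * len(levels)), tuple(ups))


def _rs_block(n_trials, sigma=2.0, seed=0, pivot=13.0):
    from randstep import default_simulation_grid

    grid = default_simulation_grid()
    rng = np.random.default_rng(seed)
    s = RandomStepSampler(grid, rng)
    trials = run_block(s, SimulatedObserver(pivot, sigma), n_trials, rng)
    return grid, trials, rng


class TestFitLogistic:
    def test_symmetric_tally_has_zero_midpoint(self):
        tally = ResponseTally((-1.0, 0.0, 1.0), (10, 10, 10), (0, 5, 10))
        fit = fit_logistic(tally)
        assert fit.converged
        assert fit.pse == pytest.approx(0.0, abs=1e-6)
        assert fit.slope > 0

    def test_recovers_generating_parameters(self):
        levels = np.arange(1.0, 21.0)
        tally = _logistic_tally(levels, pse=13.0, slope=1.2, n_per_level=200, seed=41)
        fit = fit_logistic(tally)
        assert fit.converged
        # 200 trials/level pins both parameters tightly
        assert fit.pse == pytest.approx(13.0, abs=0.3)
        assert fit.slope == pytest.approx(1.2, rel=0.15)

    @pytest.mark.parametrize("seed", range(5))
    def test_loglik_beats_brute_force_grid(self, seed):
        rng = np.random.default_rng(1000 + seed)
        levels = np.sort(rng.uniform(-5, 5, size=6))
        n_tot = rng.integers(3, 15, size=6)
        p = logistic_probability(levels, rng.uniform(-2, 2), rng.uniform(0.3, 2.0))
        n_up = rng.binomial(n_tot, p)
        if n_up.sum() == 0 or n_up.sum() == n_tot.sum():
            n_up[0], n_up[-1] = 0, n_tot[-1]  # keep the tally informative
        fit = fit_logistic(ResponseTally(tuple(levels), tuple(n_tot), tuple(n_up)))
        oracle = brute_force_loglik_max(
            levels,
            n_tot,
            n_up,
            pse_grid=np.linspace(-8, 8, 200),
            slope_grid=np.logspace(-2, 2, 200),
        )
        assert fit.loglik >= oracle - 1e-9

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(shift=st.floats(-40, 40))
    def test_shift_equivariance(self, shift):
        levels = np.arange(1.0, 21.0)
        tally = _logistic_tally(levels, 13.0, 0.8, 50, seed=7)
        base = fit_logistic(tally)
        shifted = fit_logistic(
            ResponseTally(tuple(levels + shift), tally.n_presented, tally.n_up)
        )
        assert shifted.pse == pytest.approx(base.pse + shift, abs=1e-4)
        assert shifted.slope == pytest.approx(base.slope, rel=1e-5)

    def test_slope_decreases_with_observer_noise(self):
        slopes = []
        for sigma in (2.0, 3.75, 5.0):
            levels = np.arange(1.0, 21.0)
            obs = SimulatedObserver(13.0, sigma)
            rng = np.random.default_rng(int(sigma * 100))
            from randstep import observer_probability_up

            p = observer_probability_up(levels, obs)
            ups = rng.binomial(500, p)
            fit = fit_logistic(ResponseTally(tuple(levels), tuple([500] * 20), tuple(ups)))
            assert fit.converged
            slopes.append(fit.slope)
        assert slopes[0] > slopes[1] > slopes[2]

    def test_identical_responses_do_not_converge(self):
        tally = ResponseTally((1.0, 2.0, 3.0), (5, 5, 5), (5, 5, 5))
        assert not fit_logistic(tally).converged

    def test_perfect_separation_does_not_converge(self):
        tally = ResponseTally((1.0, 2.0, 3.0, 4.0), (5, 5, 5, 5), (0, 0, 5, 5))
        assert not fit_logistic(tally).converged

    def test_single_informative_level_rejected(self):
        with pytest.raises(ValueError):
            fit_logistic(ResponseTally((1.0, 2.0, 3.0), (0, 9, 0), (0, 4, 0)))


class TestBootstrap:
    def test_rs_block_yields_finite_valid_sds(self):
        grid, trials, rng = _rs_block(300, seed=51)
        sds = bootstrap_sds(trials, grid, n_boot=300, rng=rng)
        assert np.isfinite(sds.sd_pse) and sds.pse_valid
        assert np.isfinite(sds.sd_slope) and sds.slope_valid
        assert sds.sd_pse >= 0 and sds.sd_slope >= 0

    def test_unfittable_trials_flagged_invalid(self, unit_grid):
        from randstep import UP, TrialRecord

        trials = [TrialRecord(i + 1, i % 20, float(i % 20 + 1), UP) for i in range(40)]
        sds = bootstrap_sds(trials, unit_grid, n_boot=50, rng=np.random.default_rng(0))
        assert not sds.pse_valid and not sds.slope_valid
        assert np.isnan(sds.sd_pse) and np.isnan(sds.sd_slope)

    def test_sd_shrinks_like_root_n(self):
        # quadrupling the trial count should roughly halve the PSE SD
        ratios = []
        for rep in range(12):
            _, t100, r1 = _rs_block(100, seed=600 + rep)
            _, t400, r2 = _rs_block(400, seed=900 + rep)
            grid = _rs_block(1, seed=0)[0]
            s100 = bootstrap_sds(t100, grid, n_boot=200, rng=r1)
            s400 = bootstrap_sds(t400, grid, n_boot=200, rng=r2)
            ratios.append(s400.sd_pse / s100.sd_pse)
        mean_ratio = float(np.mean(ratios))
        assert 0.5 * 0.7 < mean_ratio < 0.5 * 1.3

    def test_large_bootstrap_is_stable(self):
        grid, trials, _ = _rs_block(300, seed=77)
        a = bootstrap_sds(trials, grid, n_boot=2000, rng=np.random.default_rng(1))
        b = bootstrap_sds(trials, grid, n_boot=2000, rng=np.random.default_rng(2))
        assert a.sd_pse == pytest.approx(b.sd_pse, rel=0.10)
        assert a.sd_slope == pytest.approx(b.sd_slope, rel=0.10)


class TestFailureRate:
    def test_rates(self):
        assert failure_rate([True, True, True]) == 0.0
        assert failure_rate([True, False, True, True]) == 25.0
        assert failure_rate([False]) == 100.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            failure_rate([])


class TestGaussianOffset:
    def test_recovers_noiseless_parameters(self):
        levels = np.arange(1.0, 21.0)
        truth = dict(amplitude=3000.0, center=13.0, width=2.0, offset=1000.0)
        counts = truth["amplitude"] * np.exp(
            -((levels - truth["center"]) ** 2) / (2 * truth["width"] ** 2)
        ) + truth["offset"]
        model = fit_gaussian_offset(levels, counts)
        assert model.center_identifiable
        for key, val in truth.items():
            assert getattr(model, key) == pytest.approx(val, rel=0.05)

    def test_flat_histogram_is_pure_offset(self):
        levels = np.arange(1.0, 21.0)
        model = fit_gaussian_offset(levels, np.full(20, 42.0))
        assert model.offset == pytest.approx(42.0)
        assert model.amplitude == pytest.approx(0.0, abs=1e-9)
        assert not model.center_identifiable

    def test_too_few_occupied_levels_rejected(self):
        with pytest.raises(ValueError):
            fit_gaussian_offset(np.array([1.0, 2.0, 3.0, 4.0]), np.array([5.0, 6.0, 0.0, 0.0]))

    def test_accepts_a_response_tally(self):
        grid, trials, _ = _rs_block(5000, seed=3)
        model = fit_gaussian_offset(ResponseTally.from_trials(trials, grid))
        assert model.width > 0 and model.offset >= 0


def test_attach_bootstrap_populates_fit_fields():
    from randstep import attach_bootstrap

    grid, trials, rng = _rs_block(200, seed=5)
    fit = fit_trials(trials, grid)
    sds = bootstrap_sds(trials, grid, n_boot=100, rng=rng, base_fit=fit)
    attach_bootstrap(fit, sds)
    assert fit.sd_pse == sds.sd_pse or (np.isnan(fit.sd_pse) and np.isnan(sds.sd_pse))
    assert fit.sd_pse_valid == sds.pse_valid
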