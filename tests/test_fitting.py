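"""Likelihood, Bayesian fit, HDI computation and run pooling."""

import math

import numpy as np
import pytest

from tinnpsych.model import (
    SILENCE,
    BatchFitter,
    DegenerateFitError,
    FitConfig,
    PsychometricParams,
    RunData,
    Trial,
    fit_psychometric,
    gumbel_psi,
    log_likelihood,
    posterior_hdi,
    select_or_pool_runs,
    threshold_difference_test,
)

from conftest import make_run


class TestLogLikelihood:
    def test_single_silence_detection(self):
        run = RunData(8.0, [Trial(SILENCE, True)])
        p = PsychometricParams(40, 0.14, gamma=0.02)
        assert log_likelihood(run, p) == pytest.approx(math.log(0.02), abs=1e-12)

    def test_constant_half_probability(self):
        # when psi = 0.5 at every level, every trial contributes ln(0.5)
        p = PsychometricParams(40, 0.14)
        x_half = 40 + math.log10(-math.log(0.5)) / 0.14
        trials = [Trial(x_half, bool(i % 2)) for i in range(20)]
        run = RunData(8.0, trials)
        assert log_likelihood(run, p) == pytest.approx(20 * math.log(0.5), abs=1e-9)

    def test_zero_probability_response_flagged(self):
        run = RunData(8.0, [Trial(SILENCE, True)])
        p = PsychometricParams(40, 0.14, gamma=0.0)
        with pytest.warns(RuntimeWarning):
            assert log_likelihood(run, p) == float("-inf")

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_per_trial_product_oracle(self, seed, study_params):
        run = make_run(study_params, seed=seed)
        p = PsychometricParams(44, 0.2, 0.03, 0.01)
        # brute force: product of per-trial Bernoulli terms
        expected = 0.0
        for t in run.trials:
            prob = p.gamma if t.level == SILENCE else gumbel_psi(t.level, p)
            expected += math.log(prob if t.response else 1 - prob)
        assert log_likelihood(run, p) == pytest.approx(expected, abs=1e-10)


class TestPosteriorHdi:
    def test_point_mass(self):
        grid = np.linspace(0, 10, 101)
        dens = np.zeros(101)
        dens[37] = 1.0
        (lo, hi), segments, disjoint = posterior_hdi(grid, dens, 0.95)
        assert lo == hi == pytest.approx(grid[37])
        assert not disjoint

    def test_discretized_standard_normal(self):
        grid = np.linspace(-6, 6, 4001)
        dens = np.exp(-0.5 * grid**2)
        (lo, hi), _, disjoint = posterior_hdi(grid, dens, 0.95)
        assert lo == pytest.approx(-1.96, abs=0.01)
        assert hi == pytest.approx(1.96, abs=0.01)
        assert not disjoint

    def test_uniform_tie_broken_centrally(self):
        grid = np.linspace(0, 1, 1001)
        dens = np.ones(1001)
        (lo, hi), _, _ = posterior_hdi(grid, dens, 0.95)
        assert hi - lo == pytest.approx(0.95, abs=0.005)
        assert lo == pytest.approx(0.025, abs=0.005)

    def test_bimodal_density_flagged_disjoint(self):
        grid = np.linspace(-5, 5, 2001)
        dens = np.exp(-0.5 * ((grid + 3) / 0.3) ** 2) + np.exp(
            -0.5 * ((grid - 3) / 0.3) ** 2
        )
        interval, segments, disjoint = posterior_hdi(grid, dens, 0.95)
        assert disjoint
        assert len(segments) == 2
        assert interval[0] < -2 and interval[1] > 2


class TestFitPsychometric:
    def test_empty_run_returns_prior(self, default_cfg):
        fit = fit_psychometric(RunData(8.0, []), default_cfg)
        assert fit.map_params.alpha == pytest.approx(45.0, abs=0.5)
        # posterior of the threshold equals the (discretized, truncated) prior
        prior = np.exp(default_cfg.log_prior_alpha)
        prior /= prior.sum()
        np.testing.assert_allclose(fit.alpha_posterior, prior, atol=1e-10)

    def test_single_response_type_is_degenerate(self, default_cfg):
        run = RunData(8.0, [Trial(40.0 + i, True) for i in range(10)])
        with pytest.raises(DegenerateFitError) as err:
            fit_psychometric(run, default_cfg)
        assert err.value.diagnostic["all_response"] is True

    def test_recovers_generating_parameters(self, coarse_cfg, study_params):
        run = make_run(study_params, seed=42)
        fit = fit_psychometric(run, coarse_cfg)
        assert fit.map_params.alpha == pytest.approx(45.0, abs=2.0)
        assert fit.alpha_hdi[0] < 45.0 < fit.alpha_hdi[1]

    def test_gamma_tracks_silence_detections(self, coarse_cfg):
        # a well-separated run: the fitted false-alarm rate should sit near
        # the observed silence-trial detection fraction
        params = PsychometricParams(45.0, 0.3, gamma=0.15, lam=0.005)
        runs = [make_run(params, seed=s) for s in range(4)]
        pooled = runs[0]
        for r in runs[1:]:
            pooled = pooled.pooled_with(r)
        observed = np.mean(
            [t.response for t in pooled.trials if t.level == SILENCE]
        )
        fit = fit_psychometric(pooled, coarse_cfg)
        assert fit.map_params.gamma == pytest.approx(observed, abs=0.06)

    def test_hdi_contains_marginal_mode(self, coarse_cfg, study_params):
        fit = fit_psychometric(make_run(study_params, seed=7), coarse_cfg)
        mode = fit.alpha_grid[np.argmax(fit.alpha_posterior)]
        assert fit.alpha_hdi[0] <= mode <= fit.alpha_hdi[1]
        assert fit.alpha_posterior.sum() == pytest.approx(1.0, abs=1e-9)
        assert fit.beta_posterior.sum() == pytest.approx(1.0, abs=1e-9)

    def test_deterministic_given_config(self, coarse_cfg, study_params):
        run = make_run(study_params, seed=3)
        f1 = fit_psychometric(run, coarse_cfg)
        f2 = fit_psychometric(run, coarse_cfg)
        assert f1.map_params == f2.map_params
        np.testing.assert_array_equal(f1.alpha_posterior, f2.alpha_posterior)

    def test_batch_fitter_agrees_with_single_fit_path(self, coarse_cfg, study_params):
        run = make_run(study_params, seed=11)
        fitter = BatchFitter(coarse_cfg, tuple(run.levels))
        levels, n, k, n0, k0 = run.counts()
        batch = fitter.fit_counts(n, k, n0, k0, run.n_trials)
        single = fit_psychometric(run, coarse_cfg)
        assert batch.map_params == single.map_params
        np.testing.assert_array_equal(batch.alpha_posterior, single.alpha_posterior)


class TestDifferenceAndPooling:
    def test_identical_posteriors_not_significant(self, coarse_cfg, study_params):
        fit = fit_psychometric(make_run(study_params, seed=5), coarse_cfg)
        res = threshold_difference_test(fit, fit, coarse_cfg)
        assert not res.significant
        assert res.hdi[0] <= 0 <= res.hdi[1]
        assert res.delta_mean == pytest.approx(0.0, abs=0.1)

    def test_large_shift_detected(self, coarse_cfg):
        # 10 dB true threshold shift at a steep slope: essentially always seen
        n_sig = 0
        for seed in range(20):
            pa = PsychometricParams(40.0, 0.5, 0.02, 0.005)
            pb = PsychometricParams(50.0, 0.5, 0.02, 0.005)
            fa = fit_psychometric(make_run(pa, seed=seed, anchor=45.0), coarse_cfg)
            fb = fit_psychometric(make_run(pb, seed=1000 + seed, anchor=45.0), coarse_cfg)
            n_sig += threshold_difference_test(fa, fb, coarse_cfg).significant
        assert n_sig >= 19

    def test_identical_runs_pooled(self, coarse_cfg, study_params):
        runA = make_run(study_params, seed=9)
        runB = RunData(runA.frequency_khz, runA.trials)
        pooled, decision = select_or_pool_runs(runA, runB, coarse_cfg)
        assert decision.pooled
        assert pooled.n_trials == runA.n_trials + runB.n_trials == 180

    def test_separated_runs_select_more_precise(self, coarse_cfg):
        pa = PsychometricParams(38.0, 0.5, 0.02, 0.005)
        pb = PsychometricParams(52.0, 0.5, 0.02, 0.005)
        runA = make_run(pa, seed=13, anchor=45.0)
        runB = make_run(pb, seed=14, anchor=45.0)
        chosen, decision = select_or_pool_runs(runA, runB, coarse_cfg)
        assert not decision.pooled
        expected = "A" if decision.alpha_sd_a <= decision.alpha_sd_b else "B"
        assert decision.chosen == expected
        assert chosen.n_trials == 90

    def test_frequency_mismatch_rejected(self, coarse_cfg, study_params):
        runA = make_run(study_params, seed=2, frequency_khz=8.0)
        runB = make_run(study_params, seed=3, frequency_khz=6.0)
        with pytest.raises(ValueError, match="frequenc"):
            select_or_pool_runs(runA, runB, coarse_cfg)
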