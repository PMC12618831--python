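"""Adaptive staircase state machines and runners."""

import math

import numpy as np
import pytest

from tinnpsych.model import PsychometricParams, gumbel_psi
from tinnpsych.staircases import (
    PITCH_MAX_REVERSALS,
    PitchStaircaseState,
    StaircaseError,
    ThresholdStaircaseState,
    khz_to_oct,
    pitch_staircase_step,
    reduction_factor_after,
    run_pitch_staircase,
    run_threshold_staircase,
    threshold_staircase_step,
)

BOUNDS = (khz_to_oct(0.5), khz_to_oct(16.0))


class TestReductionFactor:
    def test_empty_product(self):
        assert reduction_factor_after(0) == 1.0

    def test_first_set_of_four(self):
        assert reduction_factor_after(4) == pytest.approx(0.25, abs=1e-12)

    def test_full_schedule_is_one_sixteenth(self):
        assert reduction_factor_after(16) == pytest.approx(1 / 16, abs=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            reduction_factor_after(17)
        with pytest.raises(ValueError):
            reduction_factor_after(-1)


class TestPitchStaircase:
    def test_first_trial_is_never_a_reversal(self):
        state = PitchStaircaseState.initial(2.0, BOUNDS)
        nxt = pitch_staircase_step(state, "high")
        assert nxt.reversal_count == 0
        assert not nxt.history[0].reversal
        # chosen high frequency anchors the next pair from below
        assert nxt.f_low == pytest.approx(state.f_high)

    def test_choice_change_is_a_reversal_and_shrinks_separation(self):
        state = PitchStaircaseState.initial(3.0, BOUNDS)
        state = pitch_staircase_step(state, "high")
        sep_before = state.separation
        state = pitch_staircase_step(state, "low")
        assert state.reversal_count == 1
        assert state.history[1].reversal
        assert state.separation == pytest.approx(sep_before * 0.5**0.5)

    def test_low_choice_anchors_from_above(self):
        state = PitchStaircaseState.initial(3.0, BOUNDS)
        nxt = pitch_staircase_step(state, "low")
        assert nxt.f_high == pytest.approx(state.f_low)

    def test_step_after_termination_rejected(self):
        state = PitchStaircaseState.initial(3.0, BOUNDS)
        choice = "high"
        while not state.terminated:
            choice = "low" if choice == "high" else "high"
            state = pitch_staircase_step(state, choice)
        with pytest.raises(StaircaseError):
            pitch_staircase_step(state, "low")

    def test_terminates_in_sixteen_reversals_with_final_factor(self):
        # strictly alternating choices: every trial after the first reverses
        state = PitchStaircaseState.initial(3.0, BOUNDS)
        choice = "high"
        while not state.terminated:
            choice = "low" if choice == "high" else "high"
            state = pitch_staircase_step(state, choice)
        assert state.reversal_count == PITCH_MAX_REVERSALS
        n_reversals = sum(t.reversal for t in state.history)
        assert n_reversals == PITCH_MAX_REVERSALS

    def test_noiseless_observer_converges(self):
        # deterministic nearest-tone observer with internal pitch P
        pitch = khz_to_oct(9.0)  # ~3.17 oct

        def observer(f_low, f_high):
            return "low" if abs(f_low - pitch) <= abs(f_high - pitch) else "high"

        trace = run_pitch_staircase(observer, pitch - 0.5, BOUNDS)
        assert trace.termination == "converged"
        assert trace.estimate == pytest.approx(pitch, abs=0.15)

    def test_noisy_observer_convergence_over_seeds(self):
        pitch = 3.17
        errors = []
        for seed in range(100):
            rng = np.random.default_rng(seed)

            def observer(f_low, f_high):
                jittered = pitch + rng.normal(0, 0.05)
                if abs(f_low - jittered) == abs(f_high - jittered):
                    return "low" if rng.random() < 0.5 else "high"
                return "low" if abs(f_low - jittered) < abs(f_high - jittered) else "high"

            trace = run_pitch_staircase(observer, pitch - 0.5, BOUNDS)
            errors.append(abs(trace.estimate - pitch))
        assert np.mean(errors) < 0.15

    def test_pairs_clamped_to_hearing_limit(self):
        limit = 3.0
        pitch = 3.4  # above the audible range
        bounds = (khz_to_oct(0.5), limit)
        rng = np.random.default_rng(17)

        def observer(f_low, f_high):
            # nearest-tone listener with a finite frequency difference limen
            jittered = pitch + rng.normal(0, 0.05)
            d_lo = abs(f_low + rng.normal(0, 0.02) - jittered)
            d_hi = abs(f_high + rng.normal(0, 0.02) - jittered)
            return "low" if d_lo < d_hi else "high"

        trace = run_pitch_staircase(observer, 2.8, bounds)
        assert all(t.f_high <= limit + 1e-9 for t in trace.trials)
        assert trace.estimate <= limit + 1e-9

    def test_reversal_count_equals_choice_sign_changes(self, rng):
        def observer(f_low, f_high):
            return "low" if rng.random() < 0.5 else "high"

        trace = run_pitch_staircase(observer, 3.0, BOUNDS)
        choices = [t.choice for t in trace.trials]
        changes = sum(a != b for a, b in zip(choices, choices[1:]))
        assert trace.n_reversals == min(changes, PITCH_MAX_REVERSALS)


class TestThresholdStaircase:
    def test_level_arithmetic_first_step(self):
        state = ThresholdStaircaseState(level=70.0)
        nxt = threshold_staircase_step(state, True)
        assert nxt.level == 62.0 and nxt.step == 8.0

    def test_first_reversal_drops_step_to_four(self):
        state = ThresholdStaircaseState(level=70.0)
        state = threshold_staircase_step(state, True)   # 62
        state = threshold_staircase_step(state, True)   # 54
        state = threshold_staircase_step(state, False)  # reversal at 54 dB
        assert state.reversal_count == 1
        assert state.step == 4.0
        assert state.level == pytest.approx(54.0 + 4.0)  # miss raises the level

    def test_step_schedule_non_increasing(self):
        rng = np.random.default_rng(0)
        state = ThresholdStaircaseState(level=60.0)
        steps = []
        while not state.terminated:
            state = threshold_staircase_step(state, bool(rng.random() < 0.5))
            steps.append(state.step)
        assert all(a >= b for a, b in zip(steps, steps[1:]))
        assert set(steps) <= {8.0, 4.0, 2.0, 1.0}

    def test_step_after_termination_rejected(self):
        rng = np.random.default_rng(0)
        state = ThresholdStaircaseState(level=60.0)
        while not state.terminated:
            state = threshold_staircase_step(state, bool(rng.random() < 0.5))
        with pytest.raises(StaircaseError):
            threshold_staircase_step(state, True)

    def test_hard_threshold_observer_converges_within_one_db(self):
        T = 41.3
        trace = run_threshold_staircase(lambda level: level >= T, T + 20)
        assert trace.estimate == pytest.approx(T, abs=1.0)

    def test_estimate_is_mean_of_last_five_reversal_levels(self):
        T = 37.0
        trace = run_threshold_staircase(lambda level: level >= T, 70.0)
        last5 = [trace.trials[i].level for i in trace.reversal_indices[-5:]]
        assert trace.estimate == pytest.approx(np.mean(last5))

    def test_probabilistic_observer_converges_to_half_response_level(self):
        # 1-up/1-down targets the 50%-response point of the observer's curve
        p = PsychometricParams(40.0, 0.14, gamma=0.02, lam=0.005)
        x_half = 40.0 + math.log10(-math.log(1 - (0.5 - 0.02) / (1 - 0.02 - 0.005))) / 0.14
        estimates = []
        for seed in range(500):
            rng = np.random.default_rng(seed)
            trace = run_threshold_staircase(
                lambda level: bool(rng.random() < gumbel_psi(level, p)), 60.0
            )
            estimates.append(trace.estimate)
        assert np.mean(estimates) == pytest.approx(x_half, abs=1.5)

    def test_runaway_observer_raises(self):
        with pytest.raises(StaircaseError, match="did not terminate"):
            run_threshold_staircase(lambda level: True, 70.0, max_trials=200)

    def test_same_seed_identical_trace(self):
        p = PsychometricParams(40.0, 0.14, gamma=0.02, lam=0.005)

        def run(seed):
            rng = np.random.default_rng(seed)
            return run_threshold_staircase(
                lambda level: bool(rng.random() < gumbel_psi(level, p)), 60.0
            )

        t1, t2 = run(99), run(99)
        assert t1.trials == t2.trials and t1.estimate == t2.estimate
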