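"""Run designs, verification tests and eligibility gates."""

import numpy as np
import pandas as pd
import pytest

from tinnpsych.model import SILENCE
from tinnpsych.protocols import (
    ParticipantRecord,
    apply_level_shift,
    design_psychometric_run,
    detection_rate,
    inclusion_gate,
    loudness_grid,
    octave_confusion_design,
    pitch_consistency_gate,
    presentation_level,
    shift_levels_between_runs,
    tonality_design,
)


class TestLoudnessGrid:
    def test_eighteen_tones_four_per_octave(self):
        grid = loudness_grid()
        assert len(grid) == 18
        assert grid[0] == pytest.approx(0.8)
        assert grid[-1] == pytest.approx(0.8 * 2 ** (17 / 4))
        ratios = grid[1:] / grid[:-1]
        np.testing.assert_allclose(ratios, 2 ** 0.25)
        assert np.all(grid <= 16.0)

    def test_presentation_level_increment_and_cap(self):
        assert presentation_level(55.0) == 65.0
        assert presentation_level(85.0) == 90.0


class TestRunDesign:
    def test_anchor_and_levels_from_fractional_estimate(self):
        design = design_psychometric_run(47.3, seed=0)
        assert design.anchor == 47
        assert design.finite_levels == (39.0, 43.0, 45.0, 47.0, 49.0, 51.0, 55.0)
        assert SILENCE in design.levels

    def test_ninety_trials_eight_levels(self):
        design = design_psychometric_run(40.0, seed=1)
        assert design.n_trials == 90
        assert len(design.levels) == 8

    def test_block_composition_exact(self):
        design = design_psychometric_run(40.0, seed=2)
        seq = np.array(design.sequence)
        blocks = np.array(design.blocks)
        for b in range(10):
            block_levels = sorted(seq[blocks == b])
            expected = sorted(list(design.finite_levels) + [SILENCE, SILENCE])
            assert block_levels == expected

    def test_deterministic_under_seed(self):
        d1 = design_psychometric_run(40.0, seed=5)
        d2 = design_psychometric_run(40.0, seed=5)
        assert d1.sequence == d2.sequence

    def test_shift_moves_all_but_highest_level(self):
        base = design_psychometric_run(40.0, seed=0)
        shifted = apply_level_shift(base, 2.0, seed=1)
        assert shifted.highest_level == base.highest_level == 48.0
        others_base = sorted(set(base.finite_levels) - {48.0})
        others_shift = sorted(set(shifted.finite_levels) - {48.0})
        np.testing.assert_allclose(others_shift, np.array(others_base) + 2.0)

    @pytest.mark.parametrize(
        "rate,expected", [(0.30, 2.0), (0.50, 0.0), (0.40, 0.0), (0.75, -2.0)]
    )
    def test_shift_rule(self, rate, expected):
        assert shift_levels_between_runs(rate) == expected


class TestOctaveConfusion:
    def test_fifteen_comparisons(self):
        design = octave_confusion_design(3.0, hearing_limit=4.5)
        assert design.n_comparisons == 15
        assert len(design.schedule(seed=0)) == 15

    def test_lowered_tone_set_near_hearing_limit(self):
        design = octave_confusion_design(3.2, hearing_limit=3.6)
        assert design.lowered
        assert design.tones == (3.2, 2.7, 2.2)

    def test_f_tp_above_limit_rejected(self):
        with pytest.raises(ValueError):
            octave_confusion_design(3.8, hearing_limit=3.6)

    def test_three_of_five_passes_at_sixty_percent(self):
        design = octave_confusion_design(3.0, hearing_limit=4.5)
        choices = []
        for pair in design.pairs:
            picks = [3.0] * 3 + [pair[0] if pair[0] != 3.0 else pair[1]] * 2
            choices.extend((pair, p) for p in picks)
        result = design.evaluate(choices)
        assert result["passed"]

    def test_two_of_five_fails(self):
        design = octave_confusion_design(3.0, hearing_limit=4.5)
        choices = []
        for pair in design.pairs:
            other = pair[0] if pair[0] != 3.0 else pair[1]
            picks = [3.0] * 2 + [other] * 3
            choices.extend((pair, p) for p in picks)
        assert not design.evaluate(choices)["passed"]


class TestTonality:
    def test_twentyfour_trials(self):
        design = tonality_design(3.0)
        assert design.n_trials == 24

    def test_four_of_six_passes_three_of_six_fails(self):
        design = tonality_design(3.0)
        ok = {c: [True] * 4 + [False] * 2 for c in design.comparators}
        assert design.evaluate(ok)["passed"]
        bad = dict(ok)
        bad[design.comparators[2]] = [True] * 3 + [False] * 3
        assert not design.evaluate(bad)["passed"]


class TestPitchConsistencyGate:
    def test_first_pair_accepted_and_averaged(self):
        res = pitch_consistency_gate([3.10, 3.35], [3.2, 3.3])
        assert res.accepted
        assert res.day1_estimate == pytest.approx(3.225)
        assert res.f_tp == res.day2_estimate == pytest.approx(3.25)

    def test_no_consistent_pair_over_five_runs_excludes(self):
        res = pitch_consistency_gate([1.0, 2.0, 3.0, 4.0, 5.0], [3.0, 3.1])
        assert not res.accepted
        assert "day-1" in res.reason

    def test_between_day_drift_excludes(self):
        res = pitch_consistency_gate([3.1, 3.3], [3.65, 3.75])
        assert not res.accepted
        assert "day-2 mean differs" in res.reason

    def test_later_successive_pair_rescues_day1(self):
        res = pitch_consistency_gate([1.0, 3.0, 3.2], [3.0, 3.1])
        assert res.accepted
        assert res.day1_estimate == pytest.approx(3.1)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            pitch_consistency_gate([], [3.0])


def _flat_audiogram(level=10.0, bone_gap=0.0, asym=0.0):
    rows = []
    for ear, sign in (("left", 1), ("right", -1)):
        for f in (0.25, 0.5, 1.0, 2.0, 4.0, 8.0):
            rows.append(
                {"frequency_khz": f, "ear": ear, "conduction": "air",
                 "threshold_db_hl": level + sign * asym / 2}
            )
        for f in (0.5, 1.0, 2.0, 4.0):
            rows.append(
                {"frequency_khz": f, "ear": ear, "conduction": "bone",
                 "threshold_db_hl": level + sign * asym / 2 - bone_gap}
            )
    return pd.DataFrame(rows)


def _eligible_record(**overrides):
    base = dict(
        group="tinnitus",
        age=55,
        audiogram=_flat_audiogram(),
        f_tp_khz=9.0,
        tinnitus_tonal=True,
        tinnitus_binaural=True,
        tinnitus_months=24,
        tinnitus_maskable=True,
        pitch_match_consistent=True,
        thi_score=40,
    )
    base.update(overrides)
    return ParticipantRecord(**base)


class TestInclusionGate:
    def test_all_criteria_met_passes_with_no_reasons(self):
        report = inclusion_gate(_eligible_record())
        assert report.passed
        assert report.reasons == ()

    def test_thi_at_threshold_fails(self):
        report = inclusion_gate(_eligible_record(thi_score=78))
        assert not report.passed
        assert any("thi" in r for r in report.reasons)

    def test_interaural_asymmetry_at_f_tp_fails(self):
        report = inclusion_gate(
            _eligible_record(audiogram=_flat_audiogram(asym=15.0))
        )
        assert not report.passed
        assert any("symmetric_at_f_tp" in r for r in report.reasons)

    def test_pta_above_45_fails(self):
        report = inclusion_gate(_eligible_record(audiogram=_flat_audiogram(level=50)))
        assert not report.passed

    def test_air_bone_gap_fails(self):
        report = inclusion_gate(
            _eligible_record(audiogram=_flat_audiogram(bone_gap=18.0))
        )
        assert not report.passed
        assert any("air_bone_gap" in r for r in report.reasons)

    def test_tinnitus_rows_not_applied_to_controls(self):
        record = _eligible_record(
            group="control", tinnitus_tonal=False, tinnitus_binaural=False,
            tinnitus_maskable=False, pitch_match_consistent=False, thi_score=None,
        )
        assert inclusion_gate(record).passed

    def test_missing_audiogram_points_reported(self):
        aud = _flat_audiogram()
        aud = aud[~((aud.frequency_khz == 2.0) & (aud.conduction == "air"))]
        with pytest.raises(ValueError, match="missing required points"):
            inclusion_gate(_eligible_record(audiogram=aud))

    def test_gate_is_pure(self):
        record = _eligible_record()
        r1, r2 = inclusion_gate(record), inclusion_gate(record)
        assert r1.passed == r2.passed and r1.reasons == r2.reasons
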