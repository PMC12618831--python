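"""Session designs and eligibility gates.

The measurement protocol: a loudness-matching grid (18 tones, 0.8–16 kHz at
4/octave), octave-confusion and tonality checks of the pitch match, the
0.4-octave pitch-consistency rules across two test days, the inclusion and
exclusion criteria, and the constant-stimuli run design used for psychometric
function measurement (90 trials: 7 finite levels x 10 plus silence x 20, in
ten randomized blocks of nine).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .model import SILENCE, RunData, Trial

__all__ = [
    "RunDesign",
    "EligibilityReport",
    "OctaveConfusionDesign",
    "TonalityDesign",
    "PitchGateResult",
    "ParticipantRecord",
    "loudness_grid",
    "design_psychometric_run",
    "detection_rate",
    "shift_levels_between_runs",
    "apply_level_shift",
    "octave_confusion_design",
    "tonality_design",
    "pitch_consistency_gate",
    "inclusion_gate",
    "presentation_level",
    "PITCH_CONSISTENCY_OCT",
]

#: Maximum difference between pitch estimates considered consistent (octaves).
PITCH_CONSISTENCY_OCT = 0.4

#: Finite level offsets (dB) around the rounded-down threshold estimate.
LEVEL_OFFSETS = (-8, -4, -2, 0, 2, 4, 8)
REPEATS_PER_LEVEL = 10
SILENCE_REPEATS = 20
N_BLOCKS = 10
MAX_PRESENTATION_DB = 90.0


def loudness_grid() -> np.ndarray:
    """The 18 loudness-matching tone frequencies (kHz), 0.8–16 kHz at 4/octave."""
    return 0.8 * 2.0 ** (np.arange(18) / 4.0)


def presentation_level(loudness_match_db: float, increment: float = 10.0) -> float:
    """Tone level for pitch/octave/tonality tests: match + 10 dB, capped at 90."""
    return min(loudness_match_db + increment, MAX_PRESENTATION_DB)


@dataclass(frozen=True)
class RunDesign:
    """One constant-stimuli run: levels, block structure and trial order."""

    frequency_khz: float
    anchor: int  # threshold estimate rounded downward to a whole dB
    levels: tuple[float, ...]  # 7 finite levels, ascending, plus SILENCE
    sequence: tuple[float, ...]  # 90 presented levels in order
    blocks: tuple[int, ...]  # block index per trial
    seed: int

    @property
    def n_trials(self) -> int:
        return len(self.sequence)

    @property
    def finite_levels(self) -> tuple[float, ...]:
        return tuple(lv for lv in self.levels if lv != SILENCE)

    @property
    def highest_level(self) -> float:
        return max(self.finite_levels)

    def to_run(self, responses: Sequence[bool]) -> RunData:
        if len(responses) != self.n_trials:
            raise ValueError(
                f"expected {self.n_trials} responses, got {len(responses)}"
            )
        trials = [
            Trial(level=lv, response=bool(r), block=b)
            for lv, r, b in zip(self.sequence, responses, self.blocks)
        ]
        return RunData(self.frequency_khz, trials)


def design_psychometric_run(
    threshold_estimate: float,
    seed: int,
    frequency_khz: float = 1.0,
    level_shift: float = 0.0,
) -> RunDesign:
    """Build the 90-trial constant-stimuli design around a threshold estimate.

    The anchor is the estimate rounded downward to a whole dB; finite levels
    are anchor + {-8, -4, -2, 0, +2, +4, +8} dB plus a silence catch level.
    Each of the ten blocks of nine presents every finite level once and
    silence twice, in seeded random order.  ``level_shift`` (±2 dB between
    runs) moves every finite level except the highest.
    """
    if not np.isfinite(threshold_estimate):
        raise ValueError(f"threshold estimate must be finite, got {threshold_estimate}")
    anchor = math.floor(threshold_estimate)
    finite = [float(anchor + off) for off in LEVEL_OFFSETS]
    if level_shift:
        top = max(finite)
        finite = [lv + level_shift if lv != top else lv for lv in finite]
    levels = tuple(sorted(finite)) + (SILENCE,)
    block_multiset = list(finite) + [SILENCE, SILENCE]
    rng = np.random.default_rng(seed)
    sequence: list[float] = []
    blocks: list[int] = []
    for b in range(N_BLOCKS):
        order = rng.permutation(len(block_multiset))
        sequence.extend(block_multiset[i] for i in order)
        blocks.extend([b] * len(block_multiset))
    return RunDesign(
        frequency_khz=float(frequency_khz),
        anchor=anchor,
        levels=levels,
        sequence=tuple(sequence),
        blocks=tuple(blocks),
        seed=seed,
    )


def detection_rate(run: RunData) -> float:
    """Overall detection rate over the finite (non-silence) levels."""
    finite = [t for t in run.trials if t.level != SILENCE]
    if not finite:
        raise ValueError("run has no finite-level trials")
    return sum(t.response for t in finite) / len(finite)


def shift_levels_between_runs(rate: float) -> float:
    """Inter-run level shift (dB) from the first run's overall detection rate.

    +2 dB when the rate is below 0.4, -2 dB above 0.6, otherwise 0 — moving
    the overall detection rate closer to 50%.  The highest level is exempt
    from the shift (see :func:`design_psychometric_run`).
    """
    if not (0.0 <= rate <= 1.0):
        raise ValueError(f"detection rate must be in [0, 1], got {rate}")
    if rate < 0.4:
        return 2.0
    if rate > 0.6:
        return -2.0
    return 0.0


def apply_level_shift(design: RunDesign, shift: float, seed: int) -> RunDesign:
    """Second-run design: same anchor, all but the highest level shifted."""
    return design_psychometric_run(
        design.anchor, seed, frequency_khz=design.frequency_khz, level_shift=shift
    )


@dataclass(frozen=True)
class OctaveConfusionDesign:
    """Schedule and pass rule of the octave-confusion check.

    Three tones — the pitch match f_tp and, when an octave above is audible,
    one octave above and below (otherwise half an octave and one octave
    below) — give three pairs, each presented five times (15 comparisons).
    The pitch match passes when it is chosen on at least 60% of the trials of
    each pair that includes it and an alternative a full or half octave away.
    """

    f_tp: float  # oct re 1 kHz
    tones: tuple[float, float, float]
    lowered: bool  # True when f_tp + 1 oct exceeded the hearing limit
    pairs: tuple[tuple[float, float], ...]
    repeats: int = 5
    pass_fraction: float = 0.6

    @property
    def n_comparisons(self) -> int:
        return len(self.pairs) * self.repeats

    def schedule(self, seed: int) -> list[tuple[float, float]]:
        """Randomized block order: each pair once per block, five blocks."""
        rng = np.random.default_rng(seed)
        out: list[tuple[float, float]] = []
        for _ in range(self.repeats):
            for i in rng.permutation(len(self.pairs)):
                out.append(self.pairs[i])
        return out

    def evaluate(self, choices: Sequence[tuple[tuple[float, float], float]]) -> dict:
        """Score chosen tones; ``choices`` pairs each presented pair with the pick.

        Pass requires >= 60% f_tp choices separately in every pair containing
        f_tp (per-pair rule; the aggregated alternative is reported too).
        """
        per_pair: dict[tuple[float, float], list[bool]] = {p: [] for p in self.pairs}
        for pair, picked in choices:
            per_pair[pair].append(picked == self.f_tp)
        ftp_pairs = {p: v for p, v in per_pair.items() if self.f_tp in p}
        fractions = {p: (np.mean(v) if v else np.nan) for p, v in ftp_pairs.items()}
        passed = all(f >= self.pass_fraction for f in fractions.values())
        pooled = [x for p, v in ftp_pairs.items() for x in v]
        return {
            "passed": bool(passed),
            "per_pair_fraction": {str(p): float(f) for p, f in fractions.items()},
            "aggregate_fraction": float(np.mean(pooled)) if pooled else float("nan"),
        }


def octave_confusion_design(f_tp: float, hearing_limit: float) -> OctaveConfusionDesign:
    """Build the octave-confusion comparison schedule (frequencies in octaves)."""
    if f_tp > hearing_limit:
        raise ValueError(
            f"pitch match {f_tp} oct is above the hearing limit {hearing_limit} oct"
        )
    lowered = (f_tp + 1.0) > hearing_limit
    if lowered:
        tones = (f_tp, f_tp - 0.5, f_tp - 1.0)
    else:
        tones = (f_tp, f_tp + 1.0, f_tp - 1.0)
    pairs = (
        (tones[0], tones[1]),
        (tones[0], tones[2]),
        (tones[1], tones[2]),
    )
    return OctaveConfusionDesign(f_tp=f_tp, tones=tones, lowered=lowered, pairs=pairs)


@dataclass(frozen=True)
class TonalityDesign:
    """Four tone-versus-noise comparisons assessing tonality of the tinnitus.

    The matched tone is compared against ½-octave narrowband noise, 1/6-octave
    narrowband noise, 3-octave wideband noise, and 3-octave noise plus an
    equal-power tone — all centered at f_tp and restricted to 0.1–16 kHz.
    Passing requires choosing the tone on at least 60% of the six repeats of
    each comparison.
    """

    f_tp: float  # oct re 1 kHz
    comparators: tuple[str, ...] = (
        "narrowband_noise_half_oct",
        "narrowband_noise_sixth_oct",
        "wideband_noise_3oct",
        "wideband_noise_3oct_plus_tone",
    )
    repeats: int = 6
    pass_fraction: float = 0.6
    band_limits_khz: tuple[float, float] = (0.1, 16.0)

    @property
    def n_trials(self) -> int:
        return len(self.comparators) * self.repeats

    def evaluate(self, tone_chosen: Mapping[str, Sequence[bool]]) -> dict:
        fractions = {}
        for comp in self.comparators:
            picks = list(tone_chosen.get(comp, []))
            if len(picks) != self.repeats:
                raise ValueError(
                    f"comparison {comp!r} needs {self.repeats} choices, got {len(picks)}"
                )
            fractions[comp] = float(np.mean(picks))
        passed = all(f >= self.pass_fraction for f in fractions.values())
        return {"passed": bool(passed), "per_comparison_fraction": fractions}


def tonality_design(f_tp: float) -> TonalityDesign:
    return TonalityDesign(f_tp=f_tp)


@dataclass(frozen=True)
class PitchGateResult:
    accepted: bool
    day1_estimate: float | None
    day2_estimate: float | None
    f_tp: float | None  # the day-2 estimate when accepted
    reason: str


def _first_consistent_pair(estimates: Sequence[float], max_runs: int) -> float | None:
    """Mean of the first successive pair differing by < 0.4 oct, if any."""
    usable = list(estimates[:max_runs])
    for a, b in zip(usable, usable[1:]):
        if abs(b - a) < PITCH_CONSISTENCY_OCT:
            return 0.5 * (a + b)
    return None


def pitch_consistency_gate(
    day1_estimates: Sequence[float], day2_estimates: Sequence[float]
) -> PitchGateResult:
    """Apply the two-day pitch-consistency rules (practice runs excluded).

    Day 1: the first successive pair of estimates differing by less than 0.4
    octave (within at most five test runs) is averaged; otherwise the
    participant is excluded.  Day 2: same rule within at most three runs, and
    the day-2 mean must lie within 0.4 octave of the day-1 mean.  The final
    pitch match is the day-2 estimate.
    """
    if not len(day1_estimates):
        raise ValueError("day-1 estimates are empty")
    day1 = _first_consistent_pair(day1_estimates, max_runs=5)
    if day1 is None:
        return PitchGateResult(
            False, None, None, None,
            "no successive day-1 pair within 0.4 oct over up to five runs",
        )
    if not len(day2_estimates):
        raise ValueError("day-2 estimates are empty")
    day2 = _first_consistent_pair(day2_estimates, max_runs=3)
    if day2 is None:
        return PitchGateResult(
            False, day1, None, None,
            "no successive day-2 pair within 0.4 oct over up to three runs",
        )
    if abs(day2 - day1) > PITCH_CONSISTENCY_OCT:
        return PitchGateResult(
            False, day1, day2, None,
            "day-2 mean differs more than 0.4 oct from day-1 mean",
        )
    return PitchGateResult(True, day1, day2, day2, "consistent")


@dataclass
class ParticipantRecord:
    """Attributes the eligibility gate evaluates.

    ``audiogram`` has columns ``frequency_khz, ear, conduction,
    threshold_db_hl`` with ears ``left``/``right`` and conduction
    ``air``/``bone``.
    """

    group: str  # "tinnitus" or "control"
    age: float
    audiogram: pd.DataFrame
    f_tp_khz: float | None = None
    tinnitus_tonal: bool = False
    tinnitus_binaural: bool = False
    tinnitus_months: float = 0.0
    tinnitus_maskable: bool = False
    pitch_match_consistent: bool = False
    thi_score: float | None = None
    hypersensitive_to_sound: bool = False
    auditory_hallucinations: bool = False
    neurological_disorder: bool = False
    in_other_study: bool = False


@dataclass(frozen=True)
class EligibilityReport:
    """Per-criterion verdicts; overall is the conjunction of applicable rows."""

    criteria: dict
    passed: bool
    reasons: tuple[str, ...]


_PTA_FREQS = (0.5, 1.0, 2.0, 4.0)


def _air_thresholds(aud: pd.DataFrame, ear: str) -> pd.Series:
    sel = aud[(aud.ear == ear) & (aud.conduction == "air")]
    return sel.set_index("frequency_khz")["threshold_db_hl"].sort_index()


def _threshold_at(series: pd.Series, f_khz: float) -> float:
    """Air-conduction HL at the audiogram frequency nearest to ``f_khz`` (log scale)."""
    freqs = series.index.to_numpy(dtype=float)
    nearest = freqs[np.argmin(np.abs(np.log2(freqs) - np.log2(f_khz)))]
    return float(series.loc[nearest])


def inclusion_gate(record: ParticipantRecord) -> EligibilityReport:
    """Evaluate every inclusion/exclusion criterion for a participant.

    Tinnitus participants must pass all criteria; for controls only the
    hearing-loss and age inclusion rows apply (plus the exclusion rules, once
    a pitch-match frequency has been assigned).
    """
    aud = record.audiogram
    missing = []
    for ear in ("left", "right"):
        air = _air_thresholds(aud, ear)
        for f in _PTA_FREQS:
            if f not in air.index:
                missing.append((ear, "air", f))
        bone = aud[(aud.ear == ear) & (aud.conduction == "bone")]
        for f in _PTA_FREQS:
            if f not in set(bone.frequency_khz):
                missing.append((ear, "bone", f))
    if missing:
        raise ValueError(f"audiogram is missing required points: {missing}")

    tinnitus = record.group == "tinnitus"
    crit: dict[str, tuple[bool, bool, str]] = {}  # name -> (passed, applicable, detail)

    air_l = _air_thresholds(aud, "left")
    air_r = _air_thresholds(aud, "right")
    pta_l = float(air_l.loc[list(_PTA_FREQS)].mean())
    pta_r = float(air_r.loc[list(_PTA_FREQS)].mean())
    crit["pta_le_45_better_ear"] = (
        min(pta_l, pta_r) <= 45.0, True,
        f"PTA left {pta_l:.1f}, right {pta_r:.1f} dB HL",
    )
    crit["age_18_70"] = (18 <= record.age <= 70, True, f"age {record.age}")
    crit["tinnitus_tonal"] = (record.tinnitus_tonal, tinnitus, "")
    crit["tinnitus_binaural"] = (record.tinnitus_binaural, tinnitus, "")
    crit["tinnitus_over_6_months"] = (record.tinnitus_months > 6, tinnitus, "")
    crit["tinnitus_maskable"] = (record.tinnitus_maskable, tinnitus, "")
    crit["pitch_match_consistent"] = (record.pitch_match_consistent, tinnitus, "")
    thi_ok = record.thi_score is not None and record.thi_score < 78
    crit["thi_below_78"] = (thi_ok, tinnitus, f"THI {record.thi_score}")

    if record.f_tp_khz is not None:
        f_hi = record.f_tp_khz
        f_lo = f_hi * 2.0 ** -0.6
        asym = max(
            abs(_threshold_at(air_l, f) - _threshold_at(air_r, f)) for f in (f_hi, f_lo)
        )
        crit["symmetric_at_f_tp"] = (
            asym <= 10.0, True, f"max interaural difference {asym:.1f} dB"
        )
        worst = max(
            max(_threshold_at(air_l, f), _threshold_at(air_r, f)) for f in (f_hi, f_lo)
        )
        crit["loss_le_70_at_f_tp"] = (worst <= 70.0, True, f"worst HL {worst:.1f} dB")
    crit["symmetric_pta"] = (
        abs(pta_l - pta_r) <= 20.0, True, f"interaural PTA difference {abs(pta_l - pta_r):.1f} dB"
    )

    gap_ok = True
    gap_detail = []
    for ear, air in (("left", air_l), ("right", air_r)):
        bone = (
            aud[(aud.ear == ear) & (aud.conduction == "bone")]
            .set_index("frequency_khz")["threshold_db_hl"]
            .sort_index()
        )
        gaps = np.array([air.loc[f] - bone.loc[f] for f in _PTA_FREQS])
        mean_gap = float(gaps.mean())
        consecutive = any(gaps[i] > 15 and gaps[i + 1] > 15 for i in range(len(gaps) - 1))
        if mean_gap > 10 or consecutive:
            gap_ok = False
        gap_detail.append(f"{ear} mean gap {mean_gap:.1f} dB")
    crit["air_bone_gap_ok"] = (gap_ok, True, "; ".join(gap_detail))

    crit["no_hypersensitivity"] = (not record.hypersensitive_to_sound, True, "")
    crit["no_auditory_hallucinations"] = (not record.auditory_hallucinations, True, "")
    crit["no_neurological_disorder"] = (not record.neurological_disorder, True, "")
    crit["not_in_other_study"] = (not record.in_other_study, True, "")

    reasons = tuple(
        f"{name}: {detail}" if detail else name
        for name, (ok, applicable, detail) in crit.items()
        if applicable and not ok
    )
    return EligibilityReport(criteria=crit, passed=not reasons, reasons=reasons)
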