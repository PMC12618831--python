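"""Adaptive staircase procedures.

Two pure state machines plus runners that drive them against an observer
callback:

* a recursive 2-AFC pitch-matching staircase — a pair of tones (lower always
  first) separated initially by 0.9 octave; the chosen tone anchors the next
  pair on its own side, and the separation shrinks after each reversal
  following the schedule 0.5^0.5, 0.5^0.25, 0.5^0.125, 0.5^0.125 (one factor
  per reversal, in four sets of four), so that after 16 reversals the
  separation is exactly 1/16 of the start;
* a 1-up/1-down yes/no threshold staircase with step sizes 8, 4, 2, 1 dB,
  stepping down after each reversal and terminating after five further
  reversals at the 1-dB step.  It converges near the 50%-response level.

Frequencies are handled in octaves re 1 kHz throughout; conversion to kHz
happens at module boundaries only.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "PitchStaircaseState",
    "ThresholdStaircaseState",
    "StaircaseTrace",
    "StaircaseError",
    "reduction_factor_after",
    "per_reversal_reduction",
    "pitch_staircase_step",
    "run_pitch_staircase",
    "threshold_staircase_step",
    "run_threshold_staircase",
    "oct_to_khz",
    "khz_to_oct",
]

#: Per-reversal separation reduction factors, one per set of four reversals.
_REDUCTIONS = (0.5 ** 0.5, 0.5 ** 0.25, 0.5 ** 0.125, 0.5 ** 0.125)

PITCH_START_SEPARATION_OCT = 0.9
PITCH_MAX_REVERSALS = 16
THRESHOLD_STEP_SCHEDULE = (8.0, 4.0, 2.0, 1.0)
THRESHOLD_TERMINAL_REVERSALS = 5  # reversals at the 1-dB step before stopping


class StaircaseError(RuntimeError):
    """Stepping a terminated staircase, or a staircase that fails to terminate."""


def khz_to_oct(f_khz: float) -> float:
    """Frequency in octaves re 1 kHz."""
    return float(np.log2(f_khz))


def oct_to_khz(f_oct: float) -> float:
    return float(2.0 ** f_oct)


def per_reversal_reduction(n_reversals_so_far: int) -> float:
    """Reduction factor applied at the next reduction event.

    The factor depends on which set of four reversals the procedure is in.
    """
    if not (0 <= n_reversals_so_far <= PITCH_MAX_REVERSALS):
        raise ValueError(f"reversal count out of range: {n_reversals_so_far}")
    return _REDUCTIONS[min(n_reversals_so_far, PITCH_MAX_REVERSALS - 1) // 4]


def reduction_factor_after(n_reversals: int) -> float:
    """Cumulative separation factor after ``n_reversals`` reversals.

    The product of the per-reversal reductions; after all 16 reversals it is
    exactly 1/16 of the starting separation.
    """
    if not (0 <= n_reversals <= PITCH_MAX_REVERSALS):
        raise ValueError(
            f"reversal count must be in [0, {PITCH_MAX_REVERSALS}], got {n_reversals}"
        )
    factor = 1.0
    for i in range(n_reversals):
        factor *= _REDUCTIONS[i // 4]
    return factor


@dataclass(frozen=True)
class PitchTrial:
    f_low: float  # oct re 1 kHz
    f_high: float
    choice: str  # "low" or "high"
    reversal: bool


@dataclass(frozen=True)
class PitchStaircaseState:
    """State of the recursive 2-AFC pitch staircase (immutable)."""

    f_low: float
    f_high: float
    bounds: tuple[float, float]  # audible range, oct re 1 kHz
    start_separation: float = PITCH_START_SEPARATION_OCT
    reversal_count: int = 0
    edge_factor: float = 1.0  # extra reductions from hearing-range clamps
    last_choice: str | None = None
    history: tuple[PitchTrial, ...] = ()
    terminated: bool = False

    def __post_init__(self):
        if not self.f_low < self.f_high:
            raise ValueError(f"need f_low < f_high, got {self.f_low} >= {self.f_high}")
        if self.reversal_count > PITCH_MAX_REVERSALS:
            raise ValueError("reversal count exceeds the 16-reversal schedule")

    @property
    def separation(self) -> float:
        return self.f_high - self.f_low

    @classmethod
    def initial(
        cls,
        start_oct: float,
        bounds: tuple[float, float],
        start_separation: float = PITCH_START_SEPARATION_OCT,
    ) -> "PitchStaircaseState":
        """Starting pair: the initial estimate and ``start_separation`` above it.

        If the upper tone would exceed the audible range the pair is clamped
        to the edge with one separation reduction applied, as during the run.
        """
        lo, hi = bounds
        if not (lo <= start_oct <= hi):
            raise ValueError(f"start {start_oct} oct outside audible range {bounds}")
        sep = start_separation
        edge_factor = 1.0
        f_low, f_high = start_oct, start_oct + sep
        while f_high > hi and sep > 1e-9:
            edge_factor *= _REDUCTIONS[0]
            sep = start_separation * edge_factor
            f_low, f_high = hi - sep, hi
            if f_low >= lo:
                break
        return cls(
            f_low=f_low, f_high=f_high, bounds=bounds,
            start_separation=start_separation, edge_factor=edge_factor,
        )


def pitch_staircase_step(state: PitchStaircaseState, choice: str) -> PitchStaircaseState:
    """Advance the pitch staircase by one trial.

    The chosen frequency anchors the next pair on its own side (chosen high →
    pair extends upward from it; chosen low → downward).  A choice differing
    from the previous one is a reversal and shrinks the separation by the
    scheduled factor; a pair clamped at the hearing-range edge also shrinks
    once, without counting a reversal.  Terminates upon the 16th reversal.
    """
    if state.terminated:
        raise StaircaseError("pitch staircase already terminated")
    if choice not in ("low", "high"):
        raise ValueError(f"choice must be 'low' or 'high', got {choice!r}")
    reversal = state.last_choice is not None and choice != state.last_choice
    reversal_count = state.reversal_count + int(reversal)
    trial = PitchTrial(state.f_low, state.f_high, choice, reversal)
    history = state.history + (trial,)
    if reversal_count >= PITCH_MAX_REVERSALS:
        return replace(
            state,
            reversal_count=reversal_count,
            last_choice=choice,
            history=history,
            terminated=True,
        )
    sep = state.start_separation * reduction_factor_after(reversal_count) * state.edge_factor
    anchor = state.f_high if choice == "high" else state.f_low
    if choice == "high":
        f_low, f_high = anchor, anchor + sep
    else:
        f_low, f_high = anchor - sep, anchor
    lo, hi = state.bounds
    edge_factor = state.edge_factor
    if f_high > hi or f_low < lo:
        # Edge contact costs one extra separation reduction (not a reversal),
        # and the pair is shifted back inside the audible range.
        edge_factor *= per_reversal_reduction(reversal_count)
        sep = state.start_separation * reduction_factor_after(reversal_count) * edge_factor
        if choice == "high":
            f_high = min(anchor + sep, hi)
            f_low = f_high - sep
        else:
            f_low = max(anchor - sep, lo)
            f_high = f_low + sep
        if f_high > hi:
            f_high, f_low = hi, hi - sep
        if f_low < lo:
            f_low, f_high = lo, lo + sep
    if f_high - f_low < 1e-9:
        # repeated edge contacts can shrink the pair below floating-point
        # resolution; keep the tones minimally distinct
        f_low = f_high - 1e-9
    return replace(
        state,
        f_low=f_low,
        f_high=f_high,
        reversal_count=reversal_count,
        edge_factor=edge_factor,
        last_choice=choice,
        history=history,
    )


@dataclass(frozen=True)
class StaircaseTrace:
    """Full history of an adaptive procedure."""

    trials: tuple  # PitchTrial or ThresholdTrial records
    reversal_indices: tuple[int, ...]
    estimate: float | None
    termination: str  # "converged", "max_trials", ...
    units: str  # "oct" or "dB SPL"

    @property
    def n_reversals(self) -> int:
        return len(self.reversal_indices)


def _pitch_estimate(history: Sequence[PitchTrial]) -> float:
    """Mean of the pair midpoints (oct) at the last four reversals."""
    reversal_mids = [
        0.5 * (t.f_low + t.f_high) for t in history if t.reversal
    ]
    return float(np.mean(reversal_mids[-4:]))


def run_pitch_staircase(
    observer: Callable[[float, float], str],
    start_oct: float,
    bounds: tuple[float, float],
    max_trials: int = 500,
) -> StaircaseTrace:
    """Run the 2-AFC pitch staircase against an observer callback.

    ``observer(f_low, f_high)`` (octaves re 1 kHz) returns ``"low"`` or
    ``"high"``.  Terminates after 16 reversals; the estimate is the mean of
    the pair midpoints at the last four reversals.
    """
    state = PitchStaircaseState.initial(start_oct, bounds)
    for _ in range(max_trials):
        choice = observer(state.f_low, state.f_high)
        state = pitch_staircase_step(state, choice)
        if state.terminated:
            reversal_idx = tuple(
                i for i, t in enumerate(state.history) if t.reversal
            )
            return StaircaseTrace(
                trials=state.history,
                reversal_indices=reversal_idx,
                estimate=_pitch_estimate(state.history),
                termination="converged",
                units="oct",
            )
    raise StaircaseError(
        f"pitch staircase did not terminate within {max_trials} trials"
    )


@dataclass(frozen=True)
class ThresholdTrial:
    level: float  # dB SPL
    heard: bool
    reversal: bool


@dataclass(frozen=True)
class ThresholdStaircaseState:
    """State of the 1-up/1-down yes/no threshold staircase (immutable)."""

    level: float
    step: float = THRESHOLD_STEP_SCHEDULE[0]
    reversal_count: int = 0
    last_response: bool | None = None
    history: tuple[ThresholdTrial, ...] = ()
    terminated: bool = False

    def __post_init__(self):
        if self.step not in THRESHOLD_STEP_SCHEDULE:
            raise ValueError(
                f"step must follow the {THRESHOLD_STEP_SCHEDULE} schedule, got {self.step}"
            )


def threshold_staircase_step(
    state: ThresholdStaircaseState, heard: bool
) -> ThresholdStaircaseState:
    """Advance the 1-up/1-down staircase by one trial.

    The level decreases after a detection and increases after a miss.  A
    response differing from the previous one is a reversal; after reversals
    1, 2 and 3 the step drops to 4, 2 and 1 dB, and the run terminates after
    five further reversals at the 1-dB step (eight reversals in total).
    """
    if state.terminated:
        raise StaircaseError("threshold staircase already terminated")
    heard = bool(heard)
    reversal = state.last_response is not None and heard != state.last_response
    reversal_count = state.reversal_count + int(reversal)
    trial = ThresholdTrial(state.level, heard, reversal)
    history = state.history + (trial,)
    n_initial = len(THRESHOLD_STEP_SCHEDULE) - 1  # reversals that shrink the step
    if reversal_count >= n_initial + THRESHOLD_TERMINAL_REVERSALS:
        return replace(
            state,
            reversal_count=reversal_count,
            last_response=heard,
            history=history,
            terminated=True,
        )
    step = THRESHOLD_STEP_SCHEDULE[min(reversal_count, n_initial)]
    level = state.level - step if heard else state.level + step
    return replace(
        state,
        level=level,
        step=step,
        reversal_count=reversal_count,
        last_response=heard,
        history=history,
    )


def run_threshold_staircase(
    observer: Callable[[float], bool],
    start_level: float,
    max_trials: int = 500,
) -> StaircaseTrace:
    """Run the yes/no threshold staircase against an observer callback.

    ``observer(level_db)`` returns whether the tone was heard.  The threshold
    estimate is the mean presented level at the last five reversals.
    """
    if not np.isfinite(start_level):
        raise ValueError(f"start level must be finite, got {start_level}")
    state = ThresholdStaircaseState(level=float(start_level))
    for _ in range(max_trials):
        heard = observer(state.level)
        state = threshold_staircase_step(state, heard)
        if state.terminated:
            reversal_idx = tuple(
                i for i, t in enumerate(state.history) if t.reversal
            )
            levels = [state.history[i].level for i in reversal_idx[-THRESHOLD_TERMINAL_REVERSALS:]]
            return StaircaseTrace(
                trials=state.history,
                reversal_indices=reversal_idx,
                estimate=float(np.mean(levels)),
                termination="converged",
                units="dB SPL",
            )
    raise StaircaseError(
        f"threshold staircase did not terminate within {max_trials} trials"
    )
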