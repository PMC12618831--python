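"""Study orchestration: matching, full-protocol sessions, group summaries,
slope-difference posterior tests, and the threshold-shift detectability
simulation.

The detectability simulation mirrors the measurement design exactly: pairs of
90-trial constant-stimuli runs are drawn from Gumbel generating functions whose
midpoint (threshold) differs between the runs by 0–3 dB, over slopes from 0.05
to 0.5; each run is fitted and the Bayesian HDI threshold-difference test is
applied, yielding per-cell significance rates, fitted-shift means, and the
slope bias of the pooled fit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import protocols
from .model import (
    SILENCE,
    BatchFitter,
    DegenerateFitError,
    FitConfig,
    FitResult,
    PsychometricParams,
    RunData,
    fit_psychometric,
    gumbel_psi,
    hdi_of_samples,
    select_or_pool_runs,
    threshold_difference_test,
)
from .observers import (
    MAX_LEVEL_DB_SPL,
    ObserverProfile,
    hl_to_spl_offset,
    loudness_match_response,
    respond_detection,
    respond_pitch_2afc,
)
from .protocols import (
    design_psychometric_run,
    detection_rate,
    loudness_grid,
    octave_confusion_design,
    pitch_consistency_gate,
    shift_levels_between_runs,
    tonality_design,
)
from .staircases import (
    khz_to_oct,
    oct_to_khz,
    run_pitch_staircase,
    run_threshold_staircase,
)

__all__ = [
    "MatchAssignment",
    "SimulationGridSpec",
    "SimulationGrid",
    "SessionResult",
    "StudyConfig",
    "match_controls",
    "average_hf_loss",
    "run_full_protocol",
    "run_study",
    "slope_difference_posterior_test",
    "figure_shift_detectability",
    "smallest_significant_shift",
    "threshold_precision_study",
    "summarize_cohort",
    "simulate_run",
]

FREQ_OFFSET_OCT = 0.6  # the lower test frequency sits 0.6 oct below f_tp


@dataclass(frozen=True)
class MatchAssignment:
    """A control participant matched to a tinnitus participant."""

    control_id: str
    tinnitus_id: str
    assigned_f_tp_oct: float
    hearing_loss_distance_db: float
    hearing_limit_distance_khz: float
    age_distance_yr: float


def average_hf_loss(profile: ObserverProfile) -> float:
    """Mean audiometric threshold (dB HL) at 4 and 8 kHz over both ears."""
    vals = []
    for ear in ("left", "right"):
        air = profile.audiogram[(ear, "air")]
        vals.extend([air[4], air[5]])  # 4 and 8 kHz entries
    return float(np.mean(vals))


def match_controls(
    tinnitus: Sequence[ObserverProfile],
    controls: Sequence[ObserverProfile],
    f_tps: dict[str, float] | None = None,
) -> list[MatchAssignment]:
    """Assign each control the pitch-match frequency of a tinnitus participant.

    For each control: among the five tinnitus participants nearest in 4–8 kHz
    hearing loss, pick the one with the nearest hearing limit; ties are broken
    by nearest age, then by stable id order.  A tinnitus participant may serve
    several controls.  ``f_tps`` maps tinnitus ids to measured pitch matches
    (octaves); defaults to the generating tinnitus pitch.
    """
    if not tinnitus:
        raise ValueError("no tinnitus participants to match against")
    t_loss = {t.id: average_hf_loss(t) for t in tinnitus}
    out = []
    t_sorted = sorted(tinnitus, key=lambda t: t.id)
    for c in sorted(controls, key=lambda c: c.id):
        c_loss = average_hf_loss(c)
        candidates = sorted(
            t_sorted, key=lambda t: (abs(t_loss[t.id] - c_loss), t.id)
        )[:5]
        best = min(
            candidates,
            key=lambda t: (
                abs(t.hearing_limit_khz - c.hearing_limit_khz),
                abs(t.age - c.age),
                t.id,
            ),
        )
        if f_tps is not None:
            f_tp = f_tps[best.id]
        else:
            f_tp = best.tinnitus_pitch_oct
        out.append(
            MatchAssignment(
                control_id=c.id,
                tinnitus_id=best.id,
                assigned_f_tp_oct=float(f_tp),
                hearing_loss_distance_db=abs(t_loss[best.id] - c_loss),
                hearing_limit_distance_khz=abs(best.hearing_limit_khz - c.hearing_limit_khz),
                age_distance_yr=abs(best.age - c.age),
            )
        )
    return out


def simulate_run(
    design: protocols.RunDesign,
    params: PsychometricParams,
    rng: np.random.Generator,
) -> RunData:
    """Draw yes/no responses for a designed run from a generating curve."""
    probs = np.array([gumbel_psi(lv, params) for lv in design.sequence])
    responses = rng.random(len(probs)) < probs
    return design.to_run(responses)


def _measured_hearing_limit(profile: ObserverProfile) -> tuple[float, list]:
    """Hearing limit from the loudness grid: highest audible grid tone (kHz)."""
    grid = loudness_grid()
    matches = [(f, loudness_match_response(profile, f)) for f in grid]
    audible = [f for f, m in matches if m is not None]
    if not audible:
        raise ValueError(f"observer {profile.id} hears no grid tone at 90 dB SPL")
    return float(max(audible)), matches


def _staircase_start_level(profile: ObserverProfile, f_khz: float) -> float:
    """Start 20 dB above the audiogram-derived threshold when the audiogram
    covers a nearby frequency (within 0.5 oct); otherwise 70 dB SPL."""
    from .observers import AUDIOGRAM_FREQS_KHZ

    freqs = np.array(AUDIOGRAM_FREQS_KHZ)
    dist = np.abs(np.log2(freqs / f_khz))
    if dist.min() <= 0.5:
        nearest = float(freqs[np.argmin(dist)])
        hl = 0.5 * (
            profile.audiogram[("left", "air")][list(freqs).index(nearest)]
            + profile.audiogram[("right", "air")][list(freqs).index(nearest)]
        )
        return min(hl + hl_to_spl_offset(nearest) + 20.0, MAX_LEVEL_DB_SPL)
    return 70.0


@dataclass
class SessionResult:
    """Everything one participant's session produced."""

    participant_id: str
    group: str
    eligible: bool
    gate_reasons: tuple[str, ...] = ()
    hearing_limit_khz: float | None = None
    pitch_day1: list[float] = field(default_factory=list)
    pitch_day2: list[float] = field(default_factory=list)
    f_tp_oct: float | None = None
    octave_confusion: dict | None = None
    tonality: dict | None = None
    threshold_estimates: dict = field(default_factory=dict)  # "low"/"high" -> dB
    runs: dict = field(default_factory=dict)  # "low"/"high" -> [RunData, RunData]
    fits: dict = field(default_factory=dict)  # "low"/"high" -> FitResult
    pooling: dict = field(default_factory=dict)  # "low"/"high" -> PoolingDecision
    skipped: str | None = None


@dataclass(frozen=True)
class StudyConfig:
    """Knobs of a full synthetic study run."""

    fit: FitConfig = field(default_factory=FitConfig)
    seed: int = 0
    max_day1_runs: int = 5
    max_day2_runs: int = 3
    skip_gates: bool = False


def _pitch_runs(
    profile: ObserverProfile, start_oct: float, bounds, rng, n_runs: int
) -> list[float]:
    estimates = []
    for _ in range(n_runs + 1):  # first run is practice
        trace = run_pitch_staircase(
            lambda lo, hi: respond_pitch_2afc(profile, lo, hi, rng),
            start_oct, bounds,
        )
        estimates.append(trace.estimate)
    return estimates[1:]  # drop the practice run


def run_full_protocol(
    profile: ObserverProfile,
    config: StudyConfig,
    rng: np.random.Generator,
    assigned_f_tp_oct: float | None = None,
    alternate_order: bool = False,
) -> SessionResult:
    """Execute the full measurement protocol on one observer.

    Tinnitus observers go through loudness matching, two days of pitch
    staircases with the consistency gate, octave-confusion and tonality
    checks; controls receive their assigned pitch-match frequency.  Both then
    get adaptive threshold staircases and two constant-stimuli runs (with the
    ±2 dB inter-run shift) at f_tp and 0.6 oct below, followed by fitting and
    run pooling.  ``alternate_order`` flips which frequency is tested first.
    """
    session = SessionResult(participant_id=profile.id, group=profile.group, eligible=True)
    limit_khz, _matches = _measured_hearing_limit(profile)
    session.hearing_limit_khz = limit_khz
    limit_oct = khz_to_oct(limit_khz)
    bounds = (khz_to_oct(0.5), limit_oct)

    if profile.group == "tinnitus":
        grid = loudness_grid()
        audible = [f for f in grid if loudness_match_response(profile, f) is not None]
        start_oct = khz_to_oct(
            min(audible, key=lambda f: abs(khz_to_oct(f) - profile.tinnitus_pitch_oct))
        )
        start_oct = float(np.clip(start_oct, bounds[0], bounds[1]))
        session.pitch_day1 = _pitch_runs(profile, start_oct, bounds, rng, config.max_day1_runs)
        session.pitch_day2 = _pitch_runs(profile, start_oct, bounds, rng, config.max_day2_runs)
        gate = pitch_consistency_gate(session.pitch_day1, session.pitch_day2)
        if not gate.accepted and not config.skip_gates:
            session.eligible = False
            session.gate_reasons = (gate.reason,)
            session.skipped = "pitch consistency gate failed"
            return session
        session.f_tp_oct = gate.f_tp if gate.f_tp is not None else session.pitch_day2[-1]

        oc = octave_confusion_design(session.f_tp_oct, limit_oct)
        choices = []
        for pair in oc.schedule(seed=int(rng.integers(2**31))):
            pick = respond_pitch_2afc(profile, pair[0], pair[1], rng)
            lo, hi = min(pair), max(pair)
            choices.append((pair, lo if pick == "low" else hi))
        session.octave_confusion = oc.evaluate(choices)
        ton = tonality_design(session.f_tp_oct)
        picks = {
            comp: [bool(rng.random() < profile.tonality_tone_preference)
                   for _ in range(ton.repeats)]
            for comp in ton.comparators
        }
        session.tonality = ton.evaluate(picks)
        if not config.skip_gates and not (
            session.octave_confusion["passed"] and session.tonality["passed"]
        ):
            session.eligible = False
            session.gate_reasons = tuple(
                name for name, res in
                [("octave_confusion", session.octave_confusion), ("tonality", session.tonality)]
                if not res["passed"]
            )
            session.skipped = "pitch verification gate failed"
            return session
    else:
        if assigned_f_tp_oct is None:
            raise ValueError("control observers need an assigned f_tp")
        session.f_tp_oct = float(min(assigned_f_tp_oct, limit_oct))

    freq_high = oct_to_khz(session.f_tp_oct)
    freq_low = oct_to_khz(session.f_tp_oct - FREQ_OFFSET_OCT)
    order = ["high", "low"] if alternate_order else ["low", "high"]
    freqs = {"low": freq_low, "high": freq_high}
    for key in order:
        f = freqs[key]
        start = _staircase_start_level(profile, f)
        trace = run_threshold_staircase(
            lambda level: respond_detection(profile, f, level, rng), start
        )
        session.threshold_estimates[key] = trace.estimate
        design1 = design_psychometric_run(
            trace.estimate, seed=int(rng.integers(2**31)), frequency_khz=f
        )
        run1 = simulate_run(design1, profile.params_at(f), rng)
        shift = shift_levels_between_runs(detection_rate(run1))
        design2 = protocols.apply_level_shift(design1, shift, seed=int(rng.integers(2**31)))
        run2 = simulate_run(design2, profile.params_at(f), rng)
        session.runs[key] = [run1, run2]
        try:
            selected, decision = select_or_pool_runs(run1, run2, config.fit, rng=rng)
            session.pooling[key] = decision
            session.fits[key] = fit_psychometric(selected, config.fit)
        except DegenerateFitError as err:
            session.pooling[key] = None
            session.fits[key] = None
            session.gate_reasons += (f"{key}: degenerate fit ({err})",)
    return session


def run_study(
    profiles: Sequence[ObserverProfile],
    config: StudyConfig,
) -> dict:
    """Run the full protocol over a cohort and collect group-level outputs."""
    tinnitus = [p for p in profiles if p.group == "tinnitus"]
    controls = [p for p in profiles if p.group == "control"]
    root = np.random.SeedSequence(config.seed)
    streams = iter(root.spawn(len(profiles) + 1))
    sessions: dict[str, SessionResult] = {}
    for i, p in enumerate(tinnitus):
        rng = np.random.default_rng(next(streams))
        sessions[p.id] = run_full_protocol(p, config, rng, alternate_order=bool(i % 2))
    f_tps = {
        p.id: sessions[p.id].f_tp_oct
        for p in tinnitus
        if sessions[p.id].f_tp_oct is not None
    }
    eligible_t = [p for p in tinnitus if p.id in f_tps and sessions[p.id].eligible]
    assignments = (
        match_controls(eligible_t or tinnitus, controls,
                       f_tps={p.id: f_tps.get(p.id, p.tinnitus_pitch_oct)
                              for p in (eligible_t or tinnitus)})
        if controls else []
    )
    assigned = {a.control_id: a.assigned_f_tp_oct for a in assignments}
    for i, p in enumerate(controls):
        rng = np.random.default_rng(next(streams))
        sessions[p.id] = run_full_protocol(
            p, config, rng, assigned_f_tp_oct=assigned[p.id],
            alternate_order=bool(i % 2),
        )
    summary = summarize_cohort(sessions)
    slope_tests = {}
    for group in ("tinnitus", "control"):
        fits_low = [
            s.fits["low"] for s in sessions.values()
            if s.group == group and s.fits.get("low") is not None
            and s.fits.get("high") is not None
        ]
        fits_high = [
            s.fits["high"] for s in sessions.values()
            if s.group == group and s.fits.get("low") is not None
            and s.fits.get("high") is not None
        ]
        if fits_low:
            slope_tests[group] = slope_difference_posterior_test(
                fits_low, fits_high, config.fit
            )
    return {
        "sessions": sessions,
        "assignments": assignments,
        "summary": summary,
        "slope_difference": slope_tests,
    }


@dataclass(frozen=True)
class SlopeDifferenceResult:
    hdi: tuple[float, float]
    mean_difference: float
    significant: bool
    n_participants: int


def slope_difference_posterior_test(
    fits_low: Sequence[FitResult],
    fits_high: Sequence[FitResult],
    cfg: FitConfig,
    rng: np.random.Generator | None = None,
) -> SlopeDifferenceResult:
    """Posterior of the group-mean slope difference (low minus high frequency).

    Per participant, independent draws from the two slope marginals form a
    difference posterior; averaging across participants per draw gives the
    group-mean difference distribution, summarized by its HDI and whether it
    excludes zero.
    """
    if len(fits_low) != len(fits_high) or not fits_low:
        raise ValueError("need paired low/high fits for at least one participant")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    deltas = np.zeros(cfg.n_draws)
    for flo, fhi in zip(fits_low, fits_high):
        deltas += flo.draw_betas(cfg.n_draws, rng) - fhi.draw_betas(cfg.n_draws, rng)
    deltas /= len(fits_low)
    if np.ptp(deltas) == 0.0:
        val = float(deltas[0])
        return SlopeDifferenceResult(
            (val, val), val, significant=val != 0.0, n_participants=len(fits_low)
        )
    lo, hi = hdi_of_samples(deltas, cfg.hdi_mass)
    return SlopeDifferenceResult(
        (lo, hi), float(deltas.mean()), significant=not (lo <= 0.0 <= hi),
        n_participants=len(fits_low),
    )


@dataclass(frozen=True)
class SimulationGridSpec:
    """Grid of the shift-detectability simulation."""

    slopes: tuple[float, ...] = (0.05, 0.1, 0.2, 0.3, 0.4, 0.5)
    shifts_db: tuple[float, ...] = (0.0, 0.5, 1.0, 1.5, 2.0, 2.5, 3.0)
    replicates: int = 200
    gamma: float = 0.02
    lam: float = 0.005
    majority: float = 0.5

    def __post_init__(self):
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


@dataclass
class SimulationGrid:
    """Results of the detectability simulation (one row per grid cell)."""

    table: pd.DataFrame
    spec: SimulationGridSpec
    seed: int


def _simulation_fit_config(base: FitConfig) -> FitConfig:
    """Fit grids re-centered on the simulation's 0-dB reference midpoint."""
    from dataclasses import replace

    return replace(base, alpha_lo=-15.0, alpha_hi=18.0)


def figure_shift_detectability(
    spec: SimulationGridSpec,
    cfg: FitConfig,
    seed: int = 0,
) -> SimulationGrid:
    """Simulate how well the fit pipeline detects between-run threshold shifts.

    For every (slope, shift) cell: draw pairs of 90-trial runs from Gumbel
    generating functions with midpoints 0 and ``shift`` dB, fit both runs,
    apply the HDI threshold-difference test, and fit the pooled data.  The
    returned table reports the significance rate, the mean fitted shift (MAP
    alphaB − MAP alphaA), and the mean slope bias of the pooled fit per cell.
    """
    sim_cfg = _simulation_fit_config(cfg)
    design = design_psychometric_run(0.0, seed=seed)
    fitter = BatchFitter(sim_cfg, design.finite_levels)
    rows = []
    root = np.random.SeedSequence(seed)
    cell_seeds = root.spawn(len(spec.slopes) * len(spec.shifts_db))
    idx = 0
    n_silence = protocols.SILENCE_REPEATS
    seq = np.array([lv for lv in design.sequence if lv != SILENCE])
    level_index = {lv: i for i, lv in enumerate(fitter.levels)}
    seq_idx = np.array([level_index[lv] for lv in seq])
    n_per_level = np.bincount(seq_idx, minlength=len(fitter.levels)).astype(float)
    for slope in spec.slopes:
        for shift in spec.shifts_db:
            rng = np.random.default_rng(cell_seeds[idx])
            idx += 1
            pa = PsychometricParams(0.0, slope, spec.gamma, spec.lam)
            pb = PsychometricParams(shift, slope, spec.gamma, spec.lam)
            prob_a = gumbel_psi(fitter.levels, pa)[seq_idx]
            prob_b = gumbel_psi(fitter.levels, pb)[seq_idx]
            n_sig = 0
            fitted_shifts = []
            slope_biases = []
            n_failed = 0
            for _ in range(spec.replicates):
                resp_a = rng.random(len(seq)) < prob_a
                resp_b = rng.random(len(seq)) < prob_b
                k_a = np.bincount(seq_idx, weights=resp_a, minlength=len(fitter.levels))
                k_b = np.bincount(seq_idx, weights=resp_b, minlength=len(fitter.levels))
                k0_a = int(np.sum(rng.random(n_silence) < spec.gamma))
                k0_b = int(np.sum(rng.random(n_silence) < spec.gamma))
                try:
                    fit_a = fitter.fit_counts(n_per_level, k_a, n_silence, k0_a, 90)
                    fit_b = fitter.fit_counts(n_per_level, k_b, n_silence, k0_b, 90)
                    test = threshold_difference_test(fit_a, fit_b, sim_cfg, rng=rng)
                    pooled = fitter.fit_counts(
                        2 * n_per_level, k_a + k_b, 2 * n_silence, k0_a + k0_b, 180
                    )
                except (DegenerateFitError, ValueError):
                    n_failed += 1
                    continue
                n_sig += int(test.significant)
                fitted_shifts.append(fit_b.map_params.alpha - fit_a.map_params.alpha)
                slope_biases.append(pooled.map_params.beta - slope)
            n_ok = spec.replicates - n_failed
            rows.append(
                {
                    "slope": slope,
                    "shift_db": shift,
                    "n_replicates": n_ok,
                    "n_failed": n_failed,
                    "significance_rate": n_sig / n_ok if n_ok else float("nan"),
                    "mean_fitted_shift_db": float(np.mean(fitted_shifts)) if fitted_shifts else float("nan"),
                    "mean_slope_bias": float(np.mean(slope_biases)) if slope_biases else float("nan"),
                }
            )
    return SimulationGrid(table=pd.DataFrame(rows), spec=spec, seed=seed)


def smallest_significant_shift(
    grid: SimulationGrid, slope: float
) -> float | None:
    """Smallest shift whose significance rate exceeds the majority criterion."""
    t = grid.table
    sub = t[(t.slope == slope) & (t.significance_rate > grid.spec.majority)]
    if sub.empty:
        return None
    return float(sub.shift_db.min())


def threshold_precision_study(
    n_fits: int,
    cfg: FitConfig,
    seed: int = 0,
    alpha_range: tuple[float, float] = (35.0, 55.0),
    beta_mean: float = 0.14,
    beta_sd: float = 0.04,
    gamma: float = 0.02,
    lam: float = 0.005,
) -> pd.DataFrame:
    """Precision of the threshold estimate under the study's run design.

    Simulates ``n_fits`` datasets, each two pooled 90-trial runs around a
    threshold drawn uniformly from ``alpha_range`` with slopes around
    ``beta_mean``, fits the pooled data, and reports per-fit posterior SD of
    the threshold and the deviation of the MAP threshold from truth.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_fits):
        alpha = rng.uniform(*alpha_range)
        beta = float(np.clip(rng.normal(beta_mean, beta_sd), 0.05, 0.5))
        params = PsychometricParams(alpha, beta, gamma, lam)
        # staircase-like estimate error feeding the design anchor
        estimate = alpha + rng.normal(0.0, 1.0)
        design1 = design_psychometric_run(estimate, seed=int(rng.integers(2**31)))
        run1 = simulate_run(design1, params, rng)
        shift = shift_levels_between_runs(detection_rate(run1))
        design2 = protocols.apply_level_shift(design1, shift, seed=int(rng.integers(2**31)))
        run2 = simulate_run(design2, params, rng)
        try:
            fit = fit_psychometric(run1.pooled_with(run2), cfg)
        except DegenerateFitError:
            continue
        rows.append(
            {
                "true_alpha": alpha,
                "true_beta": beta,
                "map_alpha": fit.map_params.alpha,
                "alpha_sd": fit.alpha_sd,
                "alpha_error": abs(fit.map_params.alpha - alpha),
            }
        )
    return pd.DataFrame(rows)


def summarize_cohort(sessions: dict) -> pd.DataFrame:
    """Descriptive fit summary by group x frequency (no inferential statistics).

    Rows are (group, frequency) cells with mean ± SD of threshold, slope,
    false-alarm rate and lapse rate; empty cells are marked missing.
    """
    rows = []
    for group in ("control", "tinnitus"):
        for freq in ("low", "high"):
            fits = [
                s.fits[freq]
                for s in sessions.values()
                if s.group == group and s.fits.get(freq) is not None
            ]
            row = {"group": group, "frequency": freq, "n": len(fits)}
            if fits:
                for name, vals in (
                    ("threshold", [f.map_params.alpha for f in fits]),
                    ("slope", [f.map_params.beta for f in fits]),
                    ("false_alarm_rate", [f.map_params.gamma for f in fits]),
                    ("lapse_rate", [f.map_params.lam for f in fits]),
                ):
                    row[f"{name}_mean"] = float(np.mean(vals))
                    row[f"{name}_sd"] = float(np.std(vals, ddof=0)) if len(vals) > 1 else 0.0
            else:
                for name in ("threshold", "slope", "false_alarm_rate", "lapse_rate"):
                    row[f"{name}_mean"] = float("nan")
                    row[f"{name}_sd"] = float("nan")
            rows.append(row)
    return pd.DataFrame(rows)
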