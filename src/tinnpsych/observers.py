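"""Virtual participants and their trial-level responses.

Generates cohorts of simulated observers — tinnitus and matched-control — with
the statistical structure the analysis assumes: a sloping high-frequency
audiogram, a hearing limit (the highest frequency audible at 90 dB SPL),
per-frequency Gumbel detection parameters (slope near 0.14 per dB, small
false-alarm and lapse rates), and for the tinnitus group an internal tonal
pitch placed a little below the hearing limit (gap ~ 0.43 ± 0.53 oct,
truncated at zero) with trial-to-trial matching noise.

Audiogram thresholds are stored in dB HL; detection operates in dB SPL.  The
HL→SPL conversion uses an embedded reference-threshold offset table in the
style of the ISO 389 series for circumaural audiometric headphones,
interpolated monotonically on a log-frequency axis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator
from scipy.stats import truncnorm

from .model import SILENCE, PsychometricParams, gumbel_psi
from .staircases import khz_to_oct, oct_to_khz

__all__ = [
    "ObserverProfile",
    "CohortSpec",
    "GroupSpec",
    "make_observer",
    "generate_cohort",
    "respond_detection",
    "respond_pitch_2afc",
    "loudness_match_response",
    "hl_to_spl_offset",
    "AUDIOGRAM_FREQS_KHZ",
    "MAX_LEVEL_DB_SPL",
]

AUDIOGRAM_FREQS_KHZ = (0.25, 0.5, 1.0, 2.0, 4.0, 8.0)
MAX_LEVEL_DB_SPL = 90.0

# Reference-threshold offsets (dB SPL at 0 dB HL), ISO-389-style values for
# circumaural high-frequency audiometric headphones; log-frequency interpolated.
_HL_SPL_TABLE = (
    (0.125, 30.5),
    (0.25, 18.0),
    (0.5, 11.0),
    (1.0, 5.5),
    (2.0, 4.5),
    (4.0, 9.5),
    (8.0, 17.5),
    (10.0, 22.0),
    (12.5, 28.0),
    (14.0, 36.0),
    (16.0, 56.0),
)
_HL_SPL_INTERP = PchipInterpolator(
    np.log2([f for f, _ in _HL_SPL_TABLE]), [o for _, o in _HL_SPL_TABLE]
)


def hl_to_spl_offset(f_khz: float) -> float:
    """dB to add to an HL threshold to express it in SPL at this frequency."""
    return float(_HL_SPL_INTERP(np.log2(np.clip(f_khz, 0.125, 16.0))))


@dataclass(frozen=True)
class ObserverProfile:
    """A virtual participant.

    ``audiogram`` maps (ear, conduction) -> tuple of dB HL thresholds at
    :data:`AUDIOGRAM_FREQS_KHZ`.  Tinnitus attributes are present only for the
    tinnitus group.
    """

    id: str
    group: str  # "tinnitus" or "control"
    age: float
    sex: str  # recorded, no effect on responses
    audiogram: dict
    hearing_limit_khz: float
    beta: float
    gamma: float
    lam: float
    tinnitus_pitch_oct: float | None = None
    pitch_noise_sd_oct: float = 0.15
    tone_jnd_sd_oct: float = 0.02  # perceptual jitter per presented tone
    tinnitus_loudness_sl: float | None = None
    tinnitus_maskable: bool | None = None
    thi_score: float | None = None
    tonality_tone_preference: float = 0.9
    assigned_f_tp_oct: float | None = None  # controls: from the matching step

    def __post_init__(self):
        if self.group not in ("tinnitus", "control"):
            raise ValueError(f"group must be tinnitus or control, got {self.group!r}")
        if self.beta <= 0:
            raise ValueError("slope beta must be positive")
        if not (self.gamma + self.lam < 1):
            raise ValueError("gamma + lambda must be < 1")
        has_tin = self.tinnitus_pitch_oct is not None
        if has_tin != (self.group == "tinnitus"):
            raise ValueError("tinnitus fields present iff group == 'tinnitus'")
        if has_tin and oct_to_khz(self.tinnitus_pitch_oct) > self.hearing_limit_khz + 1e-9:
            raise ValueError("tinnitus pitch must not exceed the hearing limit")

    @property
    def hearing_limit_oct(self) -> float:
        return khz_to_oct(self.hearing_limit_khz)

    def _air_hl(self) -> np.ndarray:
        left = np.asarray(self.audiogram[("left", "air")], dtype=float)
        right = np.asarray(self.audiogram[("right", "air")], dtype=float)
        return 0.5 * (left + right)  # binaural presentation at equal level

    def threshold_spl(self, f_khz: float) -> float:
        """Generating detection threshold (dB SPL) at any frequency.

        Below 8 kHz: monotone (PCHIP) interpolation of the binaural-mean
        audiogram plus the HL→SPL offset.  Between 8 kHz and the hearing
        limit the threshold rises linearly (in octaves) to 90 dB SPL at the
        limit; above the limit it keeps rising, making tones inaudible at the
        maximum presentation level.
        """
        freqs_oct = np.log2(AUDIOGRAM_FREQS_KHZ)
        spl = self._air_hl() + np.array([hl_to_spl_offset(f) for f in AUDIOGRAM_FREQS_KHZ])
        f_oct = khz_to_oct(f_khz)
        spl_8k = float(spl[-1])
        limit_oct = self.hearing_limit_oct
        if f_oct <= freqs_oct[-1]:
            interp = PchipInterpolator(freqs_oct, spl)
            return float(interp(max(f_oct, freqs_oct[0])))
        if limit_oct <= freqs_oct[-1]:
            # degenerate: limit at/below 8 kHz; rise steeply past the limit
            return spl_8k + 60.0 * (f_oct - freqs_oct[-1])
        frac = (f_oct - freqs_oct[-1]) / (limit_oct - freqs_oct[-1])
        return spl_8k + frac * (MAX_LEVEL_DB_SPL - spl_8k)

    def params_at(self, f_khz: float) -> PsychometricParams:
        return PsychometricParams(
            alpha=self.threshold_spl(f_khz), beta=self.beta,
            gamma=self.gamma, lam=self.lam,
        )

    def audiogram_frame(self) -> pd.DataFrame:
        rows = []
        for (ear, conduction), thresholds in sorted(self.audiogram.items()):
            freqs = AUDIOGRAM_FREQS_KHZ if conduction == "air" else AUDIOGRAM_FREQS_KHZ[1:5]
            for f, t in zip(freqs, thresholds):
                rows.append(
                    {"frequency_khz": f, "ear": ear, "conduction": conduction,
                     "threshold_db_hl": float(t)}
                )
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class GroupSpec:
    """Target moments of one group (study-cohort conditions by default)."""

    n: int = 18
    age_mean: float = 55.0
    age_sd: float = 10.0
    male_fraction: float = 0.9
    hf_loss_mean: float = 32.0  # mean of 4 & 8 kHz HL, both ears
    hf_loss_sd: float = 13.0
    hearing_limit_mean_khz: float = 11.7
    hearing_limit_sd_khz: float = 2.2
    beta_mean: float = 0.14
    beta_sd: float = 0.04
    gamma_mean: float = 0.03
    gamma_sd: float = 0.025
    lambda_mean: float = 0.005
    lambda_sd: float = 0.004
    pitch_gap_mean_oct: float = 0.43
    pitch_gap_sd_oct: float = 0.53
    pitch_noise_sd_oct: float = 0.15
    thi_mean: float = 40.0
    thi_sd: float = 20.0

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("group size must be >= 1")
        for name in ("age_sd", "hf_loss_sd", "beta_sd", "pitch_gap_sd_oct"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class CohortSpec:
    """Group sizes and distributions for a synthetic cohort."""

    tinnitus: GroupSpec = field(
        default_factory=lambda: GroupSpec(
            age_mean=53.8, age_sd=11.0, male_fraction=17 / 18,
            hf_loss_mean=36.1, hf_loss_sd=14.5,
            hearing_limit_mean_khz=11.5, hearing_limit_sd_khz=2.4,
        )
    )
    control: GroupSpec = field(
        default_factory=lambda: GroupSpec(
            age_mean=57.5, age_sd=8.1, male_fraction=16 / 18,
            hf_loss_mean=27.6, hf_loss_sd=11.3,
            hearing_limit_mean_khz=11.9, hearing_limit_sd_khz=1.9,
        )
    )
    seed: int = 0


def _truncated_normal(rng, mean, sd, lo, hi):
    if sd <= 0:
        return float(np.clip(mean, lo, hi))
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return float(truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng))


def make_observer(
    spec: CohortSpec, group: str, rng: np.random.Generator, id: str | None = None
) -> ObserverProfile:
    """Sample one virtual participant from the cohort distributions.

    The audiogram is flat at a low-frequency base level and rises toward high
    frequencies so that the 4–8 kHz mean matches the group's high-frequency
    loss target; the tinnitus pitch sits below the hearing limit by a
    truncated-normal gap (mean 0.43, SD 0.53 octaves, >= 0).
    """
    g: GroupSpec = getattr(spec, group)
    age = _truncated_normal(rng, g.age_mean, g.age_sd, 18, 70)
    sex = "M" if rng.random() < g.male_fraction else "F"
    base = _truncated_normal(rng, 10.0, 5.0, -5.0, 25.0)
    hf_loss = _truncated_normal(rng, g.hf_loss_mean, g.hf_loss_sd, max(base, 5.0), 65.0)
    spread = rng.uniform(2.0, 10.0)  # hl(8k) - hl(4k) around the 4-8 kHz mean
    hl4 = max(base, hf_loss - 0.5 * spread)
    hl8 = hf_loss + 0.5 * spread
    hl2 = base + 0.3 * max(hl4 - base, 0.0)
    shape = np.array([base, base, base, hl2, hl4, hl8])
    audiogram = {}
    asym = rng.normal(0.0, 1.5)  # small, symmetric-criterion-compatible
    for ear, sign in (("left", 1.0), ("right", -1.0)):
        air = np.maximum.accumulate(
            np.round((shape + sign * asym + rng.normal(0, 1.5, size=6)) / 5) * 5
        )
        bone = air[1:5] - np.abs(np.round(rng.normal(0, 1.0, size=4)))
        audiogram[(ear, "air")] = tuple(air)
        audiogram[(ear, "bone")] = tuple(bone)
    limit = _truncated_normal(
        rng, g.hearing_limit_mean_khz, g.hearing_limit_sd_khz, 8.3, 16.0
    )
    beta = _truncated_normal(rng, g.beta_mean, g.beta_sd, 0.03, 0.6)
    gamma = _truncated_normal(rng, g.gamma_mean, g.gamma_sd, 0.001, 0.2)
    lam = _truncated_normal(rng, g.lambda_mean, g.lambda_sd, 1e-4, 0.05)
    kwargs: dict = {}
    if group == "tinnitus":
        gap = _truncated_normal(rng, g.pitch_gap_mean_oct, g.pitch_gap_sd_oct, 0.0, 4.0)
        kwargs = {
            "tinnitus_pitch_oct": khz_to_oct(limit) - gap,
            "pitch_noise_sd_oct": g.pitch_noise_sd_oct,
            "tinnitus_loudness_sl": float(rng.uniform(5.0, 10.0)),
            "tinnitus_maskable": True,
            "thi_score": _truncated_normal(rng, g.thi_mean, g.thi_sd, 2.0, 77.0),
        }
    return ObserverProfile(
        id=id or f"{group[:1].upper()}{rng.integers(1e6):06d}",
        group=group,
        age=age,
        sex=sex,
        audiogram=audiogram,
        hearing_limit_khz=limit,
        beta=beta,
        gamma=gamma,
        lam=lam,
        **kwargs,
    )


def generate_cohort(spec: CohortSpec) -> list[ObserverProfile]:
    """Generate the full cohort (tinnitus group first), seeded from the spec."""
    root = np.random.SeedSequence(spec.seed)
    profiles: list[ObserverProfile] = []
    streams = root.spawn(spec.tinnitus.n + spec.control.n)
    k = 0
    for group, g in (("tinnitus", spec.tinnitus), ("control", spec.control)):
        prefix = "T" if group == "tinnitus" else "C"
        for i in range(g.n):
            rng = np.random.default_rng(streams[k])
            k += 1
            profiles.append(make_observer(spec, group, rng, id=f"{prefix}{i + 1:02d}"))
    return profiles


def respond_detection(
    profile: ObserverProfile, frequency_khz: float, level_db: float,
    rng: np.random.Generator,
) -> bool:
    """Bernoulli yes/no response drawn from the observer's detection curve.

    Silence trials are detected with probability gamma (false alarms).
    """
    p = gumbel_psi(level_db, profile.params_at(frequency_khz))
    return bool(rng.random() < p)


def respond_pitch_2afc(
    profile: ObserverProfile, f1_oct: float, f2_oct: float,
    rng: np.random.Generator,
) -> str:
    """2-AFC pitch choice: the tone nearer the noisy internal pitch.

    The internal pitch is jittered by Gaussian matching noise each trial, and
    each presented tone is perceived with a small frequency jitter (a
    difference limen), so near-identical tones are discriminated at chance;
    exact ties are broken uniformly.  Returns ``"low"`` or ``"high"`` for the
    lower/higher of the two tones.
    """
    if profile.tinnitus_pitch_oct is None:
        raise ValueError(f"observer {profile.id} has no tinnitus pitch")
    lo, hi = min(f1_oct, f2_oct), max(f1_oct, f2_oct)
    pitch = profile.tinnitus_pitch_oct + rng.normal(0.0, profile.pitch_noise_sd_oct)
    jnd = profile.tone_jnd_sd_oct
    d_lo = abs(lo + rng.normal(0.0, jnd) - pitch)
    d_hi = abs(hi + rng.normal(0.0, jnd) - pitch)
    if d_lo == d_hi:
        return "low" if rng.random() < 0.5 else "high"
    return "low" if d_lo < d_hi else "high"


def loudness_match_response(profile: ObserverProfile, frequency_khz: float) -> float | None:
    """Level (dB SPL) the observer sets in the loudness-matching test.

    Tinnitus observers set the tone to their tinnitus loudness (threshold +
    5–10 dB SL); controls set a just-audible level, modeled as the threshold.
    Returns ``None`` when the frequency is inaudible at the 90 dB SPL cap.
    """
    thr = profile.threshold_spl(frequency_khz)
    if thr > MAX_LEVEL_DB_SPL:
        return None
    if profile.group == "tinnitus":
        return float(min(thr + profile.tinnitus_loudness_sl, MAX_LEVEL_DB_SPL))
    return float(min(thr, MAX_LEVEL_DB_SPL))
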