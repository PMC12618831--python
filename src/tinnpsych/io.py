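"""Readers and writers for the package's tabular and JSON formats.

CSV formats: trial tables (``trial_index, block, level_db, response``,
with silence levels written as the string ``SILENCE``), audiograms
(``frequency_khz, ear, conduction, threshold_db_hl``), cohort rosters, and
simulation grids.  JSON formats: observer profiles, session records, fits and
staircase traces.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .model import SILENCE, FitResult, RunData, Trial
from .observers import AUDIOGRAM_FREQS_KHZ, CohortSpec, GroupSpec, ObserverProfile
from .staircases import StaircaseTrace

__all__ = [
    "run_to_frame",
    "run_from_frame",
    "write_run_csv",
    "read_run_csv",
    "fit_to_dict",
    "write_fit_json",
    "trace_to_dict",
    "write_trace_json",
    "profile_to_dict",
    "profile_from_dict",
    "write_profiles_json",
    "read_profiles_json",
    "roster_frame",
    "write_audiogram_csv",
    "read_audiogram_csv",
    "load_cohort_spec",
]

_SILENCE_TOKEN = "SILENCE"


def run_to_frame(run: RunData) -> pd.DataFrame:
    rows = [
        {
            "trial_index": i,
            "block": t.block,
            "level_db": _SILENCE_TOKEN if t.level == SILENCE else t.level,
            "response": int(t.response),
        }
        for i, t in enumerate(run.trials)
    ]
    frame = pd.DataFrame(rows, columns=["trial_index", "block", "level_db", "response"])
    frame.attrs["frequency_khz"] = run.frequency_khz
    return frame


def run_from_frame(frame: pd.DataFrame, frequency_khz: float) -> RunData:
    trials = []
    for _, row in frame.sort_values("trial_index").iterrows():
        raw = row["level_db"]
        level = SILENCE if str(raw).strip().upper() == _SILENCE_TOKEN else float(raw)
        trials.append(Trial(level=level, response=bool(int(row["response"])), block=int(row["block"])))
    return RunData(frequency_khz, trials)


def write_run_csv(run: RunData, path: str | Path) -> None:
    frame = run_to_frame(run)
    with open(path, "w") as fh:
        fh.write(f"# frequency_khz={run.frequency_khz}\n")
        frame.to_csv(fh, index=False)


def read_run_csv(path: str | Path) -> RunData:
    path = Path(path)
    frequency = None
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#") and "frequency_khz=" in first:
            frequency = float(first.split("=", 1)[1])
    frame = pd.read_csv(path, comment="#")
    if frequency is None:
        raise ValueError(f"{path}: missing '# frequency_khz=' header line")
    return run_from_frame(frame, frequency)


def fit_to_dict(fit: FitResult) -> dict:
    return {
        "map_params": {
            "alpha": fit.map_params.alpha,
            "beta": fit.map_params.beta,
            "gamma": fit.map_params.gamma,
            "lambda": fit.map_params.lam,
        },
        "alpha_hdi": list(fit.alpha_hdi),
        "beta_hdi": list(fit.beta_hdi),
        "alpha_sd": fit.alpha_sd,
        "alpha_mean": fit.alpha_mean,
        "beta_mean": fit.beta_mean,
        "log_likelihood_map": fit.log_likelihood_map,
        "n_trials": fit.n_trials,
        "at_boundary": fit.at_boundary,
        "hdi_flags": list(fit.hdi_flags),
    }


def write_fit_json(fit: FitResult, path: str | Path) -> None:
    Path(path).write_text(json.dumps(fit_to_dict(fit), indent=2))


def trace_to_dict(trace: StaircaseTrace) -> dict:
    return {
        "trials": [asdict(t) for t in trace.trials],
        "reversal_indices": list(trace.reversal_indices),
        "estimate": trace.estimate,
        "termination": trace.termination,
        "units": trace.units,
    }


def write_trace_json(trace: StaircaseTrace, path: str | Path) -> None:
    Path(path).write_text(json.dumps(trace_to_dict(trace), indent=2))


def profile_to_dict(p: ObserverProfile) -> dict:
    d = {
        "id": p.id,
        "group": p.group,
        "age": p.age,
        "sex": p.sex,
        "audiogram": {f"{ear}/{cond}": list(v) for (ear, cond), v in p.audiogram.items()},
        "hearing_limit_khz": p.hearing_limit_khz,
        "beta": p.beta,
        "gamma": p.gamma,
        "lambda": p.lam,
        "pitch_noise_sd_oct": p.pitch_noise_sd_oct,
        "tone_jnd_sd_oct": p.tone_jnd_sd_oct,
        "tonality_tone_preference": p.tonality_tone_preference,
    }
    if p.group == "tinnitus":
        d.update(
            tinnitus_pitch_oct=p.tinnitus_pitch_oct,
            tinnitus_loudness_sl=p.tinnitus_loudness_sl,
            tinnitus_maskable=p.tinnitus_maskable,
            thi_score=p.thi_score,
        )
    if p.assigned_f_tp_oct is not None:
        d["assigned_f_tp_oct"] = p.assigned_f_tp_oct
    return d


def profile_from_dict(d: dict) -> ObserverProfile:
    audiogram = {}
    for key, vals in d["audiogram"].items():
        ear, cond = key.split("/")
        audiogram[(ear, cond)] = tuple(vals)
    return ObserverProfile(
        id=d["id"],
        group=d["group"],
        age=d["age"],
        sex=d["sex"],
        audiogram=audiogram,
        hearing_limit_khz=d["hearing_limit_khz"],
        beta=d["beta"],
        gamma=d["gamma"],
        lam=d["lambda"],
        tinnitus_pitch_oct=d.get("tinnitus_pitch_oct"),
        pitch_noise_sd_oct=d.get("pitch_noise_sd_oct", 0.15),
        tone_jnd_sd_oct=d.get("tone_jnd_sd_oct", 0.02),
        tinnitus_loudness_sl=d.get("tinnitus_loudness_sl"),
        tinnitus_maskable=d.get("tinnitus_maskable"),
        thi_score=d.get("thi_score"),
        tonality_tone_preference=d.get("tonality_tone_preference", 0.9),
        assigned_f_tp_oct=d.get("assigned_f_tp_oct"),
    )


def write_profiles_json(profiles: Sequence[ObserverProfile], path: str | Path) -> None:
    Path(path).write_text(json.dumps([profile_to_dict(p) for p in profiles], indent=2))


def read_profiles_json(path: str | Path) -> list[ObserverProfile]:
    return [profile_from_dict(d) for d in json.loads(Path(path).read_text())]


def roster_frame(profiles: Sequence[ObserverProfile]) -> pd.DataFrame:
    """Flat cohort roster with one row per participant."""
    rows = []
    for p in profiles:
        rows.append(
            {
                "id": p.id,
                "group": p.group,
                "age": round(p.age, 1),
                "sex": p.sex,
                "hearing_limit_khz": round(p.hearing_limit_khz, 2),
                "beta": round(p.beta, 4),
                "gamma": round(p.gamma, 4),
                "lambda": round(p.lam, 5),
                "tinnitus_pitch_oct": (
                    round(p.tinnitus_pitch_oct, 3) if p.tinnitus_pitch_oct is not None else ""
                ),
                "thi_score": round(p.thi_score, 1) if p.thi_score is not None else "",
            }
        )
    return pd.DataFrame(rows)


def write_audiogram_csv(profile: ObserverProfile, path: str | Path) -> None:
    profile.audiogram_frame().to_csv(path, index=False)


def read_audiogram_csv(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    required = {"frequency_khz", "ear", "conduction", "threshold_db_hl"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: audiogram CSV missing columns {sorted(missing)}")
    return frame


def load_cohort_spec(path: str | Path) -> CohortSpec:
    """Read a cohort spec from a flat YAML config.

    Top-level keys: ``seed`` plus optional ``tinnitus:`` / ``control:``
    mappings overriding :class:`GroupSpec` fields.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    unknown = set(raw) - {"seed", "tinnitus", "control"}
    if unknown:
        raise ValueError(f"unknown cohort-spec keys: {sorted(unknown)}")
    groups = {}
    for name in ("tinnitus", "control"):
        overrides = raw.get(name, {}) or {}
        valid = set(GroupSpec.__dataclass_fields__)
        bad = set(overrides) - valid
        if bad:
            raise ValueError(f"unknown {name} group-spec keys: {sorted(bad)}")
        defaults = getattr(CohortSpec(), name)
        groups[name] = GroupSpec(**{**asdict(defaults), **overrides})
    return CohortSpec(
        tinnitus=groups["tinnitus"], control=groups["control"], seed=int(raw.get("seed", 0))
    )
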