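"""Session directory format and pipeline configuration.

A session is a directory of inspectable text files:

* ``eye_trace.csv`` — ``t_ms, x_deg, y_deg``
* ``trials.csv`` — ``trial, trial_onset, target_jump_time, target_pos_deg,
  fixation_pos_deg, reward``
* ``cs_spikes.csv`` — ``time_ms, duration_ms`` (duration column optional;
  without it the CS-duration analyses refuse to run)
* ``ss_spikes.csv`` — ``time_ms``
* ``metadata.json`` — monkey/session ids, CF direction, sampling rate

All times are ms from session start; positions are deg, rightward positive.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = ["Session", "SessionFormatError", "read_session", "write_session",
           "PipelineConfig"]

TRIAL_COLUMNS = ["trial", "trial_onset", "target_jump_time",
                 "target_pos_deg", "fixation_pos_deg", "reward"]


class SessionFormatError(ValueError):
    """A session directory violates the on-disk schema."""


@dataclass
class Session:
    time_ms: np.ndarray
    horizontal_deg: np.ndarray
    vertical_deg: np.ndarray
    trials: pd.DataFrame
    cs: pd.DataFrame              # time_ms [, duration_ms]
    ss_times: np.ndarray
    metadata: dict

    @property
    def cs_durations_available(self) -> bool:
        return "duration_ms" in self.cs.columns \
            and self.cs["duration_ms"].notna().all()

    @property
    def sampling_rate(self) -> float:
        return float(self.metadata.get("sampling_rate", 1000.0))


def write_session(session: Session, path: str | Path) -> Path:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"t_ms": session.time_ms, "x_deg": session.horizontal_deg,
                  "y_deg": session.vertical_deg}).to_csv(
        path / "eye_trace.csv", index=False, float_format="%.6f")
    session.trials.to_csv(path / "trials.csv", index=False)
    session.cs.to_csv(path / "cs_spikes.csv", index=False)
    pd.DataFrame({"time_ms": session.ss_times}).to_csv(
        path / "ss_spikes.csv", index=False)
    (path / "metadata.json").write_text(
        json.dumps(session.metadata, indent=2, sort_keys=True))
    return path


def _require(path: Path):
    if not path.exists():
        raise SessionFormatError(f"missing required file: {path.name}")
    return path


def read_session(path: str | Path) -> Session:
    path = Path(path)
    trace = pd.read_csv(_require(path / "eye_trace.csv"))
    for col in ("t_ms", "x_deg", "y_deg"):
        if col not in trace.columns:
            raise SessionFormatError(f"eye_trace.csv lacks column {col!r}")
    t = trace["t_ms"].to_numpy(dtype=float)
    if t.size < 2 or np.any(np.diff(t) <= 0):
        raise SessionFormatError("eye_trace.csv: time must be strictly increasing")

    trials = pd.read_csv(_require(path / "trials.csv"))
    for col in TRIAL_COLUMNS:
        if col not in trials.columns:
            raise SessionFormatError(f"trials.csv lacks column {col!r}")
    if np.any(trials["trial_onset"].to_numpy()
              >= trials["target_jump_time"].to_numpy()):
        raise SessionFormatError("trials.csv: trial_onset must precede "
                                 "target_jump_time")

    cs = pd.read_csv(_require(path / "cs_spikes.csv"))
    if "time_ms" not in cs.columns:
        raise SessionFormatError("cs_spikes.csv lacks column 'time_ms'")
    ss = pd.read_csv(_require(path / "ss_spikes.csv"))
    if "time_ms" not in ss.columns:
        raise SessionFormatError("ss_spikes.csv lacks column 'time_ms'")

    meta = json.loads(_require(path / "metadata.json").read_text())
    if meta.get("cf_direction") not in ("left", "right"):
        raise SessionFormatError("metadata.json: cf_direction must be "
                                 "'left' or 'right'")
    span = (t[0], t[-1])
    for name, times in (("cs_spikes", cs["time_ms"]), ("ss_spikes", ss["time_ms"])):
        tv = times.to_numpy(dtype=float)
        if tv.size and (tv.min() < span[0] or tv.max() > span[1]):
            raise SessionFormatError(f"{name}.csv: spike times outside the "
                                     "eye-trace span")
    fs = float(meta.get("sampling_rate", 1000.0))
    if not np.isclose(np.median(np.diff(t)), 1000.0 / fs, rtol=1e-3):
        raise SessionFormatError("metadata sampling_rate inconsistent with "
                                 "eye-trace step")
    return Session(time_ms=t, horizontal_deg=trace["x_deg"].to_numpy(float),
                   vertical_deg=trace["y_deg"].to_numpy(float), trials=trials,
                   cs=cs, ss_times=ss["time_ms"].to_numpy(float),
                   metadata=meta)


@dataclass
class PipelineConfig:
    """All tunables of the analysis pipeline with their canonical defaults."""

    smoothing_cutoff_hz: float = 80.0
    kernel_sd_ms: float = 5.0
    amplitude_bin_deg: float = 0.5
    amplitude_range_deg: tuple[float, float] = (13.0, 16.0)
    duration_bin_ms: float = 5.0
    duration_range_ms: tuple[float, float] = (35.0, 65.0)
    error_bin_deg: float = 0.5
    error_range_deg: tuple[float, float] = (-2.0, 2.0)
    min_events_per_bin: int = 10
    peak_bootstrap_cells: int = 50
    peak_bootstrap_min_trials: int = 10
    peak_bootstrap_reps: int = 1000
    trough_bootstrap_trials: int = 1000
    trough_bootstrap_reps: int = 1000
    alignment_window_ms: tuple[float, float] = (-300.0, 500.0)
    fatigue_edge_trials: int = 30
    seed: int = 0

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        data = (json.loads(text) if path.suffix == ".json"
                else yaml.safe_load(text))
        cfg = cls(**{k: tuple(v) if isinstance(getattr(cls(), k), tuple) else v
                     for k, v in data.items()})
        cfg.validate()
        return cfg

    def validate(self) -> None:
        for name in ("amplitude_range_deg", "duration_range_ms",
                     "error_range_deg", "alignment_window_ms"):
            lo, hi = getattr(self, name)
            if lo >= hi:
                raise ValueError(f"{name}: window must be increasing")
        if self.kernel_sd_ms <= 0:
            raise ValueError("kernel_sd_ms must be > 0")
        if int(self.seed) != self.seed:
            raise ValueError("seed must be an integer")

    def to_dict(self) -> dict:
        return {k: list(v) if isinstance(v, tuple) else v
                for k, v in asdict(self).items()}

    def content_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]
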