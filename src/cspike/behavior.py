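"""Saccade detection, kinematics, error labeling, and fatigue summaries.

Primary saccades (13–17 deg) are detected as maximal runs of eye velocity
exceeding 30 deg/s; corrective saccades (0.2–2 deg, duration > 10 ms) with a
more lenient 10 deg/s threshold between consecutive primaries.  Only the
horizontal channel enters amplitudes and directions: the task is purely
horizontal, so directions fall into two 180-degree classes.

The signed retinal error of a primary saccade is the vector from its endpoint
to the goal (target for CF, fixation dot for CP); rightward errors are
positive.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

log = logging.getLogger(__name__)

__all__ = [
    "PRIMARY_VELOCITY_THRESHOLD",
    "CORRECTIVE_VELOCITY_THRESHOLD",
    "compute_velocity",
    "detect_primary_saccades",
    "detect_corrective_saccades",
    "classify_and_error",
    "detect_events",
    "fatigue_summary",
]

PRIMARY_VELOCITY_THRESHOLD = 30.0    # deg/s
CORRECTIVE_VELOCITY_THRESHOLD = 10.0  # deg/s
PRIMARY_AMPLITUDE_RANGE = (13.0, 17.0)   # deg
CORRECTIVE_AMPLITUDE_RANGE = (0.2, 2.0)  # deg
CORRECTIVE_MIN_DURATION = 10.0  # ms, strict
MERGE_GAP = 10.0  # ms: suprathreshold runs closer than this are merged

EVENT_COLUMNS = ["onset", "offset", "amplitude", "duration", "peak_velocity",
                 "direction", "type", "subtype", "start_pos", "end_pos",
                 "signed_error", "assoc_trial"]


def smooth_position(time_ms: np.ndarray, position_deg: np.ndarray,
                    smoothing_cutoff: float = 80.0) -> np.ndarray:
    """Zero-phase low-pass filtered eye position.

    The default 80 Hz cutoff preserves the ~40 ms primary-saccade profile
    while suppressing sample noise.
    """
    dt = np.diff(time_ms)
    if time_ms.size < 2 or not np.allclose(dt, dt[0]):
        raise ValueError("eye trace must be uniformly sampled")
    fs = 1000.0 / dt[0]
    if smoothing_cutoff is None or smoothing_cutoff >= fs / 2:
        return np.asarray(position_deg, dtype=float)
    sos = signal.butter(4, smoothing_cutoff, fs=fs, output="sos")
    padlen = 3 * 2 * 4
    if position_deg.size <= padlen:
        raise ValueError("trace shorter than filter warm-up")
    return signal.sosfiltfilt(sos, position_deg)


def compute_velocity(time_ms: np.ndarray, position_deg: np.ndarray,
                     smoothing_cutoff: float = 80.0) -> np.ndarray:
    """Central-difference eye velocity (deg/s), zero-phase low-pass filtered.

    Filtering (zero-phase) and differentiation commute; the position is
    smoothed first so the same filtered trace can supply saccade endpoints.
    """
    xs = smooth_position(time_ms, position_deg, smoothing_cutoff)
    return np.gradient(xs, time_ms) * 1000.0  # deg/ms -> deg/s


def _threshold_runs(time_ms, velocity, threshold):
    """Maximal runs of |velocity| >= threshold, gaps < MERGE_GAP merged.

    Runs touching the trace boundaries are discarded (clipped events).
    Returns a list of (i_on, i_off) inclusive sample index pairs.
    """
    above = np.abs(velocity) >= threshold
    if not above.any():
        return []
    d = np.diff(above.astype(int))
    starts = list(np.flatnonzero(d == 1) + 1)
    ends = list(np.flatnonzero(d == -1))
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(above.size - 1)
    runs = list(zip(starts, ends))
    merged = [runs[0]]
    for s, e in runs[1:]:
        if time_ms[s] - time_ms[merged[-1][1]] < MERGE_GAP:
            merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    return [(s, e) for s, e in merged if s > 0 and e < above.size - 1]


def _runs_to_events(time_ms, position, velocity, runs, amp_range,
                    min_duration=0.0):
    rows = []
    for s, e in runs:
        onset, offset = time_ms[s], time_ms[e]
        duration = offset - onset
        if duration <= min_duration:
            continue
        start_pos, end_pos = position[s], position[e]
        amplitude = abs(end_pos - start_pos)
        if not (amp_range[0] <= amplitude <= amp_range[1]):
            continue
        rows.append(dict(
            onset=onset, offset=offset, amplitude=amplitude,
            duration=duration,
            peak_velocity=float(np.max(np.abs(velocity[s:e + 1]))),
            direction=int(np.sign(end_pos - start_pos)),
            type="primary", subtype="none",
            start_pos=start_pos, end_pos=end_pos,
            signed_error=np.nan, assoc_trial=-1,
        ))
    return pd.DataFrame(rows, columns=EVENT_COLUMNS)


def detect_primary_saccades(time_ms, position, velocity) -> pd.DataFrame:
    """Detect 13–17 deg primary saccades at the 30 deg/s velocity threshold."""
    runs = _threshold_runs(time_ms, velocity, PRIMARY_VELOCITY_THRESHOLD)
    return _runs_to_events(time_ms, position, velocity, runs,
                           PRIMARY_AMPLITUDE_RANGE)


def detect_corrective_saccades(time_ms, position, velocity,
                               primary: pd.DataFrame) -> pd.DataFrame:
    """Detect 0.2–2 deg corrective saccades between consecutive primaries.

    Threshold 10 deg/s, duration strictly greater than 10 ms; runs
    overlapping a primary saccade are excluded.
    """
    runs = _threshold_runs(time_ms, velocity, CORRECTIVE_VELOCITY_THRESHOLD)
    ev = _runs_to_events(time_ms, position, velocity, runs,
                         CORRECTIVE_AMPLITUDE_RANGE,
                         min_duration=CORRECTIVE_MIN_DURATION)
    if ev.empty or primary.empty:
        ev["type"] = "corrective"
        return ev
    p_on = primary["onset"].to_numpy()
    p_off = primary["offset"].to_numpy()
    keep = []
    for row in ev.itertuples():
        overlaps = np.any((row.onset < p_off) & (row.offset > p_on))
        if overlaps:
            keep.append(False)
            continue
        i = np.searchsorted(p_off, row.onset) - 1
        after_primary = i >= 0
        before_next = i + 1 >= p_on.size or row.offset < p_on[i + 1]
        keep.append(after_primary and before_next)
    ev = ev[np.array(keep, dtype=bool)].copy()
    ev["type"] = "corrective"
    return ev.reset_index(drop=True)


def classify_and_error(events: pd.DataFrame, trials: pd.DataFrame,
                       eccentricity: float | None = None) -> pd.DataFrame:
    """Label primaries as CF/CP and attach signed retinal errors.

    CF = toward the eccentric target after the go-signal; CP = return toward
    the fixation dot.  ``signed_error = goal - end_pos`` (rightward positive).
    Classification is positional: a primary starting near the center and
    ending near the target is CF, the reverse is CP.  A primary with no
    bracketing trial is labeled ``none`` with a warning.  Corrective saccades
    inherit the goal of the nearest preceding primary.
    """
    events = events.sort_values("onset").reset_index(drop=True).copy()
    if eccentricity is None:
        eccentricity = float(np.abs(trials["target_pos_deg"]).max())
    onsets = trials["trial_onset"].to_numpy()
    targets = trials["target_pos_deg"].to_numpy()
    half = eccentricity / 2.0

    goals = np.full(len(events), np.nan)
    for i, row in enumerate(events.itertuples()):
        k = np.searchsorted(onsets, row.onset) - 1
        if k < 0 or (k + 1 < onsets.size
                     and row.onset >= onsets[k + 1]):  # pragma: no cover
            k = -1
        if row.type == "primary":
            if k < 0:
                warnings.warn(f"primary saccade at {row.onset:.0f} ms has no "
                              "bracketing trial; labeled none")
                continue
            target = targets[k]
            if abs(row.start_pos) < half and abs(row.end_pos - target) < half:
                events.loc[i, "subtype"] = "CF"
                goals[i] = target
            elif abs(row.start_pos - target) < half and abs(row.end_pos) < half:
                events.loc[i, "subtype"] = "CP"
                goals[i] = 0.0
            else:
                warnings.warn(f"primary saccade at {row.onset:.0f} ms matches "
                              "neither CF nor CP geometry; labeled none")
                continue
            events.loc[i, "assoc_trial"] = k
            events.loc[i, "signed_error"] = goals[i] - row.end_pos
        else:
            prev = events.index[(events["type"] == "primary")
                                & (events["onset"] < row.onset)]
            if len(prev) and np.isfinite(goals[prev[-1]]):
                g = goals[prev[-1]]
                events.loc[i, "assoc_trial"] = events.loc[prev[-1], "assoc_trial"]
                events.loc[i, "signed_error"] = g - row.end_pos
    return events


def detect_events(session, smoothing_cutoff: float = 80.0) -> pd.DataFrame:
    """Full detection chain on a :class:`cspike.io.Session`."""
    xs = smooth_position(session.time_ms, session.horizontal_deg,
                         smoothing_cutoff)
    v = np.gradient(xs, session.time_ms) * 1000.0
    prim = detect_primary_saccades(session.time_ms, xs, v)
    corr = detect_corrective_saccades(session.time_ms, xs, v, prim)
    events = pd.concat([prim, corr], ignore_index=True)
    return classify_and_error(events, session.trials)


@dataclass
class FatigueSummary:
    per_session: pd.DataFrame
    pooled: pd.DataFrame


def fatigue_summary(event_tables: list[pd.DataFrame],
                    n_edge_trials: int = 30) -> FatigueSummary:
    """Early/late medians of primary-saccade kinematics and percent change.

    For each session and each primary subtype (CF, CP), compares the first
    and last ``n_edge_trials`` saccades:
    ``percent change = 100 * (early_median - late_median) / early_median``
    for peak velocity, and analogously for duration and amplitude (so a
    fatigue-driven duration increase appears as a negative duration change).
    Sessions with fewer than ``2 * n_edge_trials`` saccades of a subtype are
    skipped with a log entry.
    """
    rows = []
    for si, ev in enumerate(event_tables):
        prim = ev[(ev["type"] == "primary") & ev["subtype"].isin(["CF", "CP"])]
        for subtype, grp in prim.groupby("subtype"):
            grp = grp.sort_values("onset")
            if len(grp) < 2 * n_edge_trials:
                log.info("session %d: %d %s saccades < %d, skipped",
                         si, len(grp), subtype, 2 * n_edge_trials)
                continue
            early = grp.head(n_edge_trials)
            late = grp.tail(n_edge_trials)
            row = dict(session=si, subtype=subtype)
            for var in ("peak_velocity", "duration", "amplitude"):
                e, l = early[var].median(), late[var].median()
                row[f"early_{var}"] = e
                row[f"late_{var}"] = l
                row[f"pct_change_{var}"] = 100.0 * (e - l) / e
            rows.append(row)
    per_session = pd.DataFrame(rows)
    if per_session.empty:
        return FatigueSummary(per_session, pd.DataFrame())
    pooled = per_session.groupby("subtype").median(numeric_only=True)
    pooled = pooled.drop(columns=["session"], errors="ignore").reset_index()
    return FatigueSummary(per_session, pooled)
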