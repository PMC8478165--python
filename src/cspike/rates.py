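"""Event-locked spike alignment and Gaussian-kernel firing-rate estimation.

Rates are estimated by convolving each spike with a normalized Gaussian
kernel of 5 ms standard deviation (unit area, so integrating the rate of a
single spike over time gives exactly one spike).  Population responses are
the pointwise mean of the per-cell average rates.

All windows are half-open ``[start, end)`` in ms relative to the alignment
event at time 0; the rate grid has 1 ms steps and kernels are truncated at
±5 sigma.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .windows import ALIGNMENTS

KERNEL_SD = 5.0   # ms
GRID_STEP = 1.0   # ms
KERNEL_TRUNC = 5  # in units of sigma

__all__ = ["AlignedSpikes", "RateProfile", "kernel_rate", "align",
           "window_stat", "population_average", "make_grid"]


def make_grid(window: tuple[float, float], step: float = GRID_STEP) -> np.ndarray:
    """Uniform time grid covering a peri-event window (end exclusive)."""
    return np.arange(window[0], window[1], step)


@dataclass
class AlignedSpikes:
    """Spike offsets relative to a set of alignment events.

    ``offsets[i]`` holds the spike times (ms, relative to event i) falling in
    the half-open peri-event ``window``; ``events`` carries one row of
    covariates per event (amplitude, duration, signed_error, direction, ...).
    ``extras[i]`` optionally carries per-spike payloads (e.g. CS durations)
    parallel to ``offsets[i]``.
    """

    offsets: list[np.ndarray]
    events: pd.DataFrame
    alignment: str
    window: tuple[float, float]
    extras: list[np.ndarray] | None = None

    @property
    def n_events(self) -> int:
        return len(self.offsets)

    def subset(self, mask) -> "AlignedSpikes":
        idx = np.flatnonzero(np.asarray(mask))
        return AlignedSpikes(
            offsets=[self.offsets[i] for i in idx],
            events=self.events.iloc[idx].reset_index(drop=True),
            alignment=self.alignment, window=self.window,
            extras=None if self.extras is None else [self.extras[i] for i in idx],
        )

    def all_offsets(self) -> np.ndarray:
        if not self.offsets:
            return np.empty(0)
        return np.concatenate(self.offsets)


@dataclass
class RateProfile:
    """Kernel-smoothed mean rate ± SEM on a uniform time grid."""

    time: np.ndarray
    mean: np.ndarray
    sem: np.ndarray
    n: int
    flags: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_ms": self.time, "mean_rate": self.mean,
                             "sem": self.sem, "n": self.n})


def kernel_rate(spike_offsets: np.ndarray, grid: np.ndarray,
                sd: float = KERNEL_SD, n_events: int = 1) -> np.ndarray:
    """Sum of unit-area Gaussians centered at spikes, in spikes/s.

    Dividing by ``n_events`` yields the trial-averaged rate.  Kernels are
    truncated at ±5 sigma; each spike's contribution integrates to 1 spike
    (up to the truncated 5-sigma tails).
    """
    if grid.size == 0:
        raise ValueError("empty rate grid")
    if sd <= 0:
        raise ValueError("kernel sd must be > 0")
    spike_offsets = np.asarray(spike_offsets, dtype=float)
    rate = np.zeros(grid.size)
    if spike_offsets.size == 0:
        return rate
    step = grid[1] - grid[0] if grid.size > 1 else GRID_STEP
    norm = 1000.0 / (sd * np.sqrt(2.0 * np.pi))  # peak of one kernel, spikes/s
    half = KERNEL_TRUNC * sd
    for t in spike_offsets:
        lo = int(np.clip(np.floor((t - half - grid[0]) / step), 0, grid.size))
        hi = int(np.clip(np.ceil((t + half - grid[0]) / step) + 1, 0, grid.size))
        if hi > lo:
            tt = grid[lo:hi]
            rate[lo:hi] += norm * np.exp(-0.5 * ((tt - t) / sd) ** 2)
    return rate / max(n_events, 1)


def binned_counts(offsets_list: list[np.ndarray],
                  window: tuple[float, float],
                  step: float = GRID_STEP):
    """Per-event spike-count matrix on the window grid (fast bootstrap path)."""
    grid = make_grid(window, step)
    edges = np.append(grid, window[1])
    mat = np.zeros((len(offsets_list), grid.size))
    for i, off in enumerate(offsets_list):
        if len(off):
            mat[i], _ = np.histogram(off, bins=edges)
    return grid, mat


def smooth_counts(grid: np.ndarray, counts: np.ndarray,
                  sd: float = KERNEL_SD) -> np.ndarray:
    """Convolve a 1-ms count histogram with the Gaussian kernel -> spikes/s."""
    step = grid[1] - grid[0]
    half = int(np.ceil(KERNEL_TRUNC * sd / step))
    k = np.exp(-0.5 * ((np.arange(-half, half + 1) * step) / sd) ** 2)
    k *= 1000.0 / (sd * np.sqrt(2.0 * np.pi))
    return np.convolve(counts, k, mode="same")


def align(spike_times: np.ndarray, events: pd.DataFrame, alignment: str,
          window: tuple[float, float],
          spike_payload: np.ndarray | None = None,
          dedupe: bool = False) -> AlignedSpikes:
    """Align a spike train to event times.

    ``alignment`` selects the event-time column: ``saccade_onset`` /
    ``corrective_onset`` use ``onset``; ``saccade_offset`` /
    ``corrective_offset`` use ``offset``; ``trial_onset`` uses
    ``trial_onset``.  Spikes are retained when their offset lies in the
    half-open ``[window[0], window[1])``.

    With ``dedupe=True`` each spike is attributed only to the event whose
    alignment time is nearest, so a spike never appears under two
    overlapping windows (required whenever per-spike payloads are averaged,
    e.g. CS durations — duplication would correlate neighboring bins and
    bias uncertainty estimates).
    """
    if alignment not in ALIGNMENTS:
        raise ValueError(f"unknown alignment {alignment!r}; one of {ALIGNMENTS}")
    col = ("trial_onset" if alignment == "trial_onset"
           else "onset" if alignment.endswith("onset") else "offset")
    if col not in events.columns:
        raise ValueError(f"events table lacks required column {col!r}")
    spike_times = np.asarray(spike_times, dtype=float)
    t_ev = events[col].to_numpy(dtype=float)
    nearest = None
    if dedupe and t_ev.size:
        order = np.argsort(t_ev)
        sorted_ev = t_ev[order]
        pos = np.searchsorted(sorted_ev, spike_times)
        pos = np.clip(pos, 1, t_ev.size - 1) if t_ev.size > 1 else \
            np.zeros(spike_times.size, dtype=int)
        if t_ev.size > 1:
            left = sorted_ev[pos - 1]
            right = sorted_ev[pos]
            pick = np.where(spike_times - left <= right - spike_times,
                            pos - 1, pos)
        else:
            pick = np.zeros(spike_times.size, dtype=int)
        nearest = order[pick]
    offsets, extras = [], []
    for i, t0 in enumerate(t_ev):
        rel = spike_times - t0
        m = (rel >= window[0]) & (rel < window[1])
        if nearest is not None:
            m &= nearest == i
        offsets.append(rel[m])
        if spike_payload is not None:
            extras.append(np.asarray(spike_payload)[m])
    return AlignedSpikes(offsets=offsets, events=events.reset_index(drop=True),
                         alignment=alignment, window=window,
                         extras=extras if spike_payload is not None else None)


def mean_profile(aligned: AlignedSpikes, sd: float = KERNEL_SD,
                 step: float = GRID_STEP) -> RateProfile:
    """Trial-averaged kernel rate of one cell's aligned spikes."""
    grid = make_grid(aligned.window, step)
    n = aligned.n_events
    rate = kernel_rate(aligned.all_offsets(), grid, sd=sd, n_events=max(n, 1))
    return RateProfile(time=grid, mean=rate, sem=np.zeros_like(rate), n=n)


def window_stat(aligned: AlignedSpikes, window: tuple[float, float],
                stat: str, sd: float = KERNEL_SD) -> float:
    """Scalar response statistic in a sub-window.

    ``probability`` = total spikes / n_events; ``mean_rate`` =
    count / (n_events * width); ``count`` = total spikes; ``peak_rate`` /
    ``peak_time`` come from the kernel-smoothed mean profile restricted to
    the window.  Returns NaN when there are no events.
    """
    if not (aligned.window[0] <= window[0] and window[1] <= aligned.window[1]):
        raise ValueError("stat window must lie inside the alignment window")
    n = aligned.n_events
    if n == 0:
        return float("nan")
    allo = aligned.all_offsets()
    count = int(np.count_nonzero((allo >= window[0]) & (allo < window[1])))
    if stat == "count":
        return float(count)
    if stat == "probability":
        return count / n
    if stat == "mean_rate":
        width_s = (window[1] - window[0]) / 1000.0
        return count / (n * width_s)
    if stat in ("peak_rate", "peak_time"):
        prof = mean_profile(aligned, sd=sd)
        m = (prof.time >= window[0]) & (prof.time < window[1])
        if not m.any():
            return float("nan")
        seg, tseg = prof.mean[m], prof.time[m]
        i = int(np.argmax(seg))
        return float(seg[i]) if stat == "peak_rate" else float(tseg[i])
    raise ValueError(f"unknown stat {stat!r}")


def per_event_rates(aligned: AlignedSpikes,
                    window: tuple[float, float]) -> np.ndarray:
    """Per-event mean rate (spikes/s) in a sub-window."""
    width_s = (window[1] - window[0]) / 1000.0
    return np.array([
        np.count_nonzero((o >= window[0]) & (o < window[1])) / width_s
        for o in aligned.offsets])


def population_average(profiles: list[RateProfile]) -> RateProfile:
    """Pointwise mean ± SEM across cells on a common grid.

    With a single cell the SEM is 0 by convention (flagged).
    """
    if not profiles:
        raise ValueError("no profiles")
    grid = profiles[0].time
    for p in profiles[1:]:
        if p.time.shape != grid.shape or not np.allclose(p.time, grid):
            raise ValueError("profiles are on mismatched grids")
    stack = np.vstack([p.mean for p in profiles])
    n = stack.shape[0]
    mean = stack.mean(axis=0)
    if n > 1:
        sem = stack.std(axis=0, ddof=1) / np.sqrt(n)
        flags = {}
    else:
        sem = np.zeros_like(mean)
        flags = {"single_cell": True}
    return RateProfile(time=grid, mean=mean, sem=sem, n=n, flags=flags)
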