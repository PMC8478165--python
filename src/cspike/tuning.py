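"""Preferred-direction assignment and binned tuning curves with linear fits.

A cell's preferred direction (left vs right, the task's two 180-degree
classes) is assigned independently in three epochs:

* primary saccades — probability of CS firing in the early postsaccadic
  period (0–100 ms from primary offset);
* corrective saccades — mean CS rate in the postcorrective period
  (0–100 ms from corrective offset);
* errors — mean CS rate in the precorrective period (−200–0 ms from
  corrective onset), with events classed by the direction of the error.

Tuning curves bin events by a kinematic covariate and fit an ordinary
least-squares line through the bin centers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import windows
from .rates import AlignedSpikes, window_stat

log = logging.getLogger(__name__)

__all__ = ["DirectionAssignment", "TuningResult", "assign_pd", "binned_tuning"]

#: (expected alignment, window, statistic) per preferred-direction kind
PD_SPECS = {
    "primary": ("saccade_offset", windows.EARLY_POST, "probability"),
    "corrective": ("corrective_offset", windows.POSTCORRECTIVE, "mean_rate"),
    "error": ("corrective_onset", windows.PRECORRECTIVE, "mean_rate"),
}


@dataclass
class DirectionAssignment:
    pd: int
    anti: int
    stat_used: str
    window_label: str
    stat_by_direction: dict[int, float]
    tie_flag: bool = False
    refused: bool = False
    reason: str = ""


@dataclass
class TuningResult:
    variable: str
    bin_edges: np.ndarray
    bin_centers: np.ndarray
    response: np.ndarray
    dispersion: np.ndarray
    n_per_bin: np.ndarray
    fit: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "bin_center": self.bin_centers, "response": self.response,
            "dispersion": self.dispersion, "n": self.n_per_bin})


def assign_pd(aligned: AlignedSpikes, kind: str,
              direction_col: str = "direction") -> DirectionAssignment:
    """Assign the preferred direction of one cell for one epoch kind.

    ``aligned`` must be aligned to the event appropriate for ``kind`` (see
    :data:`PD_SPECS`).  The direction whose statistic is higher wins; an
    exact tie resolves to +1 with ``tie_flag`` set.  A direction with zero
    events refuses the assignment.
    """
    if kind not in PD_SPECS:
        raise ValueError(f"unknown kind {kind!r}")
    expected_alignment, window, stat = PD_SPECS[kind]
    if aligned.alignment != expected_alignment:
        raise ValueError(
            f"kind {kind!r} expects alignment {expected_alignment!r}, "
            f"got {aligned.alignment!r}")
    dirs = aligned.events[direction_col].to_numpy()
    values: dict[int, float] = {}
    for d in (-1, 1):
        sub = aligned.subset(dirs == d)
        if sub.n_events == 0:
            return DirectionAssignment(
                pd=0, anti=0, stat_used=stat, window_label=kind,
                stat_by_direction={}, refused=True,
                reason=f"no events with direction {d:+d}")
        values[d] = window_stat(sub, window, stat)
    if values[1] == values[-1]:
        return DirectionAssignment(pd=1, anti=-1, stat_used=stat,
                                   window_label=kind, stat_by_direction=values,
                                   tie_flag=True)
    pref = 1 if values[1] > values[-1] else -1
    return DirectionAssignment(pd=pref, anti=-pref, stat_used=stat,
                               window_label=kind, stat_by_direction=values)


def linear_fit(x: np.ndarray, y: np.ndarray) -> dict:
    """OLS line with slope/intercept, R², slope p-value, and 95% slope CI."""
    res = stats.linregress(x, y)
    n = len(x)
    if n > 2:
        tcrit = stats.t.ppf(0.975, n - 2)
        ci = (res.slope - tcrit * res.stderr, res.slope + tcrit * res.stderr)
    else:
        ci = (float("-inf"), float("inf"))
    return {"slope": res.slope, "intercept": res.intercept,
            "r_squared": res.rvalue ** 2, "p_value": res.pvalue,
            "slope_stderr": res.stderr, "slope_ci": ci, "n_bins": n}


def binned_tuning(aligned: AlignedSpikes, variable: str, bin_size: float,
                  value_range: tuple[float, float], response: str,
                  window: tuple[float, float] | None = None,
                  min_per_bin: int = 10) -> TuningResult:
    """Bin events by a covariate and fit a line through per-bin responses.

    ``variable`` is any event covariate column (amplitude, duration,
    peak_velocity, signed_error, arrival_time); ``response`` is a
    :func:`window_stat` statistic evaluated in ``window`` (default: the full
    alignment window).  Bins with fewer than ``min_per_bin`` events are
    dropped (logged).  Requires at least two populated bins to fit.
    """
    if window is None:
        window = aligned.window
    vals = aligned.events[variable].to_numpy(dtype=float)
    edges = np.arange(value_range[0], value_range[1] + 0.5 * bin_size, bin_size)
    if edges.size < 3:
        raise ValueError("range/bin_size give fewer than 2 bins")
    centers, resp, disp, ns = [], [], [], []
    for lo, hi in zip(edges[:-1], edges[1:]):
        m = (vals >= lo) & (vals < hi)
        n = int(m.sum())
        if n < min_per_bin:
            if n:
                log.info("bin [%g, %g) dropped: %d < %d events", lo, hi, n,
                         min_per_bin)
            continue
        sub = aligned.subset(m)
        r = window_stat(sub, window, response)
        if response == "mean_rate":
            from .rates import per_event_rates
            pr = per_event_rates(sub, window)
            d = pr.std(ddof=1) / np.sqrt(n) if n > 1 else 0.0
        else:
            d = float("nan")
        centers.append((lo + hi) / 2.0)
        resp.append(r)
        disp.append(d)
        ns.append(n)
    centers = np.asarray(centers)
    resp = np.asarray(resp)
    if centers.size < 2:
        raise ValueError("fewer than 2 populated bins; fit refused")
    fit = linear_fit(centers, resp)
    return TuningResult(variable=variable, bin_edges=edges,
                        bin_centers=centers, response=resp,
                        dispersion=np.asarray(disp),
                        n_per_bin=np.asarray(ns), fit=fit)
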