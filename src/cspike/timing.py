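"""Bootstrap estimation of CS peak time and modulation-onset (trough) time.

The peak-time bootstrap repeatedly draws 50 cells (with replacement), each
contributing at least 10 trials per saccade-duration bin (5 ms bins),
averages their rates, and takes the time of the maximum; mean and 95% CI are
reported over 1000 repetitions.

The trough — the pre-burst dip marking the onset of CS modulation — is
estimated as the intersection of two fitted functions: a second-order
polynomial fitted to the baseline period (−200 to 0 ms from saccade onset)
and a line fitted over the 45 ms preceding the rate peak.  The trough
bootstrap resamples 1000 trials per duration bin and repeats the
intersection estimate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .rates import RateProfile, binned_counts, smooth_counts, make_grid

log = logging.getLogger(__name__)

__all__ = ["PeakTimeEstimate", "TroughEstimate", "bootstrap_peak_time",
           "estimate_trough", "bootstrap_trough"]

DEFAULT_PEAK_SEARCH = (0.0, 200.0)  # ms from alignment
LINEAR_SPAN = 45.0  # ms: span of the pre-peak linear fit


@dataclass
class PeakTimeEstimate:
    duration_bin: float
    mean: float
    ci_low: float
    ci_high: float
    reps: int


@dataclass
class TroughEstimate:
    duration_bin: float
    trough: float
    ci_low: float
    ci_high: float
    peak_time: float
    baseline_coeffs: np.ndarray | None = None
    line_coeffs: np.ndarray | None = None
    diagnostic: str = ""


def bootstrap_peak_time(profiles_by_bin: dict[float, np.ndarray],
                        grid: np.ndarray, n_cells: int = 50,
                        reps: int = 1000, seed: int = 0,
                        search_window: tuple[float, float] = DEFAULT_PEAK_SEARCH,
                        ) -> list[PeakTimeEstimate]:
    """Peak time per duration bin via a cell-resampling bootstrap.

    ``profiles_by_bin`` maps a duration-bin label to an (n_cells x n_grid)
    array of per-cell mean rates on ``grid`` (eligibility — at least 10
    trials per cell and bin — is the caller's responsibility, e.g. via the
    pipeline helpers).  Bins with no eligible cells are skipped with a log
    entry.
    """
    rng = np.random.default_rng(seed)
    m = (grid >= search_window[0]) & (grid < search_window[1])
    tseg = grid[m]
    out = []
    for b in sorted(profiles_by_bin):
        mat = np.asarray(profiles_by_bin[b])
        if mat.ndim != 2 or mat.shape[0] == 0:
            log.info("duration bin %s skipped: no eligible cells", b)
            continue
        peaks = np.empty(reps)
        for r in range(reps):
            idx = rng.integers(0, mat.shape[0], size=n_cells)
            avg = mat[idx].mean(axis=0)[m]
            peaks[r] = tseg[np.argmax(avg)]
        out.append(PeakTimeEstimate(
            duration_bin=b, mean=float(peaks.mean()),
            ci_low=float(np.percentile(peaks, 2.5)),
            ci_high=float(np.percentile(peaks, 97.5)), reps=reps))
    return out


def estimate_trough(profile: RateProfile, peak_time: float,
                    baseline_window: tuple[float, float] = (-200.0, 0.0),
                    linear_span: float = LINEAR_SPAN,
                    duration_bin: float = float("nan")) -> TroughEstimate:
    """Trough time from the quadratic-baseline / pre-peak-line intersection.

    Fits a least-squares quadratic on baseline samples and a line on samples
    in ``[peak_time - linear_span, peak_time]``; the trough is the earliest
    real intersection of the line with the extrapolated quadratic lying
    between the end of the baseline window and the peak.  If no admissible
    intersection exists the trough is NaN with a diagnostic.
    """
    t, y = profile.time, profile.mean
    mb = (t >= baseline_window[0]) & (t < baseline_window[1])
    if not mb.any():
        raise ValueError("baseline window not covered by the profile")
    quad = np.polyfit(t[mb], y[mb], 2)
    ml = (t >= peak_time - linear_span) & (t <= peak_time)
    if ml.sum() < 2:
        return TroughEstimate(duration_bin, float("nan"), float("nan"),
                              float("nan"), peak_time,
                              diagnostic="pre-peak span not covered")
    line = np.polyfit(t[ml], y[ml], 1)
    # degenerate: the two fitted functions coincide (flat profile)
    span = np.linspace(baseline_window[1], peak_time, 50)
    gap = np.max(np.abs(np.polyval(quad, span) - np.polyval(line, span)))
    scale = max(float(np.max(np.abs(y))), 1e-12)
    if gap < 1e-9 * scale:
        return TroughEstimate(duration_bin, float("nan"), float("nan"),
                              float("nan"), peak_time, quad, line,
                              diagnostic="degenerate: fits coincide")
    # quad(t) = line(t): a t^2 + (b - m) t + (c - k) = 0, continuous functions
    a, b, c = quad
    mcoef, k = line
    roots = np.roots([a, b - mcoef, c - k])
    roots = roots[np.isreal(roots)].real
    admissible = roots[(roots > baseline_window[1] - 1e-9) & (roots < peak_time)]
    if admissible.size == 0:
        return TroughEstimate(duration_bin, float("nan"), float("nan"),
                              float("nan"), peak_time, quad, line,
                              diagnostic="no admissible intersection")
    trough = float(np.min(admissible))
    return TroughEstimate(duration_bin, trough, trough, trough, peak_time,
                          quad, line)


def bootstrap_trough(trials_by_bin: dict[float, list[np.ndarray]],
                     window: tuple[float, float], n_trials: int = 1000,
                     reps: int = 1000, seed: int = 0,
                     search_window: tuple[float, float] = DEFAULT_PEAK_SEARCH,
                     baseline_window: tuple[float, float] = (-200.0, 0.0),
                     ) -> list[TroughEstimate]:
    """Trough time per duration bin via a trial-resampling bootstrap.

    ``trials_by_bin`` maps a duration-bin label to per-trial spike-offset
    arrays (aligned to saccade onset, within ``window``).  Each repetition
    samples ``n_trials`` trials with replacement, smooths the pooled counts
    into a mean rate, and runs :func:`estimate_trough`.  Empty bins are
    skipped.
    """
    rng = np.random.default_rng(seed)
    out = []
    for b in sorted(trials_by_bin):
        trials = trials_by_bin[b]
        if len(trials) == 0:
            log.info("duration bin %s skipped: no trials", b)
            continue
        grid, counts = binned_counts(trials, window)
        ms = (grid >= search_window[0]) & (grid < search_window[1])
        # all resampled mean-count vectors in one matrix product
        W = np.zeros((reps, counts.shape[0]))
        for r in range(reps):
            idx = rng.integers(0, counts.shape[0], size=n_trials)
            W[r] = np.bincount(idx, minlength=counts.shape[0])
        mean_counts = W @ counts / n_trials
        troughs, peaks = [], []
        for r in range(reps):
            rate = smooth_counts(grid, mean_counts[r])
            peak_time = float(grid[ms][np.argmax(rate[ms])])
            prof = RateProfile(time=grid, mean=rate,
                               sem=np.zeros_like(rate), n=n_trials)
            est = estimate_trough(prof, peak_time,
                                  baseline_window=baseline_window,
                                  duration_bin=b)
            if np.isfinite(est.trough):
                troughs.append(est.trough)
                peaks.append(peak_time)
        if not troughs:
            out.append(TroughEstimate(b, float("nan"), float("nan"),
                                      float("nan"), float("nan"),
                                      diagnostic="no rep produced a trough"))
            continue
        troughs = np.asarray(troughs)
        out.append(TroughEstimate(
            duration_bin=b, trough=float(troughs.mean()),
            ci_low=float(np.percentile(troughs, 2.5)),
            ci_high=float(np.percentile(troughs, 97.5)),
            peak_time=float(np.mean(peaks))))
    return out
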