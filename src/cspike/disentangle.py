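"""Separating error from saccade-kinematic influences on postsaccadic CS firing.

The central dissociation: in the late postsaccadic window (50–250 ms from
primary offset) CS activity is driven by the signed retinal error, while the
early burst tracks saccade amplitude.  Four complementary tools test it:

* :func:`error_magnitude_tuning` — mean rate vs signed error bins (positive
  toward the cell's preferred error direction).
* :func:`pool_comparable_errors` — pool saccades of any direction/amplitude
  with comparable error vectors (8 signed 0.5-deg bins spanning −2..+2 deg),
  verifying amplitude balance with a Kruskal–Wallis test.
* :func:`pool_mixed_errors` — within amplitude bins, balance the two error
  signs by seeded subsampling so the mean signed error cancels, isolating
  amplitude effects.
* :func:`per_pc_multiple_regression` — per-cell OLS of window CS counts on
  amplitude and signed error, Y_i = l_i*A + m_i*E + c_i.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

from . import windows
from .rates import AlignedSpikes, per_event_rates, window_stat
from .tuning import TuningResult, binned_tuning, linear_fit

log = logging.getLogger(__name__)

__all__ = ["ErrorPooling", "MixedPooling", "RegressionFit",
           "error_magnitude_tuning", "pool_comparable_errors",
           "pool_mixed_errors", "peak_and_mean_regression",
           "per_pc_multiple_regression", "predicted_count_surface"]

DEFAULT_ERROR_EDGES = np.arange(-2.0, 2.0 + 0.25, 0.5)


def signed_error_toward_pd(events: pd.DataFrame, pd_error: int) -> np.ndarray:
    """Signed error with positive values toward the preferred error direction."""
    return events["signed_error"].to_numpy(dtype=float) * pd_error


def error_magnitude_tuning(aligned: AlignedSpikes, pd_error: int,
                           window: tuple[float, float] = windows.LATE_POST,
                           bin_size: float = 0.5,
                           value_range: tuple[float, float] = (-2.0, 2.0),
                           min_per_bin: int = 10) -> TuningResult:
    """Mean CS rate vs signed error (PD_error positive), with a linear fit.

    Requires at least 3 populated bins.
    """
    al = AlignedSpikes(offsets=aligned.offsets,
                       events=aligned.events.assign(
                           error_toward_pd=signed_error_toward_pd(
                               aligned.events, pd_error)),
                       alignment=aligned.alignment, window=aligned.window)
    res = binned_tuning(al, "error_toward_pd", bin_size, value_range,
                        response="mean_rate", window=window,
                        min_per_bin=min_per_bin)
    if res.bin_centers.size < 3:
        raise ValueError("fewer than 3 populated error bins; fit refused")
    return res


@dataclass
class ErrorPooling:
    groups: dict[float, np.ndarray]        # bin center -> event indices
    mean_amplitude: dict[float, float]
    kw_statistic: float
    kw_pvalue: float
    refused: bool = False
    reason: str = ""


def pool_comparable_errors(events: pd.DataFrame, pd_error: int,
                           edges: np.ndarray = DEFAULT_ERROR_EDGES,
                           ) -> ErrorPooling:
    """Group events by signed error bin, reporting amplitude balance.

    Groups pool saccades regardless of direction (left/right, CF/CP) and
    amplitude; a Kruskal–Wallis test across the groups' amplitude
    distributions quantifies whether the pooled bins are amplitude balanced.
    Empty bins are dropped (logged).
    """
    e = events["signed_error"].to_numpy(dtype=float) * pd_error
    amps = events["amplitude"].to_numpy(dtype=float)
    groups, mean_amp = {}, {}
    for lo, hi in zip(edges[:-1], edges[1:]):
        idx = np.flatnonzero((e >= lo) & (e < hi))
        center = (lo + hi) / 2.0
        if idx.size == 0:
            log.info("error bin %g dropped: empty", center)
            continue
        groups[center] = idx
        mean_amp[center] = float(amps[idx].mean())
    if len(groups) < 2:
        return ErrorPooling(groups, mean_amp, float("nan"), float("nan"),
                            refused=True, reason="fewer than 2 populated bins")
    kw = stats.kruskal(*[amps[idx] for idx in groups.values()])
    return ErrorPooling(groups, mean_amp, float(kw.statistic), float(kw.pvalue))


@dataclass
class MixedPooling:
    groups: dict[float, np.ndarray]        # amplitude-bin center -> indices
    mean_signed_error: dict[float, float]
    excluded_bins: list[float] = field(default_factory=list)


def pool_mixed_errors(events: pd.DataFrame, amplitude_bin_size: float = 0.5,
                      amplitude_range: tuple[float, float] | None = None,
                      seed: int = 0) -> MixedPooling:
    """Pool similarly sized saccades with opposite-sign errors, canceling error.

    Within each amplitude bin, the positive- and negative-error event counts
    are equalized by seeded subsampling without replacement; bins containing
    only one error sign are excluded (logged).  The per-bin mean signed error
    after balancing is reported.
    """
    rng = np.random.default_rng(seed)
    amps = events["amplitude"].to_numpy(dtype=float)
    errs = events["signed_error"].to_numpy(dtype=float)
    if amplitude_range is None:
        amplitude_range = (np.floor(amps.min() / amplitude_bin_size)
                           * amplitude_bin_size, amps.max())
    edges = np.arange(amplitude_range[0],
                      amplitude_range[1] + amplitude_bin_size,
                      amplitude_bin_size)
    groups, mean_err, excluded = {}, {}, []
    for lo, hi in zip(edges[:-1], edges[1:]):
        center = (lo + hi) / 2.0
        idx = np.flatnonzero((amps >= lo) & (amps < hi))
        pos = idx[errs[idx] > 0]
        neg = idx[errs[idx] < 0]
        if pos.size == 0 or neg.size == 0:
            if idx.size:
                excluded.append(center)
                log.info("amplitude bin %g excluded: single error sign", center)
            continue
        n = min(pos.size, neg.size)
        sel = np.concatenate([rng.choice(pos, n, replace=False),
                              rng.choice(neg, n, replace=False)])
        sel.sort()
        groups[center] = sel
        mean_err[center] = float(errs[sel].mean())
    return MixedPooling(groups, mean_err, excluded)


def peak_and_mean_regression(aligned: AlignedSpikes,
                             groups: dict[float, np.ndarray],
                             window: tuple[float, float] = windows.LATE_POST,
                             ) -> dict[str, dict]:
    """Linear fits of per-group peak rate and mean rate against the bin key.

    The peak firing rate captures the saccade-related burst; the mean firing
    rate registers the tonic error-related activity.  Requires >= 3 groups.
    """
    if len(groups) < 3:
        raise ValueError("need at least 3 groups for regression")
    keys = np.array(sorted(groups))
    peak = np.empty(keys.size)
    mean = np.empty(keys.size)
    for i, k in enumerate(keys):
        mask = np.zeros(aligned.n_events, dtype=bool)
        mask[groups[k]] = True
        sub = aligned.subset(mask)
        peak[i] = window_stat(sub, window, "peak_rate")
        mean[i] = window_stat(sub, window, "mean_rate")
    return {"peak_rate": linear_fit(keys, peak),
            "mean_rate": linear_fit(keys, mean),
            "bin_keys": keys.tolist(),
            "peak_values": peak.tolist(), "mean_values": mean.tolist()}


@dataclass
class RegressionFit:
    cell_id: int
    slope_amplitude: float   # l: CS count per deg of amplitude
    slope_error: float       # m: CS count per deg of signed error
    intercept: float         # c
    window_label: str
    p_amplitude: float
    p_error: float
    r_squared: float
    n_events: int
    skipped: bool = False
    reason: str = ""


def per_pc_multiple_regression(cells: list[AlignedSpikes],
                               window: tuple[float, float] = windows.REGRESSION_LATE,
                               pd_error_by_cell: list[int] | None = None,
                               min_events: int = 30):
    """Per-cell OLS of window CS counts on amplitude and signed error.

    For each cell, Y = l*A + m*E + c where Y is the CS count in ``window``
    per saccade, A the saccade amplitude and E the signed error (positive
    toward the cell's preferred error direction).  Cells with fewer than
    ``min_events`` saccades or a rank-deficient design are skipped with a
    flag.  Returns ``(fits, population_means)`` with population means of
    l, m, c over the fitted cells.
    """
    label = f"[{window[0]:g},{window[1]:g})"
    fits = []
    for i, al in enumerate(cells):
        pd_err = 1 if pd_error_by_cell is None else pd_error_by_cell[i]
        A = al.events["amplitude"].to_numpy(dtype=float)
        E = al.events["signed_error"].to_numpy(dtype=float) * pd_err
        Y = np.array([np.count_nonzero((o >= window[0]) & (o < window[1]))
                      for o in al.offsets], dtype=float)
        if A.size < min_events:
            fits.append(RegressionFit(i, np.nan, np.nan, np.nan, label,
                                      np.nan, np.nan, np.nan, A.size,
                                      skipped=True, reason="too few events"))
            continue
        X = sm.add_constant(np.column_stack([A, E]))
        if np.linalg.matrix_rank(X) < 3:
            fits.append(RegressionFit(i, np.nan, np.nan, np.nan, label,
                                      np.nan, np.nan, np.nan, A.size,
                                      skipped=True,
                                      reason="rank-deficient design"))
            continue
        res = sm.OLS(Y, X).fit()
        c, l, m = res.params
        fits.append(RegressionFit(i, l, m, c, label,
                                  res.pvalues[1], res.pvalues[2],
                                  res.rsquared, A.size))
    ok = [f for f in fits if not f.skipped]
    pop = {"l": float(np.mean([f.slope_amplitude for f in ok])) if ok else np.nan,
           "m": float(np.mean([f.slope_error for f in ok])) if ok else np.nan,
           "c": float(np.mean([f.intercept for f in ok])) if ok else np.nan,
           "n_cells": len(ok)}
    return fits, pop


def predicted_count_surface(pop: dict,
                            amplitude_grid=np.arange(13.0, 17.0 + 0.25, 0.5),
                            error_grid=np.arange(-2.0, 2.0 + 0.25, 0.5),
                            ) -> pd.DataFrame:
    """Predicted CS counts over an (amplitude x signed error) grid."""
    surf = (pop["l"] * amplitude_grid[:, None]
            + pop["m"] * error_grid[None, :] + pop["c"])
    return pd.DataFrame(surf, index=pd.Index(amplitude_grid, name="amplitude"),
                        columns=pd.Index(error_grid, name="signed_error"))
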