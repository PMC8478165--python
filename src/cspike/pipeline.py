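"""End-to-end pipeline: detection -> rates -> tuning -> timing ->
disentangle -> duration -> encoding, with per-stage CSV outputs and
provenance records.

Each session is treated as one cell's recording.  Stages write their outputs
under ``<out>/<stage>/`` together with a ``provenance.json`` recording the
configuration hash, seed, package version, and per-stage event counts, so
any output can be reproduced exactly.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, behavior, csduration, disentangle, encoding, \
    timing, tuning, windows
from .io import PipelineConfig, Session, read_session
from .rates import AlignedSpikes, align, make_grid, mean_profile, \
    per_event_rates, population_average

log = logging.getLogger(__name__)

__all__ = ["run_pipeline", "CellData", "build_cell"]

STAGES = ("detect", "rates", "tuning", "timing", "disentangle", "duration",
          "encode")


class StageError(RuntimeError):
    def __init__(self, stage, cause):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


class CellData:
    """Aligned spike sets of one cell/session for every analysis epoch."""

    def __init__(self, session: Session, events: pd.DataFrame,
                 window=(-300.0, 500.0)):
        self.session = session
        self.events = events
        self.window = window
        cs_t = session.cs["time_ms"].to_numpy(dtype=float)
        payload = (session.cs["duration_ms"].to_numpy(dtype=float)
                   if session.cs_durations_available else None)
        prim = events[(events["type"] == "primary")
                      & events["subtype"].isin(["CF", "CP"])].reset_index(drop=True)
        corr = events[events["type"] == "corrective"].reset_index(drop=True)
        self.primaries = prim
        self.correctives = corr
        self.prim_onset = align(cs_t, prim, "saccade_onset", window, payload)
        self.prim_offset = align(cs_t, prim, "saccade_offset", window, payload)
        self.corr_onset = align(cs_t, corr, "corrective_onset", window, payload)
        self.corr_offset = align(cs_t, corr, "corrective_offset", window, payload)
        trials = session.trials.copy()
        arrival = np.full(len(trials), np.nan)
        for row in prim.itertuples():
            if row.subtype == "CP" and row.assoc_trial >= 0:
                arrival[int(row.assoc_trial)] = (
                    row.offset - trials.loc[int(row.assoc_trial), "trial_onset"])
        trials["arrival_time"] = arrival
        self.trials = trials
        self.trial_onset = align(cs_t, trials, "trial_onset", window, payload)


def build_cell(session: Session, config: PipelineConfig) -> CellData:
    events = behavior.detect_events(session, config.smoothing_cutoff_hz)
    return CellData(session, events, window=config.alignment_window_ms)


def concat_aligned(parts: list[AlignedSpikes]) -> AlignedSpikes:
    parts = [p for p in parts if p.n_events]
    if not parts:
        raise ValueError("nothing to concatenate")
    offsets = [o for p in parts for o in p.offsets]
    extras = None
    if all(p.extras is not None for p in parts):
        extras = [e for p in parts for e in p.extras]
    events = pd.concat([p.events for p in parts], ignore_index=True)
    return AlignedSpikes(offsets=offsets, events=events,
                         alignment=parts[0].alignment,
                         window=parts[0].window, extras=extras)


def _provenance(out: Path, config: PipelineConfig, counts: dict):
    rec = {"config_hash": config.content_hash(), "config": config.to_dict(),
           "seed": config.seed, "cspike_version": __version__,
           "counts": counts}
    (out / "provenance.json").write_text(json.dumps(rec, indent=2))


def run_pipeline(config: PipelineConfig, session_paths: list[str | Path],
                 out_dir: str | Path) -> Path:
    """Execute every stage on the given sessions; halt on a stage failure
    (partial outputs are retained)."""
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sessions = [read_session(p) for p in session_paths]
    if not sessions:
        raise ValueError("need at least one session")

    cells: list[CellData] = []
    stage = "detect"
    try:
        d = out / stage
        d.mkdir(exist_ok=True)
        for i, s in enumerate(sessions):
            cell = build_cell(s, config)
            cells.append(cell)
            cell.events.to_csv(d / f"session_{i:03d}_events.csv", index=False)
        fat = behavior.fatigue_summary([c.events for c in cells],
                                       config.fatigue_edge_trials)
        fat.per_session.to_csv(d / "fatigue_per_session.csv", index=False)
        fat.pooled.to_csv(d / "fatigue_pooled.csv", index=False)
        _provenance(d, config, {"sessions": len(cells),
                                "events": int(sum(len(c.events) for c in cells))})

        stage = "rates"
        d = out / stage
        d.mkdir(exist_ok=True)
        profiles = [mean_profile(c.prim_onset, sd=config.kernel_sd_ms)
                    for c in cells]
        pop = population_average(profiles)
        pop.to_frame().to_csv(d / "population_primary_onset.csv", index=False)
        (d / "population_primary_onset.json").write_text(json.dumps(
            {"alignment": "saccade_onset",
             "window": list(config.alignment_window_ms)}))
        _provenance(d, config, {"cells": len(profiles)})

        stage = "tuning"
        d = out / stage
        d.mkdir(exist_ok=True)
        pd_rows = []
        for i, c in enumerate(cells):
            row = {"cell": i}
            row["pd_primary"] = tuning.assign_pd(c.prim_offset, "primary").pd
            if c.corr_offset.n_events:
                row["pd_corrective"] = tuning.assign_pd(
                    c.corr_offset, "corrective").pd
                row["pd_error"] = tuning.assign_pd(c.corr_onset, "error").pd
            pd_rows.append(row)
        pd.DataFrame(pd_rows).to_csv(d / "preferred_directions.csv", index=False)
        pooled = concat_aligned([c.prim_offset for c in cells])
        for var, bs, rng_ in (("amplitude", config.amplitude_bin_deg,
                               config.amplitude_range_deg),
                              ("duration", config.duration_bin_ms,
                               config.duration_range_ms)):
            try:
                res = tuning.binned_tuning(pooled, var, bs, rng_,
                                           response="peak_rate",
                                           window=windows.EARLY_POST,
                                           min_per_bin=config.min_events_per_bin)
                res.to_frame().to_csv(d / f"tuning_{var}.csv", index=False)
                (d / f"tuning_{var}.json").write_text(
                    json.dumps(res.fit, default=float))
            except ValueError as e:
                log.warning("tuning on %s skipped: %s", var, e)
        _provenance(d, config, {"cells": len(cells)})

        stage = "timing"
        d = out / stage
        d.mkdir(exist_ok=True)
        edges = np.arange(config.duration_range_ms[0],
                          config.duration_range_ms[1] + config.duration_bin_ms,
                          config.duration_bin_ms)
        profiles_by_bin: dict[float, list] = {}
        trials_by_bin: dict[float, list] = {}
        grid = make_grid(config.alignment_window_ms)
        for lo, hi in zip(edges[:-1], edges[1:]):
            center = (lo + hi) / 2.0
            mats, trial_offsets = [], []
            for c in cells:
                m = ((c.primaries["duration"] >= lo)
                     & (c.primaries["duration"] < hi)).to_numpy()
                if m.sum() >= config.peak_bootstrap_min_trials:
                    sub = c.prim_onset.subset(m)
                    mats.append(mean_profile(sub, sd=config.kernel_sd_ms).mean)
                    trial_offsets.extend(sub.offsets)
            if mats:
                profiles_by_bin[center] = np.vstack(mats)
                trials_by_bin[center] = trial_offsets
        peaks = timing.bootstrap_peak_time(
            profiles_by_bin, grid, n_cells=config.peak_bootstrap_cells,
            reps=config.peak_bootstrap_reps, seed=config.seed)
        pd.DataFrame([asdict(p) for p in peaks]).to_csv(
            d / "peak_times.csv", index=False)
        troughs = timing.bootstrap_trough(
            trials_by_bin, config.alignment_window_ms,
            n_trials=config.trough_bootstrap_trials,
            reps=config.trough_bootstrap_reps, seed=config.seed)
        pd.DataFrame([{k: v for k, v in asdict(t).items()
                       if not isinstance(v, np.ndarray)} for t in troughs]
                     ).to_csv(d / "trough_times.csv", index=False)
        _provenance(d, config, {"duration_bins": len(profiles_by_bin)})

        stage = "disentangle"
        d = out / stage
        d.mkdir(exist_ok=True)
        try:
            err_tuning = disentangle.error_magnitude_tuning(
                pooled, pd_error=1, window=windows.LATE_POST,
                bin_size=config.error_bin_deg,
                value_range=config.error_range_deg,
                min_per_bin=config.min_events_per_bin)
            err_tuning.to_frame().to_csv(d / "error_tuning.csv", index=False)
            (d / "error_tuning.json").write_text(
                json.dumps(err_tuning.fit, default=float))
        except ValueError as e:
            log.warning("error tuning skipped: %s", e)
        pooling = disentangle.pool_comparable_errors(pooled.events, pd_error=1)
        (d / "comparable_errors.json").write_text(json.dumps(
            {"kw_statistic": pooling.kw_statistic, "kw_pvalue": pooling.kw_pvalue,
             "mean_amplitude": pooling.mean_amplitude}, default=float))
        mixed = disentangle.pool_mixed_errors(pooled.events,
                                              seed=config.seed)
        if len(mixed.groups) >= 3:
            reg = disentangle.peak_and_mean_regression(
                pooled, mixed.groups, window=windows.LATE_POST)
            (d / "mixed_pool_regression.json").write_text(
                json.dumps(reg, default=float))
        fits, pop_coef = disentangle.per_pc_multiple_regression(
            [c.prim_offset for c in cells], window=windows.REGRESSION_LATE)
        pd.DataFrame([asdict(f) for f in fits]).to_csv(
            d / "per_cell_regression.csv", index=False)
        (d / "population_coefficients.json").write_text(
            json.dumps(pop_coef, default=float))
        disentangle.predicted_count_surface(pop_coef).to_csv(
            d / "predicted_surface.csv")
        _provenance(d, config, {"cells": len(cells)})

        stage = "duration"
        d = out / stage
        d.mkdir(exist_ok=True)
        if all(c.session.cs_durations_available for c in cells):
            series = []
            for c in cells:
                if len(c.session.cs):
                    # each CS attributed once (nearest saccade) so that
                    # per-bin duration means are statistically independent
                    al = align(c.session.cs["time_ms"].to_numpy(float),
                               c.primaries, "saccade_onset",
                               config.alignment_window_ms,
                               spike_payload=c.session.cs["duration_ms"]
                               .to_numpy(float), dedupe=True)
                    series.append(csduration.percent_change_series(
                        al,
                        cell_mean_duration=float(
                            c.session.cs["duration_ms"].mean())))
            prof = csduration.population_percent_change(series)
            pd.DataFrame({"bin_center": prof.bin_centers,
                          "mean_pct": prof.mean, "sem": prof.sem_cells,
                          "n_cells": prof.n_cells}).to_csv(
                d / "duration_profile.csv", index=False)
            epochs = csduration.detect_epochs(prof.bin_centers, prof.mean,
                                              sem=prof.sem_sampling)
            (d / "epochs.json").write_text(json.dumps(asdict(epochs)))
            _provenance(d, config, {"cells": len(series)})
        else:
            log.warning("CS durations unavailable; duration stage skipped")
            _provenance(d, config, {"cells": 0, "skipped": True})

        stage = "encode"
        d = out / stage
        d.mkdir(exist_ok=True)
        results = []
        for i, c in enumerate(cells):
            results.extend(encode_cell(c, i))
        mat = encoding.build_matrix(results)
        mat.binary.to_csv(d / "encoding_matrix.csv")
        mat.p_values.to_csv(d / "p_values.csv")
        tidy = pd.DataFrame([asdict(r) for r in results])
        tidy.to_csv(d / "encoding_flags.csv", index=False)
        corr, flagged = encoding.cross_correlate(mat)
        corr.to_csv(d / "cross_correlation.csv")
        _provenance(d, config, {"cells": len(cells), "tests": len(results)})
    except Exception as e:  # halt with a stage-named error, keep partials
        raise StageError(stage, e) from e
    return out


def _rates_counts(aligned, window):
    r = per_event_rates(aligned, window)
    counts = np.array([np.count_nonzero((o >= window[0]) & (o < window[1]))
                       for o in aligned.offsets])
    return r, counts


def encode_cell(cell: CellData, cell_id: int) -> list:
    """All seven per-parameter encoding tests for one cell."""
    res = []
    # trial onset: CP arrival time split, 150-250 ms from trial onset
    tr = cell.trial_onset.subset(np.isfinite(
        cell.trials["arrival_time"].to_numpy()))
    w = windows.TRIAL_ONSET_WIN
    if tr.n_events:
        r, n = _rates_counts(tr, w)
        res.append(encoding.median_split_test(
            tr.events["arrival_time"].to_numpy(), r, n, cell_id,
            "trial_onset", "trial_onset[150,250)"))
    else:
        res.append(encoding.EncodingTestResult(
            cell_id, "trial_onset", "trial_onset[150,250)", float("nan"),
            "not_compared", reason="no CP arrival times"))

    # primary amplitude and direction, 0-100 ms from primary offset
    w = windows.EARLY_POST
    r, n = _rates_counts(cell.prim_offset, w)
    res.append(encoding.median_split_test(
        cell.prim_offset.events["amplitude"].to_numpy(), r, n, cell_id,
        "ps_amplitude", "primary_offset[0,100)"))
    dirs = cell.prim_offset.events["direction"].to_numpy()
    pd_assign = tuning.assign_pd(cell.prim_offset, "primary")
    if pd_assign.refused:
        res.append(encoding.EncodingTestResult(
            cell_id, "ps_direction", "primary_offset[0,100)", float("nan"),
            "not_compared", reason=pd_assign.reason))
    else:
        res.append(encoding.direction_test(
            r[dirs == pd_assign.pd], r[dirs == pd_assign.anti], int(n.sum()),
            cell_id, "ps_direction", "primary_offset[0,100)"))

    # corrective amplitude and direction, 0-100 ms from corrective offset
    w = windows.POSTCORRECTIVE
    if cell.corr_offset.n_events:
        r, n = _rates_counts(cell.corr_offset, w)
        res.append(encoding.median_split_test(
            cell.corr_offset.events["amplitude"].to_numpy(), r, n, cell_id,
            "corr_amplitude", "corrective_offset[0,100)"))
        dirs = cell.corr_offset.events["direction"].to_numpy()
        ca = tuning.assign_pd(cell.corr_offset, "corrective")
        if ca.refused:
            res.append(encoding.EncodingTestResult(
                cell_id, "corr_direction", "corrective_offset[0,100)",
                float("nan"), "not_compared", reason=ca.reason))
        else:
            res.append(encoding.direction_test(
                r[dirs == ca.pd], r[dirs == ca.anti], int(n.sum()), cell_id,
                "corr_direction", "corrective_offset[0,100)"))
    else:
        for p in ("corr_amplitude", "corr_direction"):
            res.append(encoding.EncodingTestResult(
                cell_id, p, "corrective_offset[0,100)", float("nan"),
                "not_compared", reason="no corrective saccades"))

    # error magnitude and direction, 50-250 ms from primary offset
    w = windows.LATE_POST
    r, n = _rates_counts(cell.prim_offset, w)
    errs = cell.prim_offset.events["signed_error"].to_numpy()
    res.append(encoding.median_split_test(
        np.abs(errs), r, n, cell_id, "error_magnitude",
        "primary_offset[50,250)"))
    pos, neg = r[errs > 0], r[errs < 0]
    if pos.size and neg.size:
        # preferred error direction = the sign with the higher mean rate
        if pos.mean() >= neg.mean():
            res.append(encoding.direction_test(pos, neg, int(n.sum()),
                                               cell_id, "error_direction",
                                               "primary_offset[50,250)"))
        else:
            res.append(encoding.direction_test(neg, pos, int(n.sum()),
                                               cell_id, "error_direction",
                                               "primary_offset[50,250)"))
    else:
        res.append(encoding.EncodingTestResult(
            cell_id, "error_direction", "primary_offset[50,250)",
            float("nan"), "not_compared", reason="one error sign absent"))
    return res
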