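"""Synthetic oculomotor sessions with ground truth.

Generates the behavior and spike trains of a repetitive horizontal saccade
task: on each trial a central fixation dot appears (trial onset), after a
400–600 ms fixation the dot jumps to ±15 deg (go-signal), the subject makes a
centrifugal (CF) primary saccade, possibly followed by a small corrective
saccade when the landing error exceeds a threshold, and after 700–900 ms the
dot returns to the center, triggering a centripetal (CP) return saccade at the
start of the next trial.  Repetition induces saccadic fatigue: peak velocity
declines geometrically across trials while amplitude is preserved by a
compensatory increase of duration.

Complex-spike (CS) trains are drawn from an inhomogeneous Poisson process

    lambda(t) = clip(baseline * (1 - suppression(t)) + burst(t)
                     + error_tonic(t) + corrective_burst(t)
                     + trial_onset(t), 0)

via thinning, with each CS assigned a duration of ``cs_base_duration`` or
``cs_base_duration + cs_spikelet_increment`` (an extra terminal spikelet) with
probability tied to the local rate modulation, so that rate and duration
changes are yoked.  Simple spikes (SS) are a homogeneous Poisson train with an
enforced 10–20 ms pause after every CS.

Every generated quantity is recorded in :class:`GroundTruth` so downstream
estimators have a recoverable target.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

__all__ = [
    "SessionConfig",
    "NeuronTuning",
    "GroundTruth",
    "ConfigurationError",
    "minimum_jerk_position",
    "minimum_jerk_peak_velocity",
    "generate_behavior",
    "generate_spikes",
    "simulate_session",
]

# rate grid step for the latent CS rate, ms
RATE_DT = 1.0


class ConfigurationError(ValueError):
    """Raised when a session configuration cannot produce a valid session."""


@dataclass
class SessionConfig:
    """Parameters of one simulated behavioral session.

    Durations are in ms, positions in deg, rates in Hz.  Defaults reproduce
    the task structure the analysis is designed for: 15 deg horizontal
    targets, 400–600 ms fixation, 700–900 ms target display, 100 ms
    intertrial interval, 1200 ms nominal trial duration.
    """

    n_trials: int = 300
    sampling_rate: float = 1000.0
    fixation_duration_range: tuple[float, float] = (400.0, 600.0)
    target_eccentricity: float = 15.0
    target_display_duration_range: tuple[float, float] = (700.0, 900.0)
    intertrial_interval: float = 100.0
    trial_duration: float = 1200.0
    cf_direction: int = 1
    saccade_latency_mean: float = 180.0
    saccade_latency_sd: float = 30.0
    cp_latency_mean: float = 110.0
    cp_latency_sd: float = 50.0
    fatigue_velocity_ratio: float = 0.9
    endpoint_noise_sd: float = 0.6
    fixation_drift_sd: float | None = None  # default: 0.65 * endpoint_noise_sd
    corrective_trigger_threshold: float = 0.5
    corrective_latency_mean: float = 200.0
    corrective_latency_sd: float = 40.0
    position_noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ConfigurationError("n_trials must be >= 1")
        if self.target_eccentricity <= 0:
            raise ConfigurationError("target_eccentricity must be > 0")
        if not (0.0 < self.fatigue_velocity_ratio <= 1.0):
            raise ConfigurationError("fatigue_velocity_ratio must lie in (0, 1]")
        if self.endpoint_noise_sd < 0 or self.position_noise_sd < 0:
            raise ConfigurationError("noise SDs must be >= 0")
        if self.fixation_drift_sd is None:
            # slow fixational drift inside the 2x2 deg fixation window;
            # scales with endpoint scatter so noiseless configs stay exact
            self.fixation_drift_sd = 0.65 * self.endpoint_noise_sd
        for name in ("fixation_duration_range", "target_display_duration_range"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ConfigurationError(f"{name} must be an increasing positive pair")
        if self.cf_direction not in (-1, 1):
            raise ConfigurationError("cf_direction must be +1 or -1")
        # the saccadic chain must fit inside its epoch of the trial
        cf_chain = (self.saccade_latency_mean + 2 * self.saccade_latency_sd
                    + self.corrective_latency_mean + 2 * self.corrective_latency_sd
                    + 120.0)
        if cf_chain > self.target_display_duration_range[0]:
            raise ConfigurationError(
                "primary + corrective saccade chain does not fit within the "
                "minimum target display duration")
        cp_chain = self.cp_latency_mean + 3 * self.cp_latency_sd + 100.0
        if cp_chain > self.fixation_duration_range[0] + self.intertrial_interval:
            raise ConfigurationError(
                "CP return saccade chain does not fit before the go-signal")
        if (self.fixation_duration_range[1] + self.target_display_duration_range[1]
                > 1.5 * self.trial_duration):
            raise ConfigurationError("trial events do not fit within trial_duration")


@dataclass
class NeuronTuning:
    """Generative tuning of one simulated Purkinje cell's CS/SS discharge.

    Gains are peak rates in spikes/s (bursts are Gaussian bumps), slopes are
    spikes/s per deg.  ``pd_*`` are signed preferred directions (+1 right,
    -1 left).  The primary burst is locked ``burst_latency`` ms after saccade
    offset; the error tonic component occupies the late postsaccadic window
    (50–250 ms from primary offset) with rate proportional to the signed
    error projected onto ``pd_error``.
    """

    cs_baseline_rate: float = 1.0
    pd_primary: int = 1
    pd_corrective: int = 1
    pd_error: int = 1
    burst_gain_preferred: float = 3.0
    burst_gain_anti: float = 1.0
    amplitude_slope: float = 0.3
    burst_latency: float = 20.0
    burst_width: float = 10.0
    error_tonic_gain: float = 0.5
    corrective_burst_gain: float = 2.5
    corrective_anti_fraction: float = 0.3
    trial_onset_gain: float = 2.0
    trial_onset_latency: float = 200.0
    trial_onset_width: float = 30.0
    trial_onset_arrival_slope: float = 0.002
    suppression_window: tuple[float, float] = (-75.0, 85.0)
    suppression_depth: float = 0.8
    cs_base_duration: float = 4.2
    cs_spikelet_increment: float = 1.8
    spikelet_base_prob: float = 0.3
    spikelet_prob_gain: float = 0.05
    ss_baseline_rate: float = 60.0
    ss_pause_range: tuple[float, float] = (10.0, 20.0)

    def __post_init__(self) -> None:
        if min(self.cs_baseline_rate, self.ss_baseline_rate) < 0:
            raise ValueError("baseline rates must be >= 0")
        if not (0.0 <= self.suppression_depth <= 1.0):
            raise ValueError("suppression_depth must lie in [0, 1]")
        if self.cs_base_duration <= 0:
            raise ValueError("cs_base_duration must be > 0")
        if not (0.0 <= self.spikelet_base_prob <= 1.0):
            raise ValueError("spikelet_base_prob must lie in [0, 1]")
        for pd_name in ("pd_primary", "pd_corrective", "pd_error"):
            if getattr(self, pd_name) not in (-1, 1):
                raise ValueError(f"{pd_name} must be +1 or -1")


@dataclass
class GroundTruth:
    """Everything the generator knows; never read by the analysis modules."""

    trials: pd.DataFrame
    saccades: pd.DataFrame
    session_duration: float  # ms
    config: SessionConfig
    tuning: NeuronTuning | None = None
    cs_rate_time: np.ndarray | None = None
    cs_rate: np.ndarray | None = None
    cs_table: pd.DataFrame | None = None


def minimum_jerk_position(tau: np.ndarray) -> np.ndarray:
    """Normalized minimum-jerk displacement profile on tau in [0, 1]."""
    tau = np.clip(tau, 0.0, 1.0)
    return 10 * tau**3 - 15 * tau**4 + 6 * tau**5


def minimum_jerk_peak_velocity(amplitude: float, duration_ms: float) -> float:
    """Closed-form peak velocity (deg/s) of a minimum-jerk saccade."""
    return 1.875 * amplitude / (duration_ms / 1000.0)


def _saccade_duration(amplitude: float) -> float:
    """Unfatigued main-sequence duration (ms) for a saccade amplitude (deg).

    Affine main sequence: 40 ms at 15 deg, ~25 ms for tiny corrective
    saccades, keeping corrective peak velocities above the 10 deg/s
    detection threshold down to 0.2 deg.
    """
    return 25.0 + abs(amplitude)


def generate_behavior(config: SessionConfig):
    """Simulate the eye trace, trial table, and ground-truth saccade list.

    Returns ``(time_ms, horizontal_deg, vertical_deg, trials, truth)`` where
    ``trials`` is the trial table and ``truth`` a :class:`GroundTruth` whose
    ``saccades`` frame holds the true kinematics of every generated movement
    (primary CF/CP and corrective).
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    ecc = config.target_eccentricity
    n = config.n_trials

    trials = []
    saccades = []  # dicts; trace is rendered afterwards
    t0 = 300.0  # lead-in before the first trial
    eye = 0.0

    def vel_multiplier(k: int) -> float:
        if n == 1:
            return 1.0
        return config.fatigue_velocity_ratio ** (k / (n - 1))

    def add_saccade(onset, start, end, k, sac_type, subtype, goal):
        amp = abs(end - start)
        dur = _saccade_duration(amp)
        if sac_type == "primary":
            dur = dur / vel_multiplier(k)  # fatigue: slower but longer
        pv = minimum_jerk_peak_velocity(amp, dur)
        saccades.append(dict(
            assoc_trial=k, type=sac_type, subtype=subtype,
            onset=onset, offset=onset + dur, duration=dur,
            amplitude=amp, peak_velocity=pv,
            direction=int(np.sign(end - start)) if end != start else 0,
            start_pos=start, end_pos=end,
            signed_error=goal - end,
        ))
        return onset + dur, end

    for k in range(n):
        fix_dur = rng.uniform(*config.fixation_duration_range)
        go = t0 + fix_dur

        # CP return saccade from the previous target back to the fixation dot
        if k > 0:
            cp_onset = t0 + rng.normal(config.cp_latency_mean, config.cp_latency_sd)
            cp_onset = max(cp_onset, prev_free + 5.0)
            cp_end = 0.0 + rng.normal(0.0, config.endpoint_noise_sd)
            eye = eye + rng.normal(0.0, config.fixation_drift_sd)
            cp_off, eye = add_saccade(cp_onset, eye, cp_end, k, "primary", "CP", 0.0)
            cp_err = 0.0 - cp_end
            if abs(cp_err) > config.corrective_trigger_threshold:
                c_on = cp_off + max(
                    60.0, rng.normal(config.corrective_latency_mean,
                                     config.corrective_latency_sd))
                c_end = 0.0 + rng.normal(0.0, 0.1)
                c_on = min(c_on, go - 80.0)
                if c_on >= cp_off + 30.0:
                    _, eye = add_saccade(c_on, eye, c_end, k, "corrective", "none", 0.0)
            cp_offset_time = cp_off
        else:
            cp_offset_time = np.nan

        target = ecc * config.cf_direction
        cf_onset = go + max(80.0, rng.normal(config.saccade_latency_mean,
                                             config.saccade_latency_sd))
        cf_end = target + rng.normal(0.0, config.endpoint_noise_sd)
        eye = eye + rng.normal(0.0, config.fixation_drift_sd)
        cf_off, eye = add_saccade(cf_onset, eye, cf_end, k, "primary", "CF", target)
        cf_err = target - cf_end
        prev_free = cf_off
        if abs(cf_err) > config.corrective_trigger_threshold:
            c_on = cf_off + max(
                60.0, rng.normal(config.corrective_latency_mean,
                                 config.corrective_latency_sd))
            c_end = target + rng.normal(0.0, 0.1)
            _, eye = add_saccade(c_on, eye, c_end, k, "corrective", "none", target)
            prev_free = c_on + _saccade_duration(abs(c_end - cf_end))

        display = rng.uniform(*config.target_display_duration_range)
        trials.append(dict(
            trial=k, trial_onset=t0, target_jump_time=go,
            target_pos_deg=target, fixation_pos_deg=0.0,
            cp_offset=cp_offset_time, reward=True,
        ))
        t0 = go + display + config.intertrial_interval

    trials = pd.DataFrame(trials)
    sac = pd.DataFrame(saccades).sort_values("onset").reset_index(drop=True)

    total = float(sac["offset"].max() + 500.0)
    dt = 1000.0 / config.sampling_rate
    t = np.arange(0.0, total, dt)
    x = np.zeros_like(t)
    pos = 0.0
    prev_off = 0.0
    for row in sac.itertuples():
        i0, i1, i2 = np.searchsorted(t, [prev_off, row.onset, row.offset])
        # slow fixational drift ramp from the previous landing position to
        # this saccade's start (velocity well below detection thresholds)
        if i1 > i0:
            x[i0:i1] = np.linspace(pos, row.start_pos, i1 - i0)
        tau = (t[i1:i2] - row.onset) / row.duration
        x[i1:i2] = row.start_pos \
            + (row.end_pos - row.start_pos) * minimum_jerk_position(tau)
        pos = row.end_pos
        prev_off = row.offset
    x[np.searchsorted(t, prev_off):] = pos
    if config.position_noise_sd > 0:
        x = x + rng.normal(0.0, config.position_noise_sd, size=x.size)
        y = rng.normal(0.0, config.position_noise_sd, size=x.size)
    else:
        y = np.zeros_like(x)

    truth = GroundTruth(trials=trials, saccades=sac, session_duration=total,
                        config=config)
    return t, x, y, trials, truth


def _add_gaussian_bump(rate, t_grid, center, sd, amplitude):
    if amplitude <= 0:
        return
    lo = np.searchsorted(t_grid, center - 4 * sd)
    hi = np.searchsorted(t_grid, center + 4 * sd)
    tt = t_grid[lo:hi]
    rate[lo:hi] += amplitude * np.exp(-0.5 * ((tt - center) / sd) ** 2)


def latent_cs_rate(tuning: NeuronTuning, truth: GroundTruth):
    """Latent CS rate lambda(t) (spikes/s) on a 1-ms grid over the session."""
    t_grid = np.arange(0.0, truth.session_duration, RATE_DT)
    base = np.full(t_grid.size, tuning.cs_baseline_rate)
    extra = np.zeros_like(base)
    ecc = truth.config.target_eccentricity

    prim = truth.saccades[truth.saccades["type"] == "primary"]
    corr = truth.saccades[truth.saccades["type"] == "corrective"]

    for row in prim.itertuples():
        # perisaccadic suppression of the baseline
        s0 = row.onset + tuning.suppression_window[0]
        s1 = row.onset + tuning.suppression_window[1]
        lo, hi = np.searchsorted(t_grid, [s0, s1])
        base[lo:hi] *= (1.0 - tuning.suppression_depth)
        # offset-locked saccade burst
        gain = (tuning.burst_gain_preferred if row.direction == tuning.pd_primary
                else tuning.burst_gain_anti)
        gain += tuning.amplitude_slope * (row.amplitude - ecc)
        _add_gaussian_bump(extra, t_grid, row.offset + tuning.burst_latency,
                           tuning.burst_width, max(gain, 0.0))
        # error tonic component in the late postsaccadic window
        e_signed = row.signed_error * tuning.pd_error
        lo, hi = np.searchsorted(t_grid, [row.offset + 50.0, row.offset + 250.0])
        extra[lo:hi] += tuning.error_tonic_gain * e_signed

    for row in corr.itertuples():
        gain = tuning.corrective_burst_gain * (
            1.0 if row.direction == tuning.pd_corrective
            else tuning.corrective_anti_fraction)
        gain *= row.amplitude  # amplitude-proportional corrective burst
        _add_gaussian_bump(extra, t_grid, row.offset + tuning.burst_latency,
                           tuning.burst_width, max(gain, 0.0))

    for row in truth.trials.itertuples():
        lateness = 0.0
        if np.isfinite(row.cp_offset):
            lateness = max(0.0, row.cp_offset - row.trial_onset)
        amp = tuning.trial_onset_gain * (
            1.0 - tuning.trial_onset_arrival_slope * lateness)
        _add_gaussian_bump(extra, t_grid,
                           row.trial_onset + tuning.trial_onset_latency,
                           tuning.trial_onset_width, max(amp, 0.0))

    return t_grid, np.clip(base + extra, 0.0, None)


def generate_spikes(tuning: NeuronTuning, truth: GroundTruth, seed: int):
    """Draw CS and SS trains for a generated session.

    CS times come from thinning the latent rate; each CS receives a duration
    of ``cs_base_duration`` plus, with probability
    ``clip(spikelet_base_prob + spikelet_prob_gain * (lambda - baseline), 0, 1)``,
    one ``cs_spikelet_increment``.  SSs are homogeneous Poisson with an
    enforced pause (uniform ``ss_pause_range``) after every CS.

    Returns ``(cs_table, ss_times)``; also records the latent rate and the CS
    table in ``truth``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 1]))
    t_grid, lam = latent_cs_rate(tuning, truth)
    total_s = truth.session_duration / 1000.0

    lam_max = float(lam.max())
    if lam_max > 0:
        n_cand = rng.poisson(lam_max * total_s)
        cand = np.sort(rng.uniform(0.0, truth.session_duration, size=n_cand))
        lam_at = np.interp(cand, t_grid, lam)
        keep = rng.uniform(0.0, lam_max, size=n_cand) < lam_at
        cs_times = cand[keep]
    else:
        cs_times = np.empty(0)

    lam_cs = np.interp(cs_times, t_grid, lam)
    p_long = np.clip(tuning.spikelet_base_prob
                     + tuning.spikelet_prob_gain * (lam_cs - tuning.cs_baseline_rate),
                     0.0, 1.0)
    is_long = rng.uniform(size=cs_times.size) < p_long
    durations = tuning.cs_base_duration + tuning.cs_spikelet_increment * is_long
    cs_table = pd.DataFrame({"time_ms": cs_times, "duration_ms": durations,
                             "is_long": is_long})

    n_ss = rng.poisson(tuning.ss_baseline_rate * total_s)
    ss = np.sort(rng.uniform(0.0, truth.session_duration, size=n_ss))
    if cs_times.size:
        pauses = rng.uniform(*tuning.ss_pause_range, size=cs_times.size)
        idx = np.searchsorted(cs_times, ss) - 1
        valid = idx >= 0
        blocked = np.zeros(ss.size, dtype=bool)
        blocked[valid] = ss[valid] - cs_times[idx[valid]] < pauses[idx[valid]]
        ss = ss[~blocked]

    truth.tuning = tuning
    truth.cs_rate_time = t_grid
    truth.cs_rate = lam
    truth.cs_table = cs_table
    return cs_table, ss


def simulate_session(config: SessionConfig, tuning: NeuronTuning):
    """Generate one full session (behavior + spikes).

    Returns ``(session, truth)`` where ``session`` is an
    :class:`cspike.io.Session` ready for the analysis pipeline.
    """
    from .io import Session  # deferred to avoid an import cycle

    t, x, y, trials, truth = generate_behavior(config)
    cs_table, ss = generate_spikes(tuning, truth, config.seed)
    meta = {
        "session_id": f"synthetic-{config.seed}",
        "monkey_id": "synthetic",
        "cf_direction": "right" if config.cf_direction == 1 else "left",
        "sampling_rate": config.sampling_rate,
        "config": {k: list(v) if isinstance(v, tuple) else v
                   for k, v in asdict(config).items()},
    }
    session = Session(
        time_ms=t, horizontal_deg=x, vertical_deg=y,
        trials=trials.drop(columns=["cp_offset"]),
        cs=cs_table.drop(columns=["is_long"]).copy(),
        ss_times=ss, metadata=meta,
    )
    return session, truth
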