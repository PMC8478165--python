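"""Saccade detection, error sign conventions, and fatigue summaries."""

import numpy as np
import pandas as pd
import pytest

from cspike import behavior
from cspike.synth import (SessionConfig, generate_behavior,
                          minimum_jerk_position, simulate_session,
                          NeuronTuning)


def make_trace(duration_ms=2000.0, fs=1000.0):
    t = np.arange(0.0, duration_ms, 1000.0 / fs)
    return t, np.zeros_like(t)


def insert_minjerk(t, x, onset, dur, start, end):
    tau = np.clip((t - onset) / dur, 0.0, 1.0)
    x += start + (end - start) * minimum_jerk_position(tau) - (x * 0)
    return x


def single_saccade_trace(amp=15.0, dur=40.0, onset=1000.0):
    t, x = make_trace()
    tau = np.clip((t - onset) / dur, 0.0, 1.0)
    x = amp * minimum_jerk_position(tau)
    return t, x


class TestVelocity:
    def test_constant_position_gives_zero_velocity(self):
        t, x = make_trace()
        assert np.allclose(behavior.compute_velocity(t, x + 3.0), 0.0)

    def test_linear_ramp_velocity(self):
        t, _ = make_trace()
        x = 0.1 * t  # 100 deg/s
        v = behavior.compute_velocity(t, x)
        assert np.allclose(v[100:-100], 100.0, atol=0.5)

    def test_minimum_jerk_peak_velocity_within_2_percent(self):
        t, x = single_saccade_trace()
        v = behavior.compute_velocity(t, x)
        assert abs(np.max(np.abs(v)) - 703.125) / 703.125 < 0.02

    def test_short_trace_raises(self):
        with pytest.raises(ValueError):
            behavior.compute_velocity(np.arange(10.0), np.zeros(10))


class TestPrimaryDetection:
    def test_single_saccade_recovered(self):
        t, x = single_saccade_trace()
        v = behavior.compute_velocity(t, x)
        ev = behavior.detect_primary_saccades(t, x, v)
        assert len(ev) == 1
        assert ev.loc[0, "amplitude"] == pytest.approx(15.0, abs=0.1)
        assert ev.loc[0, "onset"] == pytest.approx(1000.0, abs=3.0)
        assert ev.loc[0, "offset"] == pytest.approx(1040.0, abs=3.0)

    def test_subthreshold_movement_ignored(self):
        # 25 deg/s peak < 30 deg/s threshold
        t, _ = make_trace(4000.0)
        amp, dur = 8.0, 600.0  # peak = 1.875*8/0.6 = 25 deg/s
        tau = np.clip((t - 1000.0) / dur, 0.0, 1.0)
        x = amp * minimum_jerk_position(tau)
        v = behavior.compute_velocity(t, x)
        assert np.max(np.abs(v)) < 30.0
        assert behavior.detect_primary_saccades(t, x, v).empty

    def test_ten_degree_saccade_excluded_from_primaries(self):
        t, x = single_saccade_trace(amp=10.0, dur=35.0)
        v = behavior.compute_velocity(t, x)
        assert behavior.detect_primary_saccades(t, x, v).empty


class TestCorrectiveDetection:
    def _with_primary_and_blip(self, blip_amp, blip_dur, blip_onset=1300.0):
        t, x = single_saccade_trace()
        tau = np.clip((t - blip_onset) / blip_dur, 0.0, 1.0)
        x = x + blip_amp * minimum_jerk_position(tau)
        v = behavior.compute_velocity(t, x)
        prim = behavior.detect_primary_saccades(t, x, v)
        return behavior.detect_corrective_saccades(t, x, v, prim)

    def test_one_degree_corrective_detected(self):
        # 1 deg / 25 ms: min-jerk peak 75 deg/s, duration and amplitude pass
        ev = self._with_primary_and_blip(1.0, 25.0)
        assert len(ev) == 1
        assert ev.loc[0, "amplitude"] == pytest.approx(1.0, abs=0.05)

    def test_brief_blip_rejected_by_duration_rule(self):
        ev = self._with_primary_and_blip(0.5, 8.0)
        assert ev.empty

    def test_tiny_drift_rejected_by_amplitude_rule(self):
        ev = self._with_primary_and_blip(0.1, 25.0)
        assert ev.empty

    def test_correctives_never_overlap_primaries(self):
        session, _ = simulate_session(SessionConfig(n_trials=80, seed=6),
                                      NeuronTuning())
        ev = behavior.detect_events(session)
        prim = ev[ev["type"] == "primary"]
        corr = ev[ev["type"] == "corrective"]
        for c in corr.itertuples():
            assert not np.any((c.onset < prim["offset"].to_numpy())
                              & (c.offset > prim["onset"].to_numpy()))


class TestClassifyAndError:
    TRIALS = pd.DataFrame({
        "trial": [0], "trial_onset": [500.0], "target_jump_time": [1000.0],
        "target_pos_deg": [15.0], "fixation_pos_deg": [0.0], "reward": [True]})

    def _event(self, start, end):
        return pd.DataFrame({
            "onset": [1200.0], "offset": [1240.0],
            "amplitude": [abs(end - start)], "duration": [40.0],
            "peak_velocity": [700.0],
            "direction": [int(np.sign(end - start))],
            "type": ["primary"], "subtype": ["none"],
            "start_pos": [start], "end_pos": [end],
            "signed_error": [np.nan], "assoc_trial": [-1]})

    def test_rightward_overshoot_gives_leftward_error(self):
        ev = behavior.classify_and_error(self._event(0.0, 15.5), self.TRIALS)
        assert ev.loc[0, "subtype"] == "CF"
        assert ev.loc[0, "signed_error"] == pytest.approx(-0.5)

    def test_rightward_undershoot_gives_rightward_error(self):
        ev = behavior.classify_and_error(self._event(0.0, 14.2), self.TRIALS)
        assert ev.loc[0, "signed_error"] == pytest.approx(0.8)

    def test_cp_overshoot_past_fixation(self):
        ev = behavior.classify_and_error(self._event(15.0, -0.3), self.TRIALS)
        assert ev.loc[0, "subtype"] == "CP"
        assert ev.loc[0, "signed_error"] == pytest.approx(0.3)

    def test_unbracketed_primary_warns_and_stays_none(self):
        ev = self._event(0.0, 15.0)
        ev["onset"] = 100.0  # before any trial
        with pytest.warns(UserWarning):
            out = behavior.classify_and_error(ev, self.TRIALS)
        assert out.loc[0, "subtype"] == "none"

    def test_cf_overshoot_error_always_negative(self):
        """Sign convention: rightward CF overshoot -> leftward error."""
        session, truth = simulate_session(
            SessionConfig(n_trials=60, seed=8), NeuronTuning())
        ev = behavior.detect_events(session)
        cf = ev[(ev["subtype"] == "CF") & (ev["end_pos"] > 15.0)]
        assert len(cf) > 0
        assert (cf["signed_error"] < 0).all()


class TestFatigue:
    def test_no_fatigue_gives_near_zero_change(self):
        session, _ = simulate_session(
            SessionConfig(n_trials=120, fatigue_velocity_ratio=1.0, seed=14),
            NeuronTuning())
        ev = behavior.detect_events(session)
        out = behavior.fatigue_summary([ev])
        assert np.abs(out.pooled["pct_change_peak_velocity"]).max() < 3.0

    def test_ten_percent_fatigue_recovered(self):
        n, ratio = 200, 0.9
        session, _ = simulate_session(
            SessionConfig(n_trials=n, fatigue_velocity_ratio=ratio, seed=0),
            NeuronTuning())
        ev = behavior.detect_events(session)
        out = behavior.fatigue_summary([ev])
        cf = out.per_session[out.per_session["subtype"] == "CF"].iloc[0]
        # oracle: the generator decay law ratio**(k/(n-1)) evaluated at the
        # median trial indices of the early/late 30-trial windows
        m_early = ratio ** (14.5 / (n - 1))
        m_late = ratio ** ((n - 15.5) / (n - 1))
        expected = 100.0 * (1.0 - m_late / m_early)  # = 8.6%
        assert cf["pct_change_peak_velocity"] == pytest.approx(expected, abs=2.0)
        # endpoint scatter (SD 0.6 deg) leaves ~1.3% sampling noise on the
        # 30-trial amplitude medians; the change should be indistinguishable
        # from zero at ~2 sigma while velocity/duration changes are large
        assert abs(cf["pct_change_amplitude"]) < 3.0
        assert cf["pct_change_duration"] < -5.0  # duration increases

    def test_constant_events_give_exactly_zero(self):
        ev = pd.DataFrame({
            "onset": np.arange(80) * 1000.0,
            "type": "primary", "subtype": "CF",
            "peak_velocity": 600.0, "duration": 40.0, "amplitude": 15.0})
        out = behavior.fatigue_summary([ev], n_edge_trials=30)
        assert (out.per_session["pct_change_peak_velocity"] == 0.0).all()

    def test_short_session_skipped(self):
        ev = pd.DataFrame({
            "onset": [0.0], "type": ["primary"], "subtype": ["CF"],
            "peak_velocity": [600.0], "duration": [40.0], "amplitude": [15.0]})
        out = behavior.fatigue_summary([ev])
        assert out.per_session.empty
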