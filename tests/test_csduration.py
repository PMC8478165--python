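"""CS-duration percent-change profiles, epoch detection, duration tuning."""

import numpy as np
import pandas as pd
import pytest

from conftest import quiet_tuning
from cspike.csduration import (detect_epochs, duration_tuning,
                               percent_change_series,
                               population_percent_change)
from cspike.rates import AlignedSpikes
from cspike.synth import SessionConfig, generate_behavior, generate_spikes
from cspike.rates import align


def aligned_with_durations(offsets, durations, window=(-300.0, 500.0)):
    return AlignedSpikes(
        offsets=[np.asarray(o, float) for o in offsets],
        events=pd.DataFrame({"direction": [1] * len(offsets)}),
        alignment="saccade_onset", window=window,
        extras=[np.asarray(d, float) for d in durations])


class TestPercentChange:
    def test_uniform_durations_give_zero_everywhere(self):
        al = aligned_with_durations([[-100.0, 0.0, 100.0]] * 10,
                                    [[5.0, 5.0, 5.0]] * 10)
        s = percent_change_series(al)
        assert np.nanmax(np.abs(s.percent_change)) == 0.0

    def test_locally_longer_css_raise_their_bin(self):
        # CSs at +100 ms are 20% longer than the cell mean elsewhere
        offsets = [[-200.0, 100.0]] * 20
        durations = [[5.0, 6.0]] * 20
        al = aligned_with_durations(offsets, durations)
        s = percent_change_series(al, cell_mean_duration=5.0)
        m = (s.bin_centers > 75.0) & (s.bin_centers < 125.0)
        assert np.nanmean(s.percent_change[m]) == pytest.approx(20.0)

    def test_requires_durations(self):
        al = AlignedSpikes(offsets=[np.array([0.0])],
                           events=pd.DataFrame({"direction": [1]}),
                           alignment="saccade_onset", window=(-300.0, 500.0))
        with pytest.raises(ValueError):
            percent_change_series(al)

    def test_generator_rate_yoked_durations_modulate(self):
        """Spikelet probability yoked to the rate burst produces a positive
        postsaccadic duration change and a perisaccadic dip (population of
        cells; single cells fire too few perisaccadic CSs to resolve it)."""
        cfg = SessionConfig(n_trials=400, seed=50)
        _, _, _, _, truth = generate_behavior(cfg)
        tun = quiet_tuning(burst_gain_preferred=8.0, burst_gain_anti=8.0,
                           suppression_depth=0.6, spikelet_base_prob=0.35,
                           spikelet_prob_gain=0.08)
        prim = truth.saccades[truth.saccades["type"] == "primary"]
        series = []
        for i in range(8):
            cs, _ = generate_spikes(tun, truth, seed=700 + i)
            al = align(cs["time_ms"].to_numpy(), prim, "saccade_onset",
                       (-300.0, 500.0),
                       spike_payload=cs["duration_ms"].to_numpy(),
                       dedupe=True)
            series.append(percent_change_series(
                al, cell_mean_duration=float(cs["duration_ms"].mean())))
        prof = population_percent_change(series)
        burst_bins = (prof.bin_centers > 50.0) & (prof.bin_centers < 110.0)
        peri = (prof.bin_centers > -50.0) & (prof.bin_centers < 10.0)
        assert np.nanmean(prof.mean[burst_bins]) > 2.0
        assert np.nanmean(prof.mean[peri]) < -1.0


class TestDetectEpochs:
    CENTERS = np.arange(-275.0, 480.0, 10.0)

    def test_flat_profile_has_no_epochs(self):
        rng = np.random.default_rng(0)
        prof = rng.normal(0.0, 1.0, self.CENTERS.size) * 0 + \
            np.sin(self.CENTERS / 500.0) * 0.0
        ep = detect_epochs(self.CENTERS, prof)
        assert ep.decrease_epochs == [] and ep.increase_epochs == []

    def test_injected_dip_recovered_within_one_bin(self):
        rng = np.random.default_rng(1)
        sem = np.ones(self.CENTERS.size)
        prof = rng.normal(0.0, 1.0, self.CENTERS.size)
        dip = (self.CENTERS >= 100.0) & (self.CENTERS < 200.0)
        prof[dip] -= 5.0  # 5 x the per-bin sampling SD
        ep = detect_epochs(self.CENTERS, prof, sem=sem)
        hits = [e for e in ep.decrease_epochs
                if e[1] >= 100.0 and e[0] <= 200.0]
        assert len(hits) == 1
        lo, hi = hits[0]
        assert abs(lo - 100.0) <= 50.0
        assert abs(hi - 200.0) <= 50.0

    def test_infinite_threshold_gives_no_epochs(self):
        rng = np.random.default_rng(2)
        prof = rng.normal(0.0, 1.0, self.CENTERS.size)
        ep = detect_epochs(self.CENTERS, prof, k=np.inf)
        assert ep.decrease_epochs == [] and ep.increase_epochs == []

    def test_empty_baseline_rejected(self):
        with pytest.raises(ValueError):
            detect_epochs(np.arange(0.0, 100.0, 10.0), np.zeros(10))

    def test_detection_is_deterministic(self):
        rng = np.random.default_rng(3)
        prof = rng.normal(0.0, 1.0, self.CENTERS.size)
        a = detect_epochs(self.CENTERS, prof)
        b = detect_epochs(self.CENTERS, prof)
        assert a == b


class TestDurationTuning:
    def _cells(self, err_gain, n_cells=4, seed=0):
        """Cells whose CS durations depend linearly on signed error."""
        rng = np.random.default_rng(seed)
        cells = []
        for _ in range(n_cells):
            offsets, durs, errs, dirs = [], [], [], []
            for _ in range(300):
                e = rng.uniform(-2, 2)
                k = rng.poisson(0.8)
                offsets.append(rng.uniform(100.0, 250.0, k))
                durs.append(5.0 + err_gain * e + rng.normal(0.0, 0.3, k))
                errs.append(e)
                dirs.append(rng.choice([-1, 1]))
            ev = pd.DataFrame({"signed_error": errs, "direction": dirs,
                               "amplitude": 15.0})
            cells.append(AlignedSpikes(
                offsets=offsets, events=ev, alignment="saccade_offset",
                window=(-300.0, 500.0), extras=durs))
        return cells

    def test_error_coupled_durations_recovered(self):
        out = duration_tuning(self._cells(0.3), "signed_error",
                              (100.0, 250.0), 0.5, (-2.0, 2.0))
        for d in (1, -1):
            assert out[d]["fit"]["slope"] > 0.0

    def test_error_sign_flip_negates_slope(self):
        cells = self._cells(0.3, seed=4)
        out_pos = duration_tuning(cells, "signed_error", (100.0, 250.0),
                                  0.5, (-2.0, 2.0))
        flipped = [AlignedSpikes(c.offsets,
                                 c.events.assign(
                                     signed_error=-c.events["signed_error"]),
                                 c.alignment, c.window, c.extras)
                   for c in cells]
        out_neg = duration_tuning(flipped, "signed_error", (100.0, 250.0),
                                  0.5, (-2.0, 2.0))
        assert out_neg[1]["fit"]["slope"] == pytest.approx(
            -out_pos[1]["fit"]["slope"], rel=1e-9)

    def test_uncoupled_durations_give_null_slope(self):
        out = duration_tuning(self._cells(0.0, seed=5), "signed_error",
                              (100.0, 250.0), 0.5, (-2.0, 2.0))
        lo, hi = out[1]["fit"]["slope_ci"]
        assert lo < 0.0 < hi


def test_shuffled_durations_produce_no_epochs():
    """Permutation null: duration-shuffled trains give a flat profile."""
    cfg = SessionConfig(n_trials=300, seed=60)
    _, _, _, _, truth = generate_behavior(cfg)
    tun = quiet_tuning(burst_gain_preferred=8.0, burst_gain_anti=8.0,
                       suppression_depth=0.9, spikelet_base_prob=0.35,
                       spikelet_prob_gain=0.08)
    prim = truth.saccades[truth.saccades["type"] == "primary"]
    rng = np.random.default_rng(7)
    cells = []
    for i in range(12):
        cs, _ = generate_spikes(tun, truth, seed=600 + i)
        cells.append((cs["time_ms"].to_numpy(),
                      cs["duration_ms"].to_numpy()))
    clean = 0
    n_shuffles = 30
    for s in range(n_shuffles):
        series = []
        for t, d in cells:
            dp = rng.permutation(d)
            al = align(t, prim, "saccade_onset", (-300.0, 500.0),
                       spike_payload=dp, dedupe=True)
            series.append(percent_change_series(
                al, cell_mean_duration=float(d.mean())))
        prof = population_percent_change(series)
        ep = detect_epochs(prof.bin_centers, prof.mean,
                           sem=prof.sem_sampling)
        clean += not ep.decrease_epochs and not ep.increase_epochs
    assert clean >= round(0.95 * n_shuffles)
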