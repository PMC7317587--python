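"""HRV extraction: QRS detection, NN cleaning, tachogram, AR spectrum,
time-domain summaries."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import spearmanr

from neurovisceral import hrv, synth


class TestDetectRPeaks:
    def test_constant_train(self):
        rr = np.full(299, 1000.0)
        ecg = synth.generate_ecg(rr, fs=1000, seed=0)
        peaks = hrv.detect_r_peaks(ecg, 1000)
        assert abs(peaks.peak_times.size - 300) <= 1
        assert abs(peaks.rr_intervals_ms().mean() - 1000) < 2
        assert np.all(np.diff(peaks.peak_times) >= 0.2)

    def test_alternating_intervals_recovered(self):
        rr = np.array([800.0, 900.0] * 170)
        ecg = synth.generate_ecg(rr, fs=1000, seed=1)
        peaks = hrv.detect_r_peaks(ecg, 1000)
        rec = peaks.rr_intervals_ms()
        assert rec.size == rr.size
        assert np.max(np.abs(rec - rr)) <= 10.0

    def test_roundtrip_against_generator_truth(self, modulated_rr):
        rr, beats = modulated_rr
        ecg = synth.generate_ecg(rr, fs=1000, seed=4)
        peaks = hrv.detect_r_peaks(ecg, 1000)
        assert peaks.peak_times.size == beats.size
        err = np.abs(peaks.peak_times[:, None] - beats[None, :]).min(axis=0)
        assert err.max() <= 0.010  # within 10 ms of every true beat
        # recall and precision both >= 0.99
        hits = (err <= 0.010).sum()
        assert hits / beats.size >= 0.99
        assert hits / peaks.peak_times.size >= 0.99

    def test_flatline_raises(self):
        with pytest.raises(ValueError, match="no QRS|flatline"):
            hrv.detect_r_peaks(np.zeros(20000), 1000)

    def test_low_fs_raises(self):
        with pytest.raises(ValueError):
            hrv.detect_r_peaks(np.random.default_rng(0).normal(size=5000), 100)


class TestCleanNN:
    def test_single_ectopic_removed(self):
        nn = hrv.clean_nn(np.array([800.0, 810.0, 1200.0, 805.0, 800.0]))
        # |1200-810|/810 = 48% > 20% -> removed; 805 then compared to 810
        assert 2 in nn.removed_indices
        assert np.array_equal(nn.intervals, [800.0, 810.0, 805.0, 800.0])

    def test_constant_series_untouched(self):
        nn = hrv.clean_nn(np.full(100, 800.0))
        assert nn.removed_indices == ()
        assert nn.intervals.size == 100

    def test_nineteen_percent_boundary_kept(self):
        nn = hrv.clean_nn(np.array([1000.0, 1190.0, 1000.0, 1100.0, 1000.0]))
        assert 1 not in nn.removed_indices  # 19% <= 20%

    def test_physiological_gate(self):
        nn = hrv.clean_nn(np.array([800.0, 150.0, 810.0, 805.0, 3500.0, 800.0]))
        assert 1 in nn.removed_indices and 4 in nn.removed_indices

    def test_too_few_survivors_raises(self):
        with pytest.raises(ValueError, match="too short"):
            hrv.clean_nn(np.array([100.0, 100.0, 100.0, 100.0]))

    @settings(deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(min_value=300, max_value=2000), min_size=8, max_size=60)
    )
    def test_idempotent(self, values):
        rr = np.asarray(values)
        try:
            once = hrv.clean_nn(rr)
        except ValueError:
            return
        twice = hrv.clean_nn(once.intervals, once.onset_times)
        assert np.array_equal(once.intervals, twice.intervals)
        assert twice.removed_indices == ()

    def test_retained_neighbours_within_twenty_percent(self):
        rng = np.random.default_rng(0)
        rr = 800 + 400 * rng.standard_normal(200).cumsum() % 600
        nn = hrv.clean_nn(np.clip(rr, 250, 2900))
        rel = np.abs(np.diff(nn.intervals)) / nn.intervals[:-1]
        assert np.all(rel <= 0.20 + 1e-12)


class TestTachogram:
    def _nn(self, intervals, onsets=None):
        return hrv.clean_nn(np.asarray(intervals, dtype=float), onsets)

    def test_constant(self):
        tach = hrv.interpolate_tachogram(self._nn([1000.0] * 20))
        assert np.allclose(tach.values, 1000.0)
        assert tach.fs_interp == 4.0

    def test_linear_ramp_on_the_line(self):
        n = 40
        vals = np.linspace(800, 900, n)
        onsets = np.concatenate([[0.0], np.cumsum(vals[:-1]) / 1000.0])
        nn = hrv.NNIntervalSeries(intervals=vals, onset_times=onsets)
        tach = hrv.interpolate_tachogram(nn)
        grid = np.arange(onsets[0], onsets[-1] + 0.125, 0.25)
        grid = grid[grid <= onsets[-1]]
        expected = np.interp(grid, onsets, vals)
        assert np.max(np.abs(tach.values - expected)) < 0.5

    def test_five_minute_record_length(self, modulated_rr):
        rr, beats = modulated_rr
        nn = hrv.clean_nn(rr, beats[:-1])
        tach = hrv.interpolate_tachogram(nn)
        assert abs(tach.values.size - 1200) < 20  # ~300 s x 4 Hz

    def test_mean_preserved(self, modulated_rr):
        rr, beats = modulated_rr
        nn = hrv.clean_nn(rr, beats[:-1])
        tach = hrv.interpolate_tachogram(nn)
        assert abs(tach.values.mean() - nn.intervals.mean()) < 0.01 * nn.intervals.mean()


class TestARSpectrum:
    def test_pure_hf_sinusoid(self):
        t = np.arange(0, 300, 0.25)
        a = 40.0
        sp = hrv.ar_spectrum(hrv.Tachogram(values=800 + a * np.sin(2 * np.pi * 0.25 * t)))
        assert abs(sp.hf_power - a * a / 2) / (a * a / 2) < 0.10
        assert sp.hf_power > 50 * sp.lf_power

    def test_pure_lf_sinusoid(self):
        t = np.arange(0, 300, 0.25)
        a = 40.0
        sp = hrv.ar_spectrum(hrv.Tachogram(values=800 + a * np.sin(2 * np.pi * 0.10 * t)))
        assert abs(sp.lf_power - a * a / 2) / (a * a / 2) < 0.10
        assert sp.lf_power > 50 * max(sp.hf_power, 1e-12)

    def test_white_tachogram_band_ratio(self):
        # flat spectrum -> band powers proportional to bandwidths 0.11/0.25
        ratios = []
        for seed in range(6):
            x = 800 + 30 * np.random.default_rng(seed).standard_normal(1200)
            sp = hrv.ar_spectrum(hrv.Tachogram(values=x))
            ratios.append(sp.lf_power / sp.hf_power)
        assert abs(np.mean(ratios) - 0.11 / 0.25) < 0.12

    def test_total_power_matches_variance(self, modulated_rr):
        rr, beats = modulated_rr
        nn = hrv.clean_nn(rr, beats[:-1])
        tach = hrv.interpolate_tachogram(nn)
        sp = hrv.ar_spectrum(tach)
        from scipy.signal import detrend

        var = np.var(detrend(tach.values, type="linear"))
        assert abs(sp.total_power - var) / var < 0.15
        assert np.all(sp.psd >= 0)

    def test_zero_variance_raises(self):
        with pytest.raises(ValueError, match="degenerate"):
            hrv.ar_spectrum(hrv.Tachogram(values=np.full(200, 800.0)))

    def test_hf_monotone_in_generator_amplitude(self):
        amps = np.linspace(5, 60, 10)
        hfs = []
        for a in amps:
            spec = synth.RRGenSpec(
                mean_rr=850, lf_amp=20, hf_amp=a, noise_sd=5, duration_s=300, seed=7
            )
            rr, beats = synth.generate_rr_series(spec)
            nn = hrv.clean_nn(rr, beats[:-1])
            hfs.append(hrv.ar_spectrum(hrv.interpolate_tachogram(nn)).hf_power)
        assert spearmanr(amps, hfs).statistic > 0.9


class TestTimeDomain:
    def test_hand_enumerated_fixture(self):
        nn = hrv.NNIntervalSeries(
            intervals=np.array([800.0, 860.0, 870.0, 805.0, 810.0]),
            onset_times=np.array([0.0, 0.8, 1.66, 2.53, 3.335]),
        )
        td = hrv.time_domain(nn)
        # diffs: 60, 10, -65, 5 -> two of four exceed 50 ms
        assert td["pnn50"] == 50.0
        rmssd_oracle = np.sqrt((60**2 + 10**2 + 65**2 + 5**2) / 4)
        assert td["rmssd"] == pytest.approx(rmssd_oracle, rel=1e-12)
        assert td["rmssd"] == pytest.approx(44.58, abs=0.005)

    def test_constant_series(self):
        nn = hrv.NNIntervalSeries(
            intervals=np.full(300, 1000.0),
            onset_times=np.arange(300.0),
        )
        td = hrv.time_domain(nn)
        assert td["sdnn"] == td["sdnni"] == td["rmssd"] == td["pnn50"] == 0.0
        assert td["hr"] == 60.0

    def test_sdnni_separates_within_from_between_segment_variance(self):
        # six 50-s blocks, each internally constant at a different level:
        # per-segment SDs are 0 while the overall SD is positive
        levels = [800, 850, 900, 950, 1000, 1050]
        intervals, onsets, t = [], [], 0.0
        for lev in levels:
            while t < (levels.index(lev) + 1) * 50 - 1e-9:
                intervals.append(float(lev))
                onsets.append(t)
                t += lev / 1000.0
            t = (levels.index(lev) + 1) * 50.0
        nn = hrv.NNIntervalSeries(
            intervals=np.array(intervals), onset_times=np.array(onsets)
        )
        td = hrv.time_domain(nn)
        assert td["sdnni"] == 0.0
        assert td["sdnn"] > 0

    def test_rmssd_equals_direct_loop(self, modulated_rr):
        rr, beats = modulated_rr
        nn = hrv.clean_nn(rr, beats[:-1])
        td = hrv.time_domain(nn)
        acc = 0.0
        for i in range(1, nn.intervals.size):
            acc += (nn.intervals[i] - nn.intervals[i - 1]) ** 2
        assert td["rmssd"] == pytest.approx(np.sqrt(acc / (nn.intervals.size - 1)), rel=1e-12)


class TestEndToEnd:
    def test_lf_hf_ratio_recovered_across_seeds(self):
        ok = 0
        n_seeds = 20
        for seed in range(n_seeds):
            spec = synth.RRGenSpec(
                mean_rr=850, lf_amp=30, hf_amp=30, noise_sd=5, duration_s=300, seed=seed
            )
            rr, beats = synth.generate_rr_series(spec)
            nn = hrv.clean_nn(rr, beats[:-1])
            summ = hrv.hrv_summary(nn)
            if abs(summ.lf / summ.hf - 1.0) < 0.2:
                ok += 1
        assert ok >= int(0.9 * n_seeds)
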