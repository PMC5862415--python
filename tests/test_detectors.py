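"""Burst detectors: thresholds, seed/edge logic, MP atom filtering."""

import numpy as np
import pytest

from burstlab.detectors import (
    BurstEvent,
    compute_mp_threshold,
    compute_power_threshold,
    detect_cgt,
    detect_mp,
    detect_power_1d,
    detect_wavelet,
)
from burstlab.estimators import PowerSeries, cgt_spectrogram, wavelet_spectrogram
from burstlab.mp import AtomRecord
from burstlab.synthetic import GaborParams, InjectionRecord, generate_background, render_bursts

FS = 250.0


def _series(values, fs=FS, band=(40.0, 60.0), t0=0):
    values = np.asarray(values, dtype=float)
    times = (np.arange(values.size) - t0) / fs
    return PowerSeries(values=values, times=times, band=band)


def _atomrec(scale, shift, freq, coeff):
    return AtomRecord(GaborParams(scale, shift, freq), coefficient=coeff, iteration_index=0, residual_energy_after=0.5)


class TestPowerThreshold:
    def test_ratio_14_gives_threshold_near_7(self, small_trialset):
        ts, _, _ = small_trialset
        spec = compute_power_threshold(ts, "cgt", (40, 60), fraction=0.5)
        assert spec.power_threshold == pytest.approx(7.0, rel=0.2)

    def test_fraction_one_returns_ratio(self, small_trialset):
        ts, _, _ = small_trialset
        spec = compute_power_threshold(ts, "wavelet", (40, 60), fraction=1.0)
        assert spec.power_threshold == pytest.approx(spec.ratio)

    def test_no_burst_threshold_near_fraction(self, noise_trialset):
        spec = compute_power_threshold(noise_trialset, "hilbert", (40, 60), fraction=0.5)
        assert spec.power_threshold == pytest.approx(0.5, rel=0.25)

    def test_excess_mode(self, small_trialset):
        ts, _, _ = small_trialset
        a = compute_power_threshold(ts, "feingold", (40, 60), fraction=0.5)
        b = compute_power_threshold(ts, "feingold", (40, 60), fraction=0.5, mode="excess")
        assert b.power_threshold == pytest.approx(0.5 * (a.ratio - 1.0))


class TestMpThreshold:
    def test_fraction_scaling(self):
        decomps = [
            [_atomrec(0.05, -1.0, 50.0, 2.0)],
            [_atomrec(0.05, -0.5, 45.0, 4.0)],
        ]
        full = compute_mp_threshold(decomps, (40, 60), (-1.5, 0.0), fraction=1.0)
        assert full == pytest.approx(3.0)
        quarter = compute_mp_threshold(decomps, (40, 60), (-1.5, 0.0), fraction=0.25)
        assert quarter == pytest.approx(1.5)

    def test_missing_baseline_atom_contributes_zero(self):
        decomps = [[_atomrec(0.05, -1.0, 50.0, 2.0)], [_atomrec(0.05, 1.0, 50.0, 9.0)]]
        with pytest.warns(UserWarning):
            thr = compute_mp_threshold(decomps, (40, 60), (-1.5, 0.0), fraction=1.0)
        assert thr == pytest.approx(1.0)

    def test_all_zero_baseline(self):
        decomps = [[_atomrec(0.05, -1.0, 50.0, 0.0)]]
        assert compute_mp_threshold(decomps, (40, 60), (-1.5, 0.0), fraction=0.5) == 0.0


def _oracle_1d(p, times, threshold, edge_fraction, seed_window):
    """Independent scan: maximal runs above the edge level containing a seed."""
    edge = edge_fraction * threshold
    dt = float(times[1] - times[0])
    events = []
    i = 0
    n = p.size
    while i < n:
        if p[i] >= edge:
            j = i
            while j + 1 < n and p[j + 1] >= edge:
                j += 1
            run = np.arange(i, j + 1)
            seeds = run[p[run] > threshold]
            if seed_window is not None and seeds.size:
                seeds = seeds[(times[seeds] >= seed_window[0]) & (times[seeds] <= seed_window[1])]
            if seeds.size:
                events.append((max(float(times[j] - times[i]), dt), times[seeds[np.argmax(p[seeds])]]))
            i = j + 1
        else:
            i += 1
    return events


class TestDetectPower1D:
    def test_rectangular_pulse(self):
        p = np.full(1000, 0.01)
        p[200:301] = 10.0
        ev = detect_power_1d(_series(p), threshold=1.0)
        assert len(ev) == 1
        assert ev[0].duration == pytest.approx(100 / FS, abs=2 / FS)

    def test_all_below_threshold(self):
        ev = detect_power_1d(_series(np.full(500, 0.2)), threshold=1.0)
        assert ev == []

    def test_two_pulses_with_subedge_gap(self):
        p = np.full(1000, 0.01)
        p[100:200] = 5.0
        p[400:500] = 5.0
        ev = detect_power_1d(_series(p), threshold=1.0)
        assert len(ev) == 2

    def test_overlapping_edge_intervals_merge(self):
        p = np.full(1000, 0.01)
        p[100:200] = 5.0
        p[200:300] = 0.7  # above 0.5 * threshold: bridges the two seeds
        p[300:400] = 5.0
        ev = detect_power_1d(_series(p), threshold=1.0)
        assert len(ev) == 1

    def test_matches_oracle_randomized(self):
        # brute-force crossing enumeration on random piecewise-constant series
        rng = np.random.default_rng(12)
        for _ in range(200):
            n_seg = rng.integers(3, 15)
            lens = rng.integers(5, 60, n_seg)
            levels = rng.exponential(1.0, n_seg)
            p = np.repeat(levels, lens)
            s = _series(p)
            got = detect_power_1d(s, threshold=1.0, edge_fraction=0.5)
            want = _oracle_1d(p, s.times, 1.0, 0.5, None)
            assert len(got) == len(want)
            for e, (dur, t_seed) in zip(got, want):
                assert e.duration == pytest.approx(dur, abs=1e-12)
                assert e.t_center == pytest.approx(t_seed, abs=1e-12)


class TestDetectWavelet:
    def _burst_map(self, scale=0.1, freq=50.0, amp=5.0, extra=None):
        t = np.arange(-2.0, 2.0, 1 / FS)
        atoms = [GaborParams(scale, 1.0, freq, 0.3, amp)]
        if extra:
            atoms.append(extra)
        x = render_bursts(InjectionRecord([atoms]), t)[0]
        return wavelet_spectrogram(x, FS, freqs=np.arange(35.0, 66.0), t0_index=500)

    def test_high_snr_duration_matches_gaussian_blur_oracle(self):
        # closed form: the power envelope of a Gabor burst seen through a
        # Morlet of envelope sigma_w is Gaussian with sigma_c^2 = sigma_b^2 +
        # sigma_w^2; the extent at the edge level 0.5*threshold is
        # 2 sigma_c sqrt(ln(P0 / (0.5 thr)))
        from burstlab.estimators import wavelet_sigma_t

        m = self._burst_map(scale=0.1, freq=50.0)
        peak = m.power.max()
        for div in (4.0, 16.0):
            thr = peak / div
            ev = detect_wavelet(m, threshold=thr, band=(40, 60), stim_window=(0.5, 2.0))
            assert len(ev) == 1
            sigma_c = np.hypot(0.1, wavelet_sigma_t(9.0, ev[0].f_center))
            expected = 2 * sigma_c * np.sqrt(np.log(peak / (0.5 * thr)))
            assert ev[0].duration == pytest.approx(expected, rel=0.1)
        # at a level ~P0/16 the measured extent comes out near the 4-sigma
        # duration convention itself
        ev = detect_wavelet(m, threshold=peak / 16, band=(40, 60), stim_window=(0.5, 2.0))
        assert ev[0].duration == pytest.approx(0.4, rel=0.25)

    def test_empty_band(self):
        m = self._burst_map()
        ev = detect_wavelet(m, threshold=1.0, band=(80, 90), stim_window=(0.5, 2.0))
        assert ev == []

    def test_two_frequency_separated_bursts(self):
        m = self._burst_map(freq=43.0, extra=GaborParams(0.1, 1.0, 60.0, 1.0, 5.0))
        peak = m.power.max()
        ev = detect_wavelet(m, threshold=peak / 2, band=(38, 65), stim_window=(0.5, 2.0))
        assert len(ev) == 2
        got = sorted(e.f_center for e in ev)
        assert abs(got[0] - 43.0) < 3 and abs(got[1] - 60.0) < 3


class TestDetectCGT:
    def test_no_supra_threshold_point(self):
        t = np.arange(1000) / FS
        x = 0.01 * np.cos(2 * np.pi * 50 * t)
        m = cgt_spectrogram(x, FS, freqs=np.arange(40.0, 61.0))
        ev = detect_cgt(m, threshold=1.0, band=(40, 60), stim_window=(0.5, 2.0))
        assert ev == []

    def test_duration_matches_phase_walk_oracle(self):
        # noiseless off-grid sinusoid: extent set by the linear-mismatch drift
        t = np.arange(1000) / FS
        x = np.cos(2 * np.pi * 50.4 * t)
        m = cgt_spectrogram(x, FS, freqs=np.arange(40.0, 61.0), t0_index=0)
        ev = detect_cgt(m, threshold=m.power.max() * 0.5, band=(40, 60), stim_window=(1.0, 3.0))
        assert len(ev) >= 1
        e = max(ev, key=lambda e: e.peak_value)
        col = int(np.flatnonzero(m.freqs == e.f_center)[0])
        ti = int(np.argmin(np.abs(m.times - e.t_center)))
        ph = np.unwrap(np.angle(m.values[:, col]))
        dev = ph - ph[ti] - 2 * np.pi * e.f_center * (m.times - m.times[ti])
        ok = np.abs(dev) <= np.deg2rad(45.0)
        valid = np.flatnonzero(m.valid)
        lo = ti
        while lo - 1 >= valid[0] and ok[lo - 1]:
            lo -= 1
        hi = ti
        while hi + 1 <= valid[-1] and ok[hi + 1]:
            hi += 1
        assert e.duration == pytest.approx((hi - lo) / FS, abs=2 / FS)

    def test_rejects_real_map(self):
        times = np.arange(100) / FS
        from burstlab.estimators import TimeFrequencyMap

        m = TimeFrequencyMap(np.ones((100, 2)), times, np.array([45.0, 50.0]))
        with pytest.raises(ValueError):
            detect_cgt(m, 1.0, (40, 60), (0.0, 0.4))


class TestDetectMP:
    def test_duration_is_four_sigma(self):
        ev = detect_mp([_atomrec(0.1, 1.0, 50.0, 5.0)], 1.0, (40, 60), (0.5, 2.0))
        assert len(ev) == 1
        assert ev[0].duration == pytest.approx(0.4)

    def test_out_of_band_frequency_rejected(self):
        ev = detect_mp([_atomrec(0.1, 1.0, 80.0, 50.0)], 1.0, (40, 60), (0.5, 2.0))
        assert ev == []

    def test_long_atom_excluded(self):
        ev = detect_mp([_atomrec(0.625, 1.0, 50.0, 50.0)], 1.0, (40, 60), (0.5, 2.0))
        assert ev == []  # duration 2.5 s exceeds the 2-s cap

    def test_subthreshold_rejected(self):
        ev = detect_mp([_atomrec(0.1, 1.0, 50.0, 0.5)], 1.0, (40, 60), (0.5, 2.0))
        assert ev == []

    def test_outside_stim_window_rejected(self):
        ev = detect_mp([_atomrec(0.1, -1.0, 50.0, 5.0)], 1.0, (40, 60), (0.5, 2.0))
        assert ev == []


class TestBurstEvent:
    def test_non_positive_duration_rejected(self):
        with pytest.raises(ValueError):
            BurstEvent(0, "mp", 1.0, 50.0, 0.0, 1.0)
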