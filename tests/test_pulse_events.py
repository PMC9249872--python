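"""Peak/trough detection, pulse-frame stacking and the LWIR track."""

import numpy as np
import pytest
from scipy.signal import butter, sosfiltfilt

from tstms.preprocess import DownsampledCube
from tstms.pulse_events import (
    build_pulse_stack,
    find_peaks_troughs,
    lwir_track,
    min_peak_separation,
    pair_peaks_with_troughs,
)

FS = 30.0
T = 120


def _cube_from_signal(signal, lwir_value=34.0):
    """All four reflectance channels share one pixelwise signal."""
    plane = np.tile(signal[:, None, None], (1, 50, 35))
    lwir = np.full((T, 50, 35), lwir_value)
    return DownsampledCube(np.stack([plane] * 4 + [lwir]), fs=FS)


# 1 Hz tone phased so all four peaks AND four troughs clear the prominence
# threshold: extrema at a window edge have their prominence clipped by the
# missing data beyond the boundary (a pure sine's last trough at frame 112.5
# recovers only 0.396 of the swing by frame 119, just under 0.4)
PHASED_1HZ = np.sin(2 * np.pi * 1.0 * np.arange(T) / FS
                    + (np.pi / 2 - 2 * np.pi * 7 / 30))


class TestFindPeaksTroughs:
    def test_clean_sinusoid_event_count_and_spacing(self):
        """1 Hz over 4 s: 4 peaks and 4 troughs, 30 frames apart."""
        pk, pv, tr, tv = find_peaks_troughs(PHASED_1HZ, FS, hr=1.0,
                                            prominence=0.4)
        assert len(pk) == 4 and len(tr) == 4
        np.testing.assert_array_equal(np.diff(pk), 30)
        np.testing.assert_array_equal(np.diff(tr), 30)

    def test_minimum_separation_formula(self):
        assert min_peak_separation(30.0, 1.2) == 19  # ceil(18.75)

    def test_flat_signal_has_no_events(self):
        pk, _, tr, _ = find_peaks_troughs(np.zeros(T), FS, hr=1.0,
                                          prominence=0.4)
        assert len(pk) == 0 and len(tr) == 0

    def test_nonpositive_heart_rate_rejected(self):
        with pytest.raises(ValueError):
            find_peaks_troughs(np.zeros(T), FS, hr=0.0, prominence=0.4)

    def test_values_reported_on_unnormalized_scale(self):
        x = 100.0 + 20.0 * np.sin(2 * np.pi * np.arange(T) / FS)
        pk, pv, tr, tv = find_peaks_troughs(x, FS, hr=1.0, prominence=0.4)
        assert pv.max() > 119.0 and tv.min() < 81.0

    def test_detected_trains_respect_separation(self):
        rng = np.random.default_rng(2)
        for hr in [0.9, 1.3, 1.8]:
            x = np.sin(2 * np.pi * hr * np.arange(T) / FS) + \
                rng.normal(0, 0.3, T)
            pk, _, tr, _ = find_peaks_troughs(x, FS, hr=hr, prominence=0.4)
            if len(pk) > 1:
                assert np.diff(pk).min() >= min_peak_separation(FS, hr)
            if len(tr) > 1:
                assert np.diff(tr).min() >= min_peak_separation(FS, hr)


class TestPairing:
    def test_alternating_events_pair_in_order(self):
        pairs = pair_peaks_with_troughs([5, 35, 65], [20, 50, 80])
        assert pairs == [(5, 20), (35, 50), (65, 80)]

    def test_trailing_unmatched_peak_dropped(self):
        assert pair_peaks_with_troughs([5, 35], [20]) == [(5, 20)]

    def test_leading_trough_skipped(self):
        assert pair_peaks_with_troughs([10], [5, 25]) == [(10, 25)]


class TestBuildPulseStack:
    def test_four_beats_fill_four_pulse_frames(self):
        # R channel (protocol prominence 0.2): the band-pass filter's edge
        # transient clips the last trough's prominence below the 0.4 used
        # for G/NIR, but a 4-beat pixel yields 4 full pairs at 0.2
        x = 100.0 + 10.0 * PHASED_1HZ
        stack = build_pulse_stack(_cube_from_signal(x), hr=1.0)
        filled = stack.imax["R"][:, 25, 17] > 0
        np.testing.assert_array_equal(filled, [True] * 4 + [False])
        assert np.all(stack.imax["R"][:4, 25, 17] >= stack.imin["R"][:4, 25, 17])

    def test_many_beats_truncated_to_five(self):
        x = 100.0 + 10.0 * np.sin(2 * np.pi * 1.9 * np.arange(T) / FS)
        stack = build_pulse_stack(_cube_from_signal(x), hr=1.9)
        assert np.all(stack.imax["G"][:, 25, 17] > 0)

    def test_constant_pixel_fully_padded(self):
        stack = build_pulse_stack(_cube_from_signal(np.full(T, 100.0)), hr=1.0)
        assert np.all(stack.imax["G"] == 0) and np.all(stack.imin["G"] == 0)

    def test_event_count_bounded_by_duration_times_rate(self):
        for hr in [1.0, 1.5, 1.9]:
            x = 100 + 10 * np.sin(2 * np.pi * hr * np.arange(T) / FS)
            pk, _, _, _ = find_peaks_troughs(x, FS, hr=hr, prominence=0.4)
            assert len(pk) <= int(T / FS * hr) + 1

    def test_pair_count_monotone_in_modulation_amplitude(self):
        counts = []
        for amp in [0.0, 0.5, 2.0, 10.0]:
            x = 100.0 + amp * np.sin(2 * np.pi * np.arange(T) / FS)
            stack = build_pulse_stack(_cube_from_signal(x), hr=1.0)
            counts.append(int((stack.imax["G"][:, 25, 17] > 0).sum()))
        assert counts == sorted(counts)

    def test_simulator_peak_values_match_analytic_imax(
        self, oracle_recording, oracle_profile, noiseless_optics
    ):
        """Detected Imax on the noiseless render ≈ A e^{-a z0} + a_dc term."""
        from tstms.preprocess import build_cube
        from tstms.simulator import face_mask

        cube = build_cube(oracle_recording)
        stack = build_pulse_stack(cube, hr=1.25)
        a = noiseless_optics.alpha["G"]
        amp = oracle_profile.skin_base_intensity["G"]
        analytic_imax = amp * np.exp(-a * noiseless_optics.z0)
        mask = face_mask()
        got = stack.imax["G"][0][mask & (stack.imax["G"][0] > 0)]
        assert np.max(np.abs(got - analytic_imax)) <= 1.0


class TestLwirTrack:
    def test_constant_temperature_preserved(self):
        cube = np.full((T, 50, 35), 34.0)
        f1 = lwir_track(cube, FS)
        assert f1.shape == (5, 50, 35)
        np.testing.assert_allclose(f1, 34.0, atol=1e-9)

    def test_linear_drift_sampled_at_1p5_hz(self):
        t = np.arange(T) / FS
        cube = (34.0 + 0.05 * t)[:, None, None] * np.ones((1, 50, 35))
        f1 = lwir_track(cube, FS)
        expect = 34.0 + 0.05 * (np.arange(5) * 20 / FS)
        np.testing.assert_allclose(f1[:, 10, 10], expect, atol=0.02)

    def test_fast_oscillation_attenuated(self):
        osc = np.sin(2 * np.pi * 1.2 * np.arange(600) / FS)
        sos = butter(6, 0.75, btype="lowpass", fs=FS, output="sos")
        out = sosfiltfilt(sos, osc)
        mid = slice(150, 450)
        atten = -20 * np.log10(
            np.sqrt(np.mean(out[mid] ** 2)) / np.sqrt(np.mean(osc[mid] ** 2))
        )
        assert atten > 20


class TestExtractEvents:
    def test_zero_padding_bookkeeping(self):
        """Event arrays are padded to the trial maximum with exact zeros."""
        from tstms.pulse_events import extract_events

        x = 100.0 + 10.0 * np.sin(2 * np.pi * 1.0 * np.arange(T) / FS)
        cube = _cube_from_signal(x)
        # silence one pixel: it must be fully padded
        data = cube.data.copy()
        data[:4, :, 10, 10] = 100.0
        cube = DownsampledCube(data, fs=FS)
        events = extract_events(cube, hr=1.0)
        g = events["G"]
        assert g.peak_times.shape[2] == g.n_peaks.max()
        assert g.n_peaks[10, 10] == 0
        assert np.all(g.peak_values[10, 10] == 0.0)
        # non-padded times strictly increase
        busy = g.peak_times[25, 17, : g.n_peaks[25, 17]]
        assert np.all(np.diff(busy) > 0)
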