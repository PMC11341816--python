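"""Bandpass, click detection, windowing, matched filtering, spectra and
band selection — plus the end-to-end composition with the forward model."""

import numpy as np
import pytest

from biosonar import preprocess as pp
from biosonar.forward import (EchoDataset, add_noise, build_steering,
                              default_freq_grid, simulate_echoes, synth_click,
                              time_domain_record)
from biosonar.scene import (TransmitterSet, default_sensor_array,
                            default_transmitters, desk_grid)

FS = 500e3


def click_train(n_clicks=150, spacing=0.0075, start=0.004, fs=FS):
    click = synth_click(sample_rate=fs, duration=2e-4)
    times = start + spacing * np.arange(n_clicks)
    ts = np.zeros(int((times[-1] + 0.01) * fs))
    for t in times:
        i = int(round(t * fs))
        ts[i:i + len(click.samples)] += click.samples
    return ts, times, click


class TestBandpass:
    def test_passband_and_stopband(self):
        t = np.arange(int(0.01 * FS)) / FS
        inner = slice(2000, -2000)   # avoid filter edge transients
        tone_pass = np.sin(2 * np.pi * 100e3 * t)
        tone_stop = np.sin(2 * np.pi * 10e3 * t)
        for tone, bound, kind in ((tone_pass, -1.0, "pass"),
                                  (tone_stop, -40.0, "stop")):
            out = pp.bandpass(tone, FS)
            gain = 20 * np.log10(np.linalg.norm(out[inner])
                                 / np.linalg.norm(tone[inner]))
            if kind == "pass":
                assert gain >= bound
            else:
                assert gain <= bound

    def test_zero_in_zero_out(self):
        assert not pp.bandpass(np.zeros(1000), FS).any()

    def test_invalid_band_rejected(self):
        with pytest.raises(ValueError):
            pp.bandpass(np.zeros(100), FS, low_hz=50e3, high_hz=400e3)


class TestDetectClicks:
    def test_planted_train_recovered(self):
        """150 clicks at 7.5 ms spacing, 20 dB SNR: all found within
        0.5 ms of the planted times."""
        ts, times, click = click_train()
        noisy, _ = add_noise(ts, 20.0, seed=0)
        det = pp.detect_clicks(noisy, FS)
        assert det.count == 150
        # planted onset + half a click = envelope peak
        assert np.max(np.abs(det.times - (times + click.duration / 2))) \
            <= 0.5e-3

    def test_silence_gives_none(self):
        det = pp.detect_clicks(np.zeros(1000) + 1e-12, FS,
                               energy_threshold=1.0)
        assert det.count == 0

    def test_minimum_separation_merges_close_bursts(self):
        """Two bursts 2 ms apart yield a single detection."""
        ts, _, _ = click_train(n_clicks=2, spacing=0.002)
        det = pp.detect_clicks(ts, FS)
        assert det.count == 1

    def test_count_nonincreasing_in_threshold(self):
        ts, _, _ = click_train(n_clicks=20)
        noisy, _ = add_noise(ts, 15.0, seed=1)
        counts = [pp.detect_clicks(noisy, FS, energy_threshold=th).count
                  for th in (0.05, 0.2, 0.5, 0.9)]
        assert counts == sorted(counts, reverse=True)


class TestWindowsAndMatchedFilter:
    def test_windows_are_source_slices(self):
        ts, times, _ = click_train(n_clicks=3)
        ts = np.vstack([ts, 2 * ts])
        win, starts = pp.extract_windows(ts, FS, times, 0.004)
        assert win.shape[0] == 3
        for k, t0 in enumerate(starts):
            i0 = int(round(t0 * FS))
            assert np.array_equal(win[k], ts[:, i0:i0 + win.shape[-1]])

    def test_trailing_window_dropped_with_warning(self):
        ts, times, _ = click_train(n_clicks=3)
        with pytest.warns(UserWarning):
            win, _ = pp.extract_windows(np.atleast_2d(ts), FS,
                                        times, 0.004, offset_s=0.0075)
        assert win.shape[0] == 2

    def test_no_clicks_rejected(self):
        with pytest.raises(ValueError):
            pp.extract_windows(np.zeros((1, 100)), FS, np.array([]), 1e-4)

    def test_matched_filter_peak_at_delay(self):
        template = synth_click(sample_rate=FS, duration=2e-4).samples
        delay = 37
        window = np.zeros(1000)
        window[delay:delay + len(template)] = template
        out = pp.matched_filter(window, template)
        assert int(np.argmax(out)) == delay
        assert out[delay] == pytest.approx(np.sum(template ** 2), rel=1e-9)

    def test_matched_filter_linear_in_window(self, rng):
        template = rng.standard_normal(50)
        w1 = rng.standard_normal((3, 400))
        w2 = rng.standard_normal((3, 400))
        lhs = pp.matched_filter(w1 + 2 * w2, template)
        rhs = pp.matched_filter(w1, template) + 2 * pp.matched_filter(
            w2, template)
        assert np.allclose(lhs, rhs)

    def test_noise_only_stays_below_half_energy(self, rng):
        template = synth_click(sample_rate=FS, duration=2e-4).samples
        energy = np.sum(template ** 2)
        # Monte-Carlo at fixed seed: unit-variance noise correlates weakly
        hits = 0
        for _ in range(20):
            window = 0.05 * rng.standard_normal(2000)
            if pp.matched_filter(window, template).max() > energy / 2:
                hits += 1
        assert hits == 0


class TestSpectra:
    def test_tone_concentrates_at_its_bin(self):
        w = 1000
        t = np.arange(w) / FS
        f_bin = 40 * FS / w            # exactly on an FFT bin
        windows = np.sin(2 * np.pi * f_bin * t)[None, None, :]
        ds = pp.to_spectra(windows, FS, np.array([f_bin / 2, f_bin,
                                                  2 * f_bin]))
        mags = np.abs(ds.data[0, :, 0])
        assert mags[1] > 100 * max(mags[0], mags[2])

    def test_parseval_and_round_trip(self, rng):
        w = rng.standard_normal(512)
        spec = pp.window_spectrum(w)
        # Parseval over the full FFT (rfft halves need doubling)
        power = np.abs(spec) ** 2
        power[1:-1] *= 2               # 512 even: bin 0 and Nyquist single
        assert power.sum() / 512 == pytest.approx(np.sum(w ** 2), rel=1e-9)
        back = np.fft.irfft(spec, n=512)
        assert np.allclose(back, w, rtol=0, atol=1e-9 * np.abs(w).max())

    def test_bin_beyond_nyquist_rejected(self):
        with pytest.raises(ValueError):
            pp.to_spectra(np.zeros((1, 1, 100)), FS, np.array([300e3]))


class TestSelectBands:
    def _ds(self, data):
        return EchoDataset(data, default_freq_grid(data.shape[1]), "unknown")

    def test_uniform_high_snr_all_true(self, rng):
        sig = 10 * (rng.standard_normal((4, 5, 3))
                    + 1j * rng.standard_normal((4, 5, 3)))
        sel = pp.select_bands(self._ds(sig), np.ones((4, 5)))
        assert sel.mask.all()

    def test_exact_threshold_excluded(self):
        """Signal exactly at the noise level fails the strict inequality."""
        sig = np.ones((2, 3, 4), complex)
        sel = pp.select_bands(self._ds(sig), np.ones((2, 3)))
        assert not sel.mask.any()

    def test_band_limited_signal_masks_exactly(self, rng):
        data = 1e-3 * (rng.standard_normal((4, 10, 2))
                       + 1j * rng.standard_normal((4, 10, 2)))
        data[:, 3:8, :] += 5.0         # signal only in bins 3..7
        sel = pp.select_bands(self._ds(data), np.ones((4, 10)))
        expected = np.zeros((4, 10), bool)
        expected[:, 3:8] = True
        assert np.array_equal(sel.mask, expected)

    def test_missing_reference_rejected(self, rng):
        data = rng.standard_normal((2, 3, 1)) + 0j
        with pytest.raises(ValueError):
            pp.select_bands(self._ds(data), None)


def test_pipeline_composition_matches_direct_simulation():
    """Time-domain synthesis -> preprocess -> spectra reproduces the
    directly simulated frequency-domain dataset (single scatterer,
    no noise) within 5% per entry."""
    grid = desk_grid()
    arr = default_sensor_array()
    tx0 = default_transmitters()
    tx = TransmitterSet(tx0.positions, tx0.beam_axes, tx0.beamwidth_deg, [0])
    click = synth_click()
    g = np.zeros(grid.n_voxels)
    g[int(grid.xy_to_index(0.03, -0.02))] = 1.0
    t_click = 0.005
    rec = time_domain_record(grid, arr, tx, g, click, [t_click],
                             duration=0.02, sample_rate=FS,
                             directivity=False)
    windows, starts = pp.extract_windows(rec, FS,
                                         np.array([t_click + 0.0005]), 0.002)
    freqs = default_freq_grid(10)
    probe = pp.to_spectra(windows, FS, freqs, window_starts=starts - t_click)
    equalizer = click.spectrum(probe.freqs) * FS / click.sample_rate
    ds = pp.to_spectra(windows, FS, freqs, window_starts=starts - t_click,
                       equalizer=equalizer, mode="known")
    steering = build_steering(grid, arr, ds.freqs, tx)
    direct = simulate_echoes(g, steering, directivity=False)
    rel = np.abs(ds.data - direct.data) / np.abs(direct.data)
    assert rel.max() <= 0.05
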