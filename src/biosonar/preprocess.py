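"""Raw multichannel time series -> per-click frequency-domain data vectors.

The receive chain mirrors standard sonar practice: bandpass to the click
band, detect transmit clicks by their energy bursts (enforcing the minimum
inter-click separation), window each listening period, matched-filter
against the transmit template when it is known, extract complex spectra at
the analysis bins, and keep only the (sensor, frequency) cells whose
average echo SNR across clicks exceeds a threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .forward import EchoDataset, validate_freq_grid

DEFAULT_BANDPASS = (50e3, 170e3)
MIN_CLICK_SEPARATION_S = 0.004


@dataclass
class ClickTimes:
    """Detected click onset times (seconds), strictly increasing."""

    times: np.ndarray
    min_separation_s: float = MIN_CLICK_SEPARATION_S

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, float)
        if self.times.ndim != 1:
            raise ValueError("times must be 1-D")
        if len(self.times) > 1:
            gaps = np.diff(self.times)
            if np.any(gaps <= 0):
                raise ValueError("click times must be strictly increasing")
            if np.any(gaps < self.min_separation_s - 1e-12):
                raise ValueError("click times violate the minimum separation")

    @property
    def count(self) -> int:
        return len(self.times)


@dataclass
class BandSelection:
    """Boolean keep-mask over (sensor, frequency bin)."""

    mask: np.ndarray              # (M, F) bool
    threshold_db: float = 0.0

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be (M, F)")


def bandpass(ts: np.ndarray, sample_rate: float,
             low_hz: float = DEFAULT_BANDPASS[0],
             high_hz: float = DEFAULT_BANDPASS[1],
             order: int = 6) -> np.ndarray:
    """Zero-phase Butterworth bandpass; out-of-band rejection >= 40 dB.

    Operates along the last axis; accepts (T,) or (M, T).
    """
    nyq = sample_rate / 2.0
    if not (0 < low_hz < high_hz < nyq):
        raise ValueError("invalid band for this sample rate")
    sos = sps.butter(order, [low_hz, high_hz], btype="bandpass",
                     fs=sample_rate, output="sos")
    return sps.sosfiltfilt(sos, np.asarray(ts, float), axis=-1)


def detect_clicks(ts: np.ndarray, sample_rate: float,
                  energy_threshold: float | None = None,
                  min_sep_s: float = MIN_CLICK_SEPARATION_S) -> ClickTimes:
    """Greedy energy-burst click detection on a single channel.

    The analytic envelope is thresholded (default: 6x its median, a robust
    floor estimate); candidate bursts within ``min_sep_s`` of a stronger
    accepted burst are suppressed, the stronger one winning.
    """
    ts = np.asarray(ts, float)
    if ts.ndim != 1 or len(ts) == 0:
        raise ValueError("detect_clicks expects a non-empty 1-D channel")
    env = np.abs(sps.hilbert(ts))
    if energy_threshold is None:
        energy_threshold = 6.0 * float(np.median(env))
    distance = max(1, int(round(min_sep_s * sample_rate)))
    peaks, _ = sps.find_peaks(env, height=energy_threshold, distance=distance)
    return ClickTimes(peaks / sample_rate, min_sep_s)


def extract_windows(ts: np.ndarray, sample_rate: float,
                    click_times: ClickTimes | np.ndarray,
                    window_s: float,
                    offset_s: float = 0.0) -> tuple[np.ndarray, np.ndarray]:
    """Cut one listening window per click from every channel.

    Returns ``(windows, starts)`` with windows shaped (K, M, W) and
    ``starts`` the realized window start times (s).  A window that would
    run past the end of the recording is dropped with a warning.
    """
    ts = np.atleast_2d(np.asarray(ts, float))
    times = click_times.times if isinstance(click_times, ClickTimes) \
        else np.asarray(click_times, float)
    if len(times) == 0:
        raise ValueError("no clicks: empty dataset")
    w = int(round(window_s * sample_rate))
    if w < 1 or w > ts.shape[1]:
        raise ValueError("window does not fit inside the recording")
    out, starts = [], []
    for t0 in times:
        i0 = int(round((t0 + offset_s) * sample_rate))
        if i0 < 0 or i0 + w > ts.shape[1]:
            warnings.warn(f"dropping window at t={t0:.4f}s: outside recording")
            continue
        out.append(ts[:, i0:i0 + w])
        starts.append(i0 / sample_rate)
    if not out:
        raise ValueError("all windows fell outside the recording")
    return np.stack(out), np.asarray(starts)


def matched_filter(window: np.ndarray, template: np.ndarray) -> np.ndarray:
    """Cross-correlate a window with the transmit template.

    Output index j is the correlation at lag j (template delayed by j
    samples); a window equal to the delayed template peaks at that delay
    with the template energy.  Works on (..., W) arrays along the last
    axis; output length equals the window length.
    """
    window = np.asarray(window, float)
    template = np.asarray(template, float)
    if template.ndim != 1:
        raise ValueError("template must be 1-D")
    if len(template) > window.shape[-1]:
        raise ValueError("template longer than window")
    out = sps.fftconvolve(window, template[::-1][None, :]
                          if window.ndim > 1 else template[::-1], axes=-1,
                          mode="full")
    return out[..., len(template) - 1:len(template) - 1 + window.shape[-1]]


def window_spectrum(windows: np.ndarray) -> np.ndarray:
    """Full one-sided FFT of windows along the last axis (rfft)."""
    return np.fft.rfft(np.asarray(windows, float), axis=-1)


def to_spectra(windows: np.ndarray, sample_rate: float,
               freqs: np.ndarray,
               window_starts: np.ndarray | None = None,
               equalizer: np.ndarray | None = None,
               mode: str = "unknown") -> EchoDataset:
    """FFT the per-click windows and sample the analysis bins.

    Parameters
    ----------
    windows : (K, M, W) aligned listening windows.
    freqs : requested analysis frequencies; each is snapped to the nearest
        FFT bin of the window (error beyond Nyquist).  The dataset carries
        the realized bin frequencies.
    window_starts : (K,) absolute start time of each window relative to
        the transmit instant; when given, phases are re-referenced to the
        transmit time (known-transmit convention), otherwise phases are
        referenced to the window start.
    equalizer : (F,) complex; spectra are divided by it (e.g. the transmit
        spectrum at the bins, turning the product into the idealized
        matched-filter output with flat response).
    """
    windows = np.asarray(windows, float)
    if windows.ndim != 3:
        raise ValueError("windows must be (K, M, W)")
    freqs = validate_freq_grid(freqs)
    K, M, W = windows.shape
    if np.any(freqs >= sample_rate / 2):
        raise ValueError("requested bin beyond Nyquist")
    fft_freqs = np.fft.rfftfreq(W, 1.0 / sample_rate)
    idx = np.rint(freqs * W / sample_rate).astype(int)
    bin_freqs = fft_freqs[idx]
    spec = window_spectrum(windows)[:, :, idx]       # (K, M, F)
    if window_starts is not None:
        starts = np.asarray(window_starts, float)
        if starts.shape != (K,):
            raise ValueError("one start time per window required")
        spec = spec * np.exp(-2j * np.pi * bin_freqs[None, None, :]
                             * starts[:, None, None])
    if equalizer is not None:
        eq = np.asarray(equalizer, complex)
        if eq.shape != bin_freqs.shape:
            raise ValueError("equalizer must match the frequency grid")
        spec = spec / eq[None, None, :]
    data = np.transpose(spec, (1, 2, 0))             # (M, F, K)
    return EchoDataset(data, bin_freqs, mode,
                       meta={"sample_rate": sample_rate})


def select_bands(spectra: EchoDataset,
                 noise_reference: EchoDataset | np.ndarray,
                 threshold_db: float = 0.0) -> BandSelection:
    """Keep (sensor, frequency) cells whose click-averaged SNR exceeds
    the threshold (strict inequality, default 0 dB).

    ``noise_reference`` is either a noise-only dataset with matching
    (M, F) layout or an (M, F) array of mean noise powers.
    """
    if noise_reference is None:
        raise ValueError("a noise reference is required for band selection")
    sig_power = np.mean(np.abs(spectra.data) ** 2, axis=2)
    if isinstance(noise_reference, EchoDataset):
        noise_power = np.mean(np.abs(noise_reference.data) ** 2, axis=2)
    else:
        noise_power = np.asarray(noise_reference, float)
    if noise_power.shape != sig_power.shape:
        raise ValueError("noise reference shape mismatch")
    if np.any(noise_power <= 0):
        raise ValueError("noise reference must be strictly positive")
    snr_db = 10.0 * np.log10(sig_power / noise_power)
    return BandSelection(snr_db > threshold_db, threshold_db)


def apply_band_selection(dataset: EchoDataset,
                         selection: BandSelection) -> EchoDataset:
    """Return a dataset whose validity mask is intersected with the
    selection; processors later delete the masked rows per frequency."""
    if selection.mask.shape != dataset.data.shape[:2]:
        raise ValueError("selection mask must be (M, F)")
    return EchoDataset(dataset.data, dataset.freqs, dataset.mode,
                       valid=dataset.valid & selection.mask,
                       meta=dict(dataset.meta))
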