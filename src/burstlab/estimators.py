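"""Time-frequency and envelope power estimators used by the competitor detectors.

Four estimators are provided: a continuous Gabor transform (fixed Gaussian
window), a Morlet wavelet transform (constant-Q Gaussian window), a Hilbert
analytic-signal power on band-passed data, and the band-pass/square/Hann-smooth
envelope. A sliding single-taper spectrogram is included for variability
diagnostics, plus dB baseline correction.

All convolutional estimators carry a per-map validity mask marking the
half-support edge regions where the estimate is contaminated by the trial
boundary; detection and variability statistics use the interior only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

__all__ = [
    "TimeFrequencyMap",
    "PowerSeries",
    "EstimatorConfig",
    "bandpass",
    "cgt_spectrogram",
    "wavelet_sigma_t",
    "wavelet_spectrogram",
    "analytic_power",
    "envelope_power",
    "hann_length_s",
    "taper_spectrogram",
    "baseline_correct",
]


@dataclass
class TimeFrequencyMap:
    """Complex or real values on a (time x frequency) grid."""

    values: np.ndarray  # (n_times, n_freqs)
    times: np.ndarray  # seconds, 0 at stimulus onset
    freqs: np.ndarray  # Hz
    estimator: str = ""
    config: dict = field(default_factory=dict)
    valid: np.ndarray | None = None  # bool per time point; None = all valid

    def __post_init__(self) -> None:
        if np.any(np.diff(self.times) <= 0) or np.any(np.diff(self.freqs) <= 0):
            raise ValueError("time and frequency grids must be strictly increasing")
        if self.valid is None:
            self.valid = np.ones(self.times.size, dtype=bool)

    @property
    def power(self) -> np.ndarray:
        if np.iscomplexobj(self.values):
            return np.abs(self.values) ** 2
        return self.values

    def band_rows(self, band: tuple[float, float]) -> np.ndarray:
        return np.flatnonzero((self.freqs >= band[0]) & (self.freqs <= band[1]))


@dataclass
class PowerSeries:
    """Non-negative instantaneous power versus time for one analysis band."""

    values: np.ndarray
    times: np.ndarray
    band: tuple[float, float]
    estimator: str = ""
    valid: np.ndarray | None = None

    def __post_init__(self) -> None:
        if np.any(self.values < 0):
            raise ValueError("power values must be non-negative")
        if self.valid is None:
            self.valid = np.ones(self.times.size, dtype=bool)


@dataclass
class EstimatorConfig:
    """Shared estimator defaults (units: seconds, Hz)."""

    cgt_sigma_s: float = 0.025
    wavelet_q: float = 9.0
    band: tuple[float, float] = (40.0, 60.0)
    butter_order: int = 4
    taper_len_s: float = 0.1

    def __post_init__(self) -> None:
        if min(self.cgt_sigma_s, self.wavelet_q, self.taper_len_s) <= 0 or self.butter_order <= 0:
            raise ValueError("all estimator parameters must be positive")


def bandpass(
    x: np.ndarray, fs: float, band: tuple[float, float], order: int = 4, zero_phase: bool = True
) -> np.ndarray:
    """Butterworth band-pass along the last axis; zero-phase via forward-backward."""
    if not (0 < band[0] < band[1] < fs / 2):
        raise ValueError(f"band {band} outside (0, Nyquist)")
    sos = sps.butter(order, band, btype="bandpass", fs=fs, output="sos")
    if zero_phase:
        return sps.sosfiltfilt(sos, x, axis=-1)
    return sps.sosfilt(sos, x, axis=-1)


def _edge_mask(n: int, half_samples: int) -> np.ndarray:
    valid = np.zeros(n, dtype=bool)
    if half_samples < n - half_samples:
        valid[half_samples : n - half_samples] = True
    return valid


def cgt_spectrogram(
    x: np.ndarray,
    fs: float,
    sigma_s: float = 0.025,
    freqs: np.ndarray | None = None,
    t0_index: int = 0,
) -> TimeFrequencyMap:
    """Continuous Gabor transform: complex Gaussian-windowed filtering.

    The kernel is demodulated so that the phase of a sustained cosine at the
    row frequency advances at 2*pi*f rad/s, which the phase-consistency
    detector depends on. The window is the standard Gaussian
    exp(-t^2 / (2 sigma^2)) truncated at +/- 4 sigma.
    """
    if sigma_s < 2.0 / fs:
        raise ValueError("sigma_s must be at least two sample periods")
    if freqs is None:
        freqs = np.arange(10.0, 101.0, 1.0)
    freqs = np.asarray(freqs, dtype=float)
    x = np.asarray(x, dtype=float)
    half = int(np.ceil(4 * sigma_s * fs))
    tau = np.arange(-half, half + 1) / fs
    win = np.exp(-(tau**2) / (2 * sigma_s**2))
    win /= win.sum()  # unit-gain window: a sustained unit cosine gives |G| ~ 1/2
    kernels = win[None, :] * np.exp(2j * np.pi * freqs[:, None] * tau[None, :])
    xc = np.broadcast_to(x.astype(complex), (freqs.size, x.size))
    vals = sps.fftconvolve(xc, kernels, mode="same", axes=1)
    times = (np.arange(x.size) - t0_index) / fs
    return TimeFrequencyMap(
        values=vals.T,
        times=times,
        freqs=freqs,
        estimator="cgt",
        config={"sigma_s": sigma_s},
        valid=_edge_mask(x.size, half),
    )


def wavelet_sigma_t(q: float, freq_hz: float) -> float:
    """Gaussian envelope standard deviation of a constant-Q Morlet at freq_hz."""
    return q / (2 * np.pi * freq_hz)


def wavelet_spectrogram(
    x: np.ndarray,
    fs: float,
    q: float = 9.0,
    freqs: np.ndarray | None = None,
    t0_index: int = 0,
) -> TimeFrequencyMap:
    """Morlet (Gabor-windowed) wavelet transform with constant Q-factor.

    Per-frequency envelope sigma_t = Q / (2 pi f); each wavelet is unit-energy
    (the 1/sqrt(s) continuous-wavelet normalization).
    """
    if q <= 1:
        raise ValueError("Q must exceed 1")
    if freqs is None:
        freqs = np.arange(10.0, 101.0, 1.0)
    freqs = np.asarray(freqs, dtype=float)
    x = np.asarray(x, dtype=float)
    sig_t = wavelet_sigma_t(q, freqs)
    half = int(np.ceil(4 * sig_t.max() * fs))
    tau = np.arange(-half, half + 1) / fs
    env = np.exp(-(tau[None, :] ** 2) / (2 * sig_t[:, None] ** 2))
    env[np.abs(tau[None, :]) > 4 * sig_t[:, None]] = 0.0
    kernels = env * np.exp(2j * np.pi * freqs[:, None] * tau[None, :])
    kernels /= np.sqrt((np.abs(kernels) ** 2).sum(axis=1))[:, None]
    xc = np.broadcast_to(x.astype(complex), (freqs.size, x.size))
    vals = sps.fftconvolve(xc, kernels, mode="same", axes=1)
    times = (np.arange(x.size) - t0_index) / fs
    # conservative validity: half-support of the widest (lowest-frequency) wavelet
    return TimeFrequencyMap(
        values=vals.T,
        times=times,
        freqs=freqs,
        estimator="wavelet",
        config={"q": q},
        valid=_edge_mask(x.size, half),
    )


def analytic_power(
    x_bandpassed: np.ndarray,
    fs: float,
    band: tuple[float, float],
    t0_index: int = 0,
    edge_s: float = 0.1,
) -> PowerSeries:
    """Squared magnitude of the analytic signal (Hilbert transform).

    Input must already be band-passed. The transform is taken on the full
    trial and an ``edge_s`` margin is marked invalid to absorb edge ringing.
    """
    x = np.asarray(x_bandpassed, dtype=float)
    amp = np.abs(sps.hilbert(x))
    times = (np.arange(x.size) - t0_index) / fs
    return PowerSeries(
        values=amp**2,
        times=times,
        band=tuple(band),
        estimator="hilbert",
        valid=_edge_mask(x.size, int(edge_s * fs)),
    )


def hann_length_s(band: tuple[float, float]) -> float:
    """Smoothing-window rule: twice the period of the lowest band frequency."""
    return 2.0 / band[0]


def envelope_power(
    x: np.ndarray,
    fs: float,
    band: tuple[float, float],
    order: int = 4,
    t0_index: int = 0,
) -> PowerSeries:
    """Band-pass, square, and smooth with a unit-area Hann window.

    The Hann length follows the 2/f_lo rule (50 ms for a 40-60 Hz band).
    """
    xb = bandpass(x, fs, band, order=order)
    n_h = max(int(round(hann_length_s(band) * fs)), 1)
    win = sps.windows.hann(n_h, sym=True)
    win = win / win.sum() if win.sum() > 0 else np.ones(1)
    p = np.apply_along_axis(lambda v: np.convolve(v, win, mode="same"), -1, np.asarray(xb) ** 2)
    x = np.asarray(x)
    times = (np.arange(x.shape[-1]) - t0_index) / fs
    return PowerSeries(
        values=np.clip(p, 0, None),
        times=times,
        band=tuple(band),
        estimator="feingold",
        valid=_edge_mask(x.shape[-1], int(0.1 * fs) + n_h // 2),
    )


def taper_spectrogram(
    x: np.ndarray,
    fs: float,
    taper_len_s: float = 0.1,
    step: int = 1,
    t0_index: int = 0,
) -> TimeFrequencyMap:
    """Sliding single-taper power spectrum (first Slepian taper, NW = 2)."""
    x = np.asarray(x, dtype=float)
    nwin = int(round(taper_len_s * fs))
    if nwin > x.size:
        raise ValueError("taper longer than the signal")
    taper = sps.windows.dpss(nwin, 2)
    taper = taper / np.sqrt(np.sum(taper**2))
    frames = np.lib.stride_tricks.sliding_window_view(x, nwin)[::step]
    spec = np.fft.rfft(frames * taper[None, :], axis=1)
    power = (np.abs(spec) ** 2) / fs
    freqs = np.fft.rfftfreq(nwin, d=1.0 / fs)
    centers = np.arange(frames.shape[0]) * step + nwin // 2
    times = (centers - t0_index) / fs
    keep = freqs > 0  # drop DC so the grid pairs with band selections
    return TimeFrequencyMap(
        values=power[:, keep],
        times=times,
        freqs=freqs[keep],
        estimator="taper",
        config={"taper_len_s": taper_len_s, "step": step},
    )


def baseline_correct(tfmap: TimeFrequencyMap, baseline_window: tuple[float, float]) -> TimeFrequencyMap:
    """Express power in dB relative to the mean baseline power per frequency."""
    mask = (tfmap.times >= baseline_window[0]) & (tfmap.times <= baseline_window[1]) & tfmap.valid
    if not mask.any():
        raise ValueError("baseline window contains no valid time points")
    p = tfmap.power
    b = p[mask].mean(axis=0)
    if np.any(b <= 0):
        raise ValueError("zero baseline power at some frequency")
    vals = 10.0 * (np.log10(np.clip(p, np.finfo(float).tiny, None)) - np.log10(b)[None, :])
    return TimeFrequencyMap(
        values=vals,
        times=tfmap.times,
        freqs=tfmap.freqs,
        estimator=tfmap.estimator + "_db",
        config=dict(tfmap.config, baseline_window=tuple(baseline_window)),
        valid=tfmap.valid.copy(),
    )
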