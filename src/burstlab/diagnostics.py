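"""Spectral-variability diagnostics: why raw power estimates look bursty.

Single-trial spectrogram power at a fixed frequency is approximately
exponentially distributed for stationary Gaussian input, so its coefficient
of variation (CV) across time is ~1 and its amplitude (square root) is
Rayleigh with CV ~ sqrt(4/pi - 1) ~ 0.523. These diagnostics quantify that
estimator-induced variability per frequency and compare empirical power
histograms against the unit-mean exponential law.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy import stats

from .detectors import method_power_maps
from .synthetic import TrialSet

__all__ = [
    "CvProfile",
    "PowerHistogram",
    "power_cv_profile",
    "normalized_power_histogram",
    "trial_psd",
]

RAYLEIGH_CV = float(np.sqrt(4 / np.pi - 1))  # ~0.523


@dataclass
class CvProfile:
    freqs: np.ndarray
    cv_mean: np.ndarray  # across-trial mean of per-trial CV
    cv_se: np.ndarray
    estimator: str
    window: tuple[float, float]
    statistic: str = "power"  # or "amplitude"


@dataclass
class PowerHistogram:
    bin_centers: np.ndarray
    density: np.ndarray
    reference: np.ndarray  # Exp(1) density at the bin centers
    config: dict = field(default_factory=dict)


def power_cv_profile(
    trialset: TrialSet,
    estimator: str = "cgt",
    band: tuple[float, float] | None = None,
    window: tuple[float, float] = (0.5, 1.5),
    statistic: str = "power",
    config=None,
) -> CvProfile:
    """Across-time CV of single-trial power (or amplitude), per frequency.

    CV = sd/mean over the analysis window, computed separately per trial and
    then averaged across trials with its standard error. The window default
    (0.5-1.5 s) excludes onset/offset transients.
    """
    if statistic not in ("power", "amplitude"):
        raise ValueError("statistic must be 'power' or 'amplitude'")
    if window[0] >= window[1]:
        raise ValueError("empty analysis window")
    if estimator in ("feingold", "hilbert"):
        return _cv_profile_banded(trialset, estimator, window, statistic)
    if band is None:
        band = (10.0, 100.0)
    maps, _ = method_power_maps(trialset, estimator, band, config=config)
    m0 = maps[0]
    tmask = (m0.times >= window[0]) & (m0.times <= window[1]) & m0.valid
    if not tmask.any():
        raise ValueError("analysis window contains no valid time points")
    cvs = []
    for m in maps:
        p = m.power[tmask]
        if statistic == "amplitude":
            p = np.sqrt(p)
        mean = p.mean(axis=0)
        cvs.append(p.std(axis=0, ddof=1) / np.where(mean > 0, mean, np.inf))
    cvs = np.asarray(cvs)
    return CvProfile(
        freqs=m0.freqs.copy(),
        cv_mean=cvs.mean(axis=0),
        cv_se=cvs.std(axis=0, ddof=1) / np.sqrt(len(maps)) if len(maps) > 1 else np.zeros(m0.freqs.size),
        estimator=estimator,
        window=tuple(window),
        statistic=statistic,
    )


def _cv_profile_banded(trialset, estimator, window, statistic, centers=None, half_bw=10.0):
    """Per-frequency CV for the 1-D estimators by shifting the band-pass center.

    Mirrors the procedure of stepping the filter center in 10-Hz steps; the
    Hann smoothing length of the envelope estimator then grows at low
    frequencies, which is what suppresses its CV there.
    """
    from .estimators import analytic_power, bandpass, envelope_power

    if centers is None:
        centers = np.arange(20.0, 101.0, 10.0)
    fs, t0 = trialset.fs, trialset.t0_index
    cv_mean, cv_se = [], []
    for f0 in centers:
        band = (f0 - half_bw, f0 + half_bw)
        cvs = []
        for x in trialset.data:
            if estimator == "feingold":
                s = envelope_power(x, fs, band, t0_index=t0)
            else:
                s = analytic_power(bandpass(x, fs, band), fs, band, t0_index=t0)
            mask = (s.times >= window[0]) & (s.times <= window[1]) & s.valid
            p = s.values[mask]
            if statistic == "amplitude":
                p = np.sqrt(p)
            cvs.append(p.std(ddof=1) / p.mean())
        cvs = np.asarray(cvs)
        cv_mean.append(cvs.mean())
        cv_se.append(cvs.std(ddof=1) / np.sqrt(cvs.size) if cvs.size > 1 else 0.0)
    return CvProfile(
        freqs=np.asarray(centers, dtype=float),
        cv_mean=np.asarray(cv_mean),
        cv_se=np.asarray(cv_se),
        estimator=estimator,
        window=tuple(window),
        statistic=statistic,
    )


def normalized_power_histogram(
    power_values: np.ndarray,
    per_trial_normalize: bool = True,
    n_bins: int = 50,
    upper: float = 8.0,
) -> PowerHistogram:
    """Histogram of mean-normalized power against the unit-mean exponential.

    ``power_values`` is (n_trials, n_points) or a flat vector. Each trial (or
    the pool) is normalized to unit mean before binning into ``n_bins`` equal
    bins on [0, upper].
    """
    p = np.atleast_2d(np.asarray(power_values, dtype=float))
    if p.size < 100:
        raise ValueError("need at least 100 power values")
    if np.any(p < 0):
        raise ValueError("power values must be non-negative")
    if per_trial_normalize:
        means = p.mean(axis=1, keepdims=True)
        if np.any(means <= 0):
            raise ValueError("a trial has zero mean power")
        p = p / means
    else:
        p = p / p.mean()
    flat = p.ravel()
    density, edges = np.histogram(flat, bins=n_bins, range=(0.0, upper), density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return PowerHistogram(
        bin_centers=centers,
        density=density,
        reference=np.exp(-centers),
        config={"per_trial_normalize": per_trial_normalize, "n_bins": n_bins, "upper": upper},
    )


def ks_vs_exponential(power_values: np.ndarray, per_trial_normalize: bool = True) -> float:
    """KS distance between mean-normalized power values and Exp(1)."""
    p = np.atleast_2d(np.asarray(power_values, dtype=float))
    if per_trial_normalize:
        p = p / p.mean(axis=1, keepdims=True)
    else:
        p = p / p.mean()
    return float(stats.kstest(p.ravel(), "expon").statistic)


def save_tf_map(tfmap, path, vmin=None, vmax=None) -> None:
    """Render a time-frequency map (typically baseline-corrected dB) to an image file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    mesh = ax.pcolormesh(tfmap.times, tfmap.freqs, tfmap.power.T, vmin=vmin, vmax=vmax, shading="auto")
    ax.set_xlabel("time (s)")
    ax.set_ylabel("frequency (Hz)")
    ax.set_title(tfmap.estimator)
    fig.colorbar(mesh, ax=ax, label="power" + (" (dB)" if tfmap.estimator.endswith("_db") else ""))
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def trial_psd(trialset: TrialSet, window: tuple[float, float]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Trial-averaged periodogram of a window: (freqs, mean power, SE)."""
    sl = trialset.window_slice(window)
    seg = trialset.data[:, sl]
    f, p = sps.periodogram(seg, fs=trialset.fs, window="boxcar", axis=1)
    n = p.shape[0]
    se = p.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.zeros(f.size)
    return f, p.mean(axis=0), se
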