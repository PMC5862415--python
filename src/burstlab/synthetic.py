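"""Synthetic LFP generation: 1/f background noise plus injected Gabor bursts.

The generator emulates a visual-cortex gamma experiment: each trial has a
pre-stimulus (spontaneous) epoch and a stimulus epoch, and gamma bursts are
modelled as Gabor atoms (Gaussian-windowed sinusoids) injected fully inside
the stimulus window. Burst duration is defined throughout as four times the
Gaussian envelope standard deviation (4*sigma). The injected gamma power is
calibrated to a target stimulus/spontaneous band-power ratio.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

__all__ = [
    "TrialSet",
    "GaborParams",
    "InjectionRecord",
    "CalibrationError",
    "generate_background",
    "draw_injections",
    "render_bursts",
    "inject_bursts",
    "band_power",
    "calibrate_gamma_power",
    "simulate_lfp",
]


@dataclass
class TrialSet:
    """Multi-trial single-channel signal matrix with epoch bookkeeping.

    data has shape (n_trials, n_samples); time 0 is the stimulus onset at
    sample index ``t0_index``. Windows are (start_s, end_s) relative to onset.
    """

    data: np.ndarray
    fs: float
    t0_index: int
    baseline_window: tuple[float, float] = (-1.5, 0.0)
    stim_window: tuple[float, float] = (0.5, 2.0)

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        t = self.times
        for w in (self.baseline_window, self.stim_window):
            if w[0] > w[1]:
                raise ValueError(f"window {w} has start > end")
            # allow windows ending at the nominal trial end (one sample past the grid)
            if w[0] < t[0] - 1.01 / self.fs or w[1] > t[-1] + 1.01 / self.fs:
                raise ValueError(f"window {w} outside recorded span [{t[0]}, {t[-1]}]")
        if self.baseline_window[1] > 0 or self.stim_window[0] < 0:
            raise ValueError("baseline must end at or before onset; stimulus must start at or after onset")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def times(self) -> np.ndarray:
        """Time axis in seconds, 0 at stimulus onset."""
        return (np.arange(self.data.shape[1]) - self.t0_index) / self.fs

    def window_slice(self, window: tuple[float, float]) -> slice:
        """Sample slice covering a (start_s, end_s) window relative to onset."""
        i0 = int(np.ceil(window[0] * self.fs)) + self.t0_index
        i1 = int(np.floor(window[1] * self.fs)) + self.t0_index
        i0 = max(i0, 0)
        i1 = min(i1, self.n_samples - 1)
        if i1 < i0:
            raise ValueError(f"window {window} contains no samples")
        return slice(i0, i1 + 1)

    def copy_with(self, data: np.ndarray) -> "TrialSet":
        return replace(self, data=data)


@dataclass
class GaborParams:
    """One Gabor atom: amplitude * exp(-(t-u)^2/(2 sigma^2)) * cos(2 pi xi (t-u) + phase)."""

    scale_s: float
    shift_u: float
    freq_xi: float
    phase: float = 0.0
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        if self.scale_s <= 0:
            raise ValueError("scale_s must be positive")
        if self.freq_xi < 0:
            raise ValueError("freq_xi must be non-negative")

    @property
    def duration_s(self) -> float:
        """Burst duration under the 4-sigma convention."""
        return 4.0 * self.scale_s


@dataclass
class InjectionRecord:
    """Ground-truth injected bursts, one list of GaborParams per trial."""

    bursts: list[list[GaborParams]]
    config: dict = field(default_factory=dict)

    @property
    def n_trials(self) -> int:
        return len(self.bursts)

    def all_bursts(self):
        for trial, atoms in enumerate(self.bursts):
            for atom in atoms:
                yield trial, atom

    def scaled(self, factor: float) -> "InjectionRecord":
        out = [[replace(a, amplitude=a.amplitude * factor) for a in trial] for trial in self.bursts]
        cfg = dict(self.config)
        cfg["amplitude_scale"] = cfg.get("amplitude_scale", 1.0) * factor
        return InjectionRecord(out, cfg)


class CalibrationError(RuntimeError):
    """Raised when gamma-power calibration is impossible (e.g. no bursts)."""


def generate_background(
    n_trials: int,
    duration_s: float,
    fs: float,
    alpha: float = 2.0,
    rng_seed: int | None = None,
    t0_s: float | None = None,
    baseline_window: tuple[float, float] | None = None,
    stim_window: tuple[float, float] | None = None,
) -> TrialSet:
    """Zero-mean Gaussian noise with a 1/f^alpha power spectrum.

    The spectral shaping is flattened below 1 Hz so that low frequencies do
    not dominate the variance. alpha=0 reproduces white noise. The output is
    scaled to unit sample variance (arbitrary microvolt-like units).
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if duration_s <= 0 or fs <= 0:
        raise ValueError("duration_s and fs must be positive")
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    n = int(round(duration_s * fs))
    if t0_s is None:
        t0_s = duration_s / 2.0
    t0_index = int(round(t0_s * fs))

    rng = np.random.default_rng(rng_seed)
    white = rng.standard_normal((n_trials, n))
    spec = np.fft.rfft(white, axis=1)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    shape = np.ones_like(f)
    nz = f >= 1.0  # flatten below 1 Hz at the 1-Hz level
    shape[nz] = f[nz] ** (-alpha / 2.0)
    shape[~nz] = 1.0
    shape[0] = 0.0  # zero mean
    data = np.fft.irfft(spec * shape, n=n, axis=1)
    sd = data.std()
    if sd > 0:
        data /= sd

    t_min = -t0_index / fs
    t_max = (n - t0_index) / fs
    if baseline_window is None:
        baseline_window = (max(-1.5, t_min), 0.0)
    if stim_window is None:
        hi = min(2.0, t_max)
        stim_window = (min(0.5, hi / 2), hi)
    return TrialSet(data=data, fs=fs, t0_index=t0_index, baseline_window=baseline_window, stim_window=stim_window)


def _intervals_overlap(a: GaborParams, b: GaborParams) -> bool:
    lo_a, hi_a = a.shift_u - 2 * a.scale_s, a.shift_u + 2 * a.scale_s
    lo_b, hi_b = b.shift_u - 2 * b.scale_s, b.shift_u + 2 * b.scale_s
    return lo_a < hi_b and lo_b < hi_a


def draw_injections(
    n_trials: int,
    stim_window: tuple[float, float],
    duration_s: float,
    mode: str = "single",
    freq_range: tuple[float, float] = (40.0, 60.0),
    amp_mean: float = 1.0,
    amp_cv: float = 0.1,
    rng_seed: int | None = None,
) -> InjectionRecord:
    """Draw ground-truth burst parameters for every trial.

    mode="single" injects exactly one burst per trial; mode="poisson" draws
    the per-trial count from Poisson(stim_length / duration), then removes
    bursts overlapping an earlier-kept one (containment intervals u +/- 2 sigma).
    Centers are uniform subject to the full 4-sigma extent lying inside the
    stimulus window; frequency is Uniform(freq_range); amplitude is
    Normal(amp_mean, amp_cv*amp_mean) truncated at zero.
    """
    if mode not in ("single", "poisson"):
        raise ValueError(f"unknown mode {mode!r}")
    sigma = duration_s / 4.0
    stim_len = stim_window[1] - stim_window[0]
    if duration_s > stim_len:
        raise ValueError("burst duration exceeds the stimulus window")
    lo_u = stim_window[0] + 2 * sigma
    hi_u = stim_window[1] - 2 * sigma

    rng = np.random.default_rng(rng_seed)
    mean_count = stim_len / duration_s
    bursts: list[list[GaborParams]] = []
    pre_counts = []
    for _ in range(n_trials):
        count = 1 if mode == "single" else int(rng.poisson(mean_count))
        pre_counts.append(count)
        kept: list[GaborParams] = []
        for _ in range(count):
            u = rng.uniform(lo_u, hi_u) if hi_u > lo_u else 0.5 * (lo_u + hi_u)
            xi = rng.uniform(*freq_range)
            amp = rng.normal(amp_mean, amp_cv * amp_mean)
            while amp <= 0:
                amp = rng.normal(amp_mean, amp_cv * amp_mean)
            cand = GaborParams(sigma, u, xi, phase=rng.uniform(0, 2 * np.pi), amplitude=amp)
            # overlap removal in generation order: drop the later burst
            if any(_intervals_overlap(cand, k) for k in kept):
                continue
            kept.append(cand)
        bursts.append(kept)

    config = {
        "mode": mode,
        "duration_s": duration_s,
        "freq_range": tuple(freq_range),
        "amp_mean": amp_mean,
        "amp_cv": amp_cv,
        "rng_seed": rng_seed,
        "stim_window": tuple(stim_window),
        "pre_removal_counts": pre_counts,
        "pre_removal_mean": mean_count if mode == "poisson" else 1.0,
    }
    return InjectionRecord(bursts, config)


def render_bursts(record: InjectionRecord, times: np.ndarray) -> np.ndarray:
    """Render the injected atoms alone on the given time grid (trials x samples)."""
    out = np.zeros((record.n_trials, times.size))
    for trial, atom in record.all_bursts():
        tt = times - atom.shift_u
        out[trial] += (
            atom.amplitude
            * np.exp(-(tt**2) / (2 * atom.scale_s**2))
            * np.cos(2 * np.pi * atom.freq_xi * tt + atom.phase)
        )
    return out


def inject_bursts(background: TrialSet, record: InjectionRecord) -> TrialSet:
    """Add the rendered atoms to the background noise."""
    if record.n_trials != background.n_trials:
        raise ValueError("record and background disagree on trial count")
    t = background.times
    for _, atom in record.all_bursts():
        if atom.shift_u - 2 * atom.scale_s < t[0] or atom.shift_u + 2 * atom.scale_s > t[-1]:
            raise ValueError("burst extends outside the recorded span")
    return background.copy_with(background.data + render_bursts(record, t))


def band_power(trialset: TrialSet, window: tuple[float, float], band: tuple[float, float]) -> float:
    """Mean periodogram band power in a window, averaged over trials.

    Quadratic in the signal (plain rectangular-window periodogram), which the
    calibration solver relies on.
    """
    sl = trialset.window_slice(window)
    seg = trialset.data[:, sl]
    f, p = sps.periodogram(seg, fs=trialset.fs, window="boxcar", axis=1)
    mask = (f >= band[0]) & (f <= band[1])
    if not mask.any():
        raise ValueError("band contains no frequency bins for this window length")
    return float(p[:, mask].mean())


def calibrate_gamma_power(
    background: TrialSet,
    record: InjectionRecord,
    target_ratio: float,
    band: tuple[float, float] = (40.0, 60.0),
    tol: float = 0.05,
) -> tuple[TrialSet, InjectionRecord, float]:
    """Scale burst amplitudes so stimulus/baseline band power hits target_ratio.

    Only the injected atoms are scaled; the background is untouched. The band
    power of background + k*bursts is an exact quadratic in k, so k is solved
    in closed form. Returns (scaled TrialSet, scaled InjectionRecord, k).
    """
    if target_ratio <= 1:
        raise ValueError("target_ratio must exceed 1")
    nyq = background.fs / 2
    if not (0 < band[0] < band[1] < nyq):
        raise ValueError("band must lie within (0, Nyquist)")
    if all(len(b) == 0 for b in record.bursts):
        raise CalibrationError("no injected bursts to scale")

    t = background.times
    burst_only = render_bursts(record, t)
    bg = background
    N = band_power(bg, bg.stim_window, band)
    B = band_power(bg, bg.baseline_window, band)
    if B <= 0:
        raise CalibrationError("baseline band power is zero")
    pure = bg.copy_with(burst_only)
    G = band_power(pure, bg.stim_window, band)
    if G <= 0:
        raise CalibrationError("injected bursts carry no band power")
    mixed = bg.copy_with(bg.data + burst_only)
    C = (band_power(mixed, bg.stim_window, band) - N - G) / 2.0  # cross term at k=1

    # solve G k^2 + 2 C k + (N - R B) = 0 for the positive root
    rhs = target_ratio * B - N
    if rhs <= 0:
        raise CalibrationError("background alone already exceeds the target ratio")
    disc = C * C + G * rhs
    k = (-C + math.sqrt(disc)) / G
    if k <= 0:
        raise CalibrationError("no positive amplitude scale achieves the target ratio")

    scaled = bg.copy_with(bg.data + k * burst_only)
    achieved = band_power(scaled, bg.stim_window, band) / band_power(scaled, bg.baseline_window, band)
    if abs(achieved / target_ratio - 1) > tol:
        raise CalibrationError(f"calibration missed target: achieved {achieved:.3f} vs {target_ratio}")
    return scaled, record.scaled(k), k


def simulate_lfp(
    n_trials: int,
    burst_duration_s: float,
    gamma_ratio: float = 14.0,
    mode: str = "single",
    duration_s: float = 4.0,
    fs: float = 250.0,
    alpha: float = 2.0,
    freq_range: tuple[float, float] = (40.0, 60.0),
    amp_cv: float = 0.1,
    band: tuple[float, float] = (40.0, 60.0),
    rng_seed: int | None = None,
) -> tuple[TrialSet, InjectionRecord, float]:
    """End-to-end synthetic set: background + injections + power calibration.

    Trials span [-duration_s/2, duration_s/2] around stimulus onset with the
    default baseline (-1.5, 0) and stimulus (0.5, 2.0) windows.
    """
    rng = np.random.default_rng(rng_seed)
    seed_bg = int(rng.integers(2**31))
    seed_inj = int(rng.integers(2**31))
    bg = generate_background(n_trials, duration_s, fs, alpha=alpha, rng_seed=seed_bg)
    record = draw_injections(
        n_trials,
        bg.stim_window,
        burst_duration_s,
        mode=mode,
        freq_range=freq_range,
        amp_cv=amp_cv,
        rng_seed=seed_inj,
    )
    return calibrate_gamma_power(bg, record, gamma_ratio, band=band)
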