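"""Burst detection on estimator outputs and MP atom lists, under one threshold scheme.

The unified threshold is a fraction of the stimulus/spontaneous band-power
ratio, expressed in units of the mean baseline band power (fraction 0.5 on a
14-fold power increase gives a threshold of ~7x baseline). Power-based
detectors seed bursts at supra-threshold points and measure the extent around
each seed; the MP detector instead keeps band-limited stimulus-window atoms
whose coefficient exceeds sqrt(fraction) times the mean per-trial maximum
spontaneous coefficient, and reads the duration directly off the atom scale
(duration = 4 sigma).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .estimators import (
    PowerSeries,
    TimeFrequencyMap,
    analytic_power,
    bandpass,
    cgt_spectrogram,
    envelope_power,
    taper_spectrogram,
    wavelet_spectrogram,
)
from .mp import AtomRecord
from .synthetic import TrialSet

__all__ = [
    "BurstEvent",
    "ThresholdSpec",
    "compute_power_threshold",
    "compute_mp_threshold",
    "detect_cgt",
    "detect_power_1d",
    "detect_wavelet",
    "detect_mp",
    "method_power_maps",
    "events_to_frame",
]

logger = logging.getLogger(__name__)

POWER_METHODS = ("cgt", "feingold", "wavelet", "hilbert")
ALL_METHODS = POWER_METHODS + ("mp",)


@dataclass
class BurstEvent:
    trial: int
    method: str
    t_center: float  # s, relative to stimulus onset
    f_center: float  # Hz
    duration: float  # s
    peak_value: float  # power in units of mean baseline band power, or |MP coefficient|

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")


@dataclass
class ThresholdSpec:
    """Unified detection threshold.

    ``power_threshold`` is in units of the mean baseline band power;
    ``ratio`` is the measured stimulus/baseline band-power ratio. With
    mode="ratio" (default) power_threshold = fraction * ratio; the
    alternative reading mode="excess" gives fraction * (ratio - 1).
    """

    fraction: float
    power_threshold: float
    ratio: float = np.nan
    mp_coeff_threshold: float = np.nan
    mode: str = "ratio"

    def __post_init__(self) -> None:
        if not (0 < self.fraction <= 1):
            raise ValueError("fraction must be in (0, 1]")


def method_power_maps(trialset: TrialSet, method: str, band: tuple[float, float], config=None):
    """Per-trial estimator outputs for one method, in baseline-mean units.

    Returns (outputs, ratio) where outputs is a list of TimeFrequencyMap or
    PowerSeries (one per trial) whose values are divided by the pooled mean
    baseline band power, and ratio is the stimulus/baseline band-power ratio
    measured with the same estimator.
    """
    from .estimators import EstimatorConfig

    cfg = config or EstimatorConfig(band=tuple(band))
    fs, t0 = trialset.fs, trialset.t0_index
    outputs = []
    if method in ("cgt", "wavelet", "taper"):
        lo = max(band[0] - 10.0, 1.0)
        freqs = np.arange(lo, band[1] + 10.0 + 0.5, 1.0)
        for x in trialset.data:
            if method == "cgt":
                m = cgt_spectrogram(x, fs, sigma_s=cfg.cgt_sigma_s, freqs=freqs, t0_index=t0)
            elif method == "wavelet":
                m = wavelet_spectrogram(x, fs, q=cfg.wavelet_q, freqs=freqs, t0_index=t0)
            else:
                m = taper_spectrogram(x, fs, taper_len_s=cfg.taper_len_s, t0_index=t0)
            outputs.append(m)
        rows = outputs[0].band_rows(band)
        base = _pooled_band_power(outputs, rows, trialset.baseline_window)
        stim = _pooled_band_power(outputs, rows, trialset.stim_window)
        # complex maps keep their phase: scale by sqrt(base) so power is in baseline units
        norm = [
            TimeFrequencyMap(
                o.values / np.sqrt(base) if np.iscomplexobj(o.values) else o.power / base,
                o.times,
                o.freqs,
                o.estimator,
                dict(o.config),
                o.valid.copy(),
            )
            for o in outputs
        ]
    elif method in ("feingold", "hilbert"):
        for x in trialset.data:
            if method == "feingold":
                s = envelope_power(x, fs, band, order=cfg.butter_order, t0_index=t0)
            else:
                xb = bandpass(x, fs, band, order=cfg.butter_order)
                s = analytic_power(xb, fs, band, t0_index=t0)
            outputs.append(s)
        base = _pooled_series_power(outputs, trialset.baseline_window)
        stim = _pooled_series_power(outputs, trialset.stim_window)
        norm = [PowerSeries(s.values / base, s.times, s.band, s.estimator, s.valid.copy()) for s in outputs]
    else:
        raise ValueError(f"unknown power method {method!r}")
    if base <= 0:
        raise ValueError("zero baseline power")
    return norm, stim / base


def _pooled_band_power(maps, rows, window) -> float:
    vals = []
    for m in maps:
        mask = (m.times >= window[0]) & (m.times <= window[1]) & m.valid
        vals.append(m.power[np.ix_(mask, rows)].mean())
    return float(np.mean(vals))


def _pooled_series_power(series, window) -> float:
    vals = []
    for s in series:
        mask = (s.times >= window[0]) & (s.times <= window[1]) & s.valid
        vals.append(s.values[mask].mean())
    return float(np.mean(vals))


def compute_power_threshold(
    trialset: TrialSet,
    estimator: str,
    band: tuple[float, float],
    fraction: float = 0.5,
    mode: str = "ratio",
    config=None,
) -> ThresholdSpec:
    """Unified threshold: fraction of the stimulus/baseline band-power ratio."""
    _, ratio = method_power_maps(trialset, estimator, band, config=config)
    thr = fraction * ratio if mode == "ratio" else fraction * (ratio - 1.0)
    return ThresholdSpec(fraction=fraction, power_threshold=thr, ratio=ratio, mode=mode)


def compute_mp_threshold(
    decompositions: list[list[AtomRecord]],
    band: tuple[float, float],
    baseline_window: tuple[float, float],
    fraction: float = 0.5,
) -> float:
    """MP coefficient threshold from spontaneous activity.

    Mean over trials of the largest |coefficient| among band-limited atoms
    centered in the baseline window, times sqrt(fraction) (the threshold
    fraction applies to power; coefficients are amplitudes).
    """
    maxima = []
    for i, recs in enumerate(decompositions):
        cands = [
            abs(r.coefficient)
            for r in recs
            if band[0] <= r.atom.freq_xi <= band[1] and baseline_window[0] <= r.atom.shift_u <= baseline_window[1]
        ]
        if not cands:
            warnings.warn(f"trial {i}: no baseline atom in band; contributes 0 to the MP threshold")
            maxima.append(0.0)
        else:
            maxima.append(max(cands))
    return float(np.mean(maxima)) * float(np.sqrt(fraction))


def _labeled_regions(power, rows, times, valid, stim_window, threshold):
    """Connected supra-threshold regions in the band submatrix.

    Yields (region mask rows/cols arrays, seed_time_idx, seed_row_idx) for
    regions having at least one supra-threshold point inside the stimulus
    window; the seed is the power maximum among those points.
    """
    sub = power[:, rows]  # (n_times, n_band)
    supra = (sub > threshold) & valid[:, None]
    labels, n = ndimage.label(supra)
    in_stim = (times >= stim_window[0]) & (times <= stim_window[1])
    for lab in range(1, n + 1):
        ti, fi = np.nonzero(labels == lab)
        ok = in_stim[ti]
        if not ok.any():
            continue
        ti_s, fi_s = ti[ok], fi[ok]
        k = np.argmax(sub[ti_s, fi_s])
        yield int(ti_s[k]), int(fi_s[k])


def detect_cgt(
    tfmap: TimeFrequencyMap,
    threshold: float,
    band: tuple[float, float],
    stim_window: tuple[float, float],
    phase_tol_deg: float = 45.0,
    trial: int = 0,
) -> list[BurstEvent]:
    """Phase-consistency burst detection on a complex CGT map.

    Seeds are supra-threshold power maxima of connected regions in the band x
    stimulus window; from each seed the burst extends in time while the
    unwrapped phase at the seed's frequency row stays within ``phase_tol_deg``
    of the linear trend 2*pi*f*(t - t_seed) + phase_seed ("delinearized"
    phase). One event per connected region.
    """
    if not np.iscomplexobj(tfmap.values):
        raise ValueError("detect_cgt needs a complex map (power and phase)")
    rows = tfmap.band_rows(band)
    if rows.size == 0:
        return []
    power = tfmap.power
    tol = np.deg2rad(phase_tol_deg)
    dt = float(np.median(np.diff(tfmap.times)))
    valid_idx = np.flatnonzero(tfmap.valid)
    if valid_idx.size == 0:
        return []
    lo_lim, hi_lim = valid_idx[0], valid_idx[-1]
    events = []
    for ti, fi in _labeled_regions(power, rows, tfmap.times, tfmap.valid, stim_window, threshold):
        col = rows[fi]
        f_hz = tfmap.freqs[col]
        phases = np.angle(tfmap.values[:, col])
        i_lo = i_hi = ti
        # walk outward, unwrapping incrementally relative to the seed
        for direction in (+1, -1):
            i = ti
            acc = phases[ti]
            while True:
                j = i + direction
                if j < lo_lim or j > hi_lim:
                    break
                step = phases[j] - phases[i]
                step = (step + np.pi) % (2 * np.pi) - np.pi
                acc = acc + step
                lin = phases[ti] + 2 * np.pi * f_hz * (tfmap.times[j] - tfmap.times[ti])
                if abs(acc - lin) > tol:
                    break
                i = j
            if direction > 0:
                i_hi = i
            else:
                i_lo = i
        duration = max((i_hi - i_lo) * dt, dt)
        events.append(
            BurstEvent(
                trial=trial,
                method="cgt",
                t_center=float(tfmap.times[ti]),
                f_center=float(f_hz),
                duration=float(duration),
                peak_value=float(power[ti, col]),
            )
        )
    return events


def detect_wavelet(
    tfmap: TimeFrequencyMap,
    threshold: float,
    band: tuple[float, float],
    stim_window: tuple[float, float],
    edge_fraction: float = 0.5,
    trial: int = 0,
) -> list[BurstEvent]:
    """Power-only burst detection on a (wavelet) time-frequency map.

    One event per connected supra-threshold region; the duration is measured
    along the seed's frequency row, extending until the power drops below
    ``edge_fraction * threshold``.
    """
    rows = tfmap.band_rows(band)
    if rows.size == 0:
        return []
    power = tfmap.power
    dt = float(np.median(np.diff(tfmap.times)))
    edge = edge_fraction * threshold
    valid_idx = np.flatnonzero(tfmap.valid)
    if valid_idx.size == 0:
        return []
    lo_lim, hi_lim = valid_idx[0], valid_idx[-1]
    events = []
    for ti, fi in _labeled_regions(power, rows, tfmap.times, tfmap.valid, stim_window, threshold):
        col = rows[fi]
        row_power = power[:, col]
        i_lo = i_hi = ti
        while i_lo - 1 >= lo_lim and row_power[i_lo - 1] >= edge:
            i_lo -= 1
        while i_hi + 1 <= hi_lim and row_power[i_hi + 1] >= edge:
            i_hi += 1
        duration = max((i_hi - i_lo) * dt, dt)
        events.append(
            BurstEvent(
                trial=trial,
                method=tfmap.estimator or "wavelet",
                t_center=float(tfmap.times[ti]),
                f_center=float(tfmap.freqs[col]),
                duration=float(duration),
                peak_value=float(row_power[ti]),
            )
        )
    return events


def detect_power_1d(
    series: PowerSeries,
    threshold: float,
    edge_fraction: float = 0.5,
    seed_window: tuple[float, float] | None = None,
    method: str | None = None,
    trial: int = 0,
) -> list[BurstEvent]:
    """Threshold-crossing burst detection on a 1-D power series.

    Seeds are points above ``threshold``; each burst spans the surrounding
    interval bounded by the nearest crossings of ``edge_fraction * threshold``.
    Bursts whose edge intervals overlap merge into one event. If
    ``seed_window`` is given, only bursts seeded inside it are kept.
    """
    p = series.values
    above_edge = (p >= edge_fraction * threshold) & series.valid
    labels, n = ndimage.label(above_edge)
    dt = float(series.times[1] - series.times[0]) if series.times.size > 1 else 1.0
    in_win = np.ones(p.size, dtype=bool)
    if seed_window is not None:
        in_win = (series.times >= seed_window[0]) & (series.times <= seed_window[1])
    events = []
    for lab in range(1, n + 1):
        idx = np.flatnonzero(labels == lab)
        seeds = idx[(p[idx] > threshold) & in_win[idx]]
        if seeds.size == 0:
            continue
        k = seeds[np.argmax(p[seeds])]
        duration = max(float(series.times[idx[-1]] - series.times[idx[0]]), dt)
        events.append(
            BurstEvent(
                trial=trial,
                method=method or series.estimator or "power1d",
                t_center=float(series.times[k]),
                f_center=float(0.5 * (series.band[0] + series.band[1])),
                duration=float(duration),
                peak_value=float(p[k]),
            )
        )
    return events


def detect_mp(
    atom_records: list[AtomRecord],
    mp_coeff_threshold: float,
    band: tuple[float, float],
    stim_window: tuple[float, float],
    duration_factor: float = 4.0,
    max_duration_s: float = 2.0,
    trial: int = 0,
) -> list[BurstEvent]:
    """Accept MP atoms as gamma bursts by frequency, position and coefficient.

    duration = duration_factor * scale; atoms longer than ``max_duration_s``
    are excluded (count logged) — such atoms reflect the Gaussian-taper model
    over-reaching across transients, not sustained rhythms.
    """
    events = []
    n_excluded = 0
    for rec in atom_records:
        a = rec.atom
        if not (band[0] <= a.freq_xi <= band[1]):
            continue
        if not (stim_window[0] <= a.shift_u <= stim_window[1]):
            continue
        if abs(rec.coefficient) <= mp_coeff_threshold:
            continue
        duration = duration_factor * a.scale_s
        if duration > max_duration_s:
            n_excluded += 1
            continue
        events.append(
            BurstEvent(
                trial=trial,
                method="mp",
                t_center=float(a.shift_u),
                f_center=float(a.freq_xi),
                duration=float(duration),
                peak_value=float(abs(rec.coefficient)),
            )
        )
    if n_excluded:
        logger.info("detect_mp: excluded %d atoms with duration > %.3g s", n_excluded, max_duration_s)
    return events


def events_to_frame(events: list[BurstEvent]) -> pd.DataFrame:
    """BurstEvent list as the standard CSV-ready table."""
    return pd.DataFrame(
        [
            {
                "trial": e.trial,
                "method": e.method,
                "t_center_s": e.t_center,
                "f_center_hz": e.f_center,
                "duration_ms": e.duration * 1000.0,
                "peak_value": e.peak_value,
            }
            for e in events
        ],
        columns=["trial", "method", "t_center_s", "f_center_hz", "duration_ms", "peak_value"],
    )
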