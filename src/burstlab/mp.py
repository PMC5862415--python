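"""Matching pursuit with a stochastic Gabor dictionary.

The decomposition greedily subtracts, at each iteration, the dictionary atom
with the largest inner product against the current residue. Atoms are real
Gabor functions g(t) = env(t) * cos(2 pi xi (t-u) + phi) with the phase
solved in closed form from the cosine/sine quadrature pair, so a dictionary
entry is just the triple (scale, shift, frequency) sampled uniformly over
its range (a "stochastic" dictionary — no dyadic scale grid, hence no
power-of-two quantization of burst durations).

Implementation notes
--------------------
Atom selection is the hot path: both quadrature waveforms of every atom are
pre-rendered (truncated to +/- 4 sigma support) into one dense float32
matrix, so each iteration is a single BLAS product against the residue(s).
The selected atom is then re-projected in float64 before subtraction, which
keeps the energy ledger (signal energy = sum of squared coefficients +
residue energy) accurate to ~1e-12 relative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .synthetic import GaborParams

__all__ = [
    "Dictionary",
    "AtomRecord",
    "gabor_waveform",
    "build_stochastic_dictionary",
    "best_fit_coefficient",
    "mp_decompose",
    "mp_decompose_batch",
]

_DET_RTOL = 1e-9  # quadrature pair treated as degenerate below this relative determinant


@dataclass
class Dictionary:
    """Stochastic Gabor dictionary: uniform (scale, shift, frequency) triples."""

    scales: np.ndarray  # sigma, seconds
    shifts: np.ndarray  # center time, seconds (trial time coordinate)
    freqs: np.ndarray  # Hz
    scale_range_s: tuple[float, float]
    shift_range_s: tuple[float, float]
    freq_range_hz: tuple[float, float]
    rng_seed: int | None = None
    _matrix: tuple | None = field(default=None, repr=False, compare=False)

    @property
    def size(self) -> int:
        return int(self.scales.size)

    def params(self, i: int) -> tuple[float, float, float]:
        return float(self.scales[i]), float(self.shifts[i]), float(self.freqs[i])

    def design_matrix(self, times: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(2N x T float32 quadrature matrix, N x 3 float64 Gram entries), cached."""
        if self._matrix is not None and self._matrix[0].size == times.size:
            return self._matrix[1], self._matrix[2]
        mat, gram = _build_matrix(self, times)
        object.__setattr__(self, "_matrix", (times, mat, gram))
        return mat, gram


@dataclass
class AtomRecord:
    """One selected atom: fitted parameters, signed coefficient, ledger state."""

    atom: GaborParams
    coefficient: float
    iteration_index: int
    residual_energy_after: float  # fraction of the input energy


def _support(times: np.ndarray, shift_u: float, scale_s: float) -> slice:
    """Sample slice covering +/- 4 sigma around the atom center."""
    dt = times[1] - times[0]
    i0 = int(np.searchsorted(times, shift_u - 4 * scale_s))
    i1 = int(np.searchsorted(times, shift_u + 4 * scale_s, side="right"))
    return slice(max(i0, 0), min(i1, times.size))


def _quadrature_pair(times: np.ndarray, scale_s: float, shift_u: float, freq_xi: float):
    """Raw (unnormalized) cosine/sine quadrature waveforms on the +/-4 sigma support."""
    sl = _support(times, shift_u, scale_s)
    tt = times[sl] - shift_u
    env = np.exp(-(tt**2) / (2 * scale_s**2))
    arg = 2 * np.pi * freq_xi * tt
    return sl, env * np.cos(arg), env * np.sin(arg)


def gabor_waveform(params: GaborParams, n_samples: int, fs: float, t0_index: int = 0) -> np.ndarray:
    """Discrete unit-energy Gabor atom on the trial grid (sum of squares = 1).

    ``params.amplitude`` is ignored; the waveform is normalized. freq_xi = 0
    yields a pure Gaussian. Raises if sigma is unresolvable at fs.
    """
    if params.scale_s < 1.0 / fs:
        raise ValueError("scale_s below one sample period")
    times = (np.arange(n_samples) - t0_index) / fs
    sl, qc, qs = _quadrature_pair(times, params.scale_s, params.shift_u, params.freq_xi)
    w = np.cos(params.phase) * qc - np.sin(params.phase) * qs
    norm = math.sqrt(float(np.dot(w, w)))
    if norm == 0:
        raise ValueError("atom support does not intersect the sample grid")
    out = np.zeros(n_samples)
    out[sl] = w / norm
    return out


def build_stochastic_dictionary(
    size: int,
    n_samples: int,
    fs: float,
    scale_range_s: tuple[float, float] = (0.00625, 1.0),
    freq_range_hz: tuple[float, float] | None = None,
    shift_range_s: tuple[float, float] | None = None,
    rng_seed: int | None = None,
    t0_index: int = 0,
) -> Dictionary:
    """Sample ``size`` atoms with uniform scale, shift and frequency marginals.

    Defaults: scales spanning 4-sigma durations of 25 ms to 4 s, frequencies
    over the full 0-Nyquist range, shifts over the whole trial span (atoms may
    extend beyond any analysis window).
    """
    if size < 1:
        raise ValueError("size must be >= 1")
    if freq_range_hz is None:
        freq_range_hz = (0.0, fs / 2)
    if shift_range_s is None:
        shift_range_s = (-t0_index / fs, (n_samples - 1 - t0_index) / fs)
    for lo, hi in (scale_range_s, freq_range_hz, shift_range_s):
        if not hi > lo:
            raise ValueError("parameter ranges must be non-degenerate")
    rng = np.random.default_rng(rng_seed)
    return Dictionary(
        scales=rng.uniform(*scale_range_s, size),
        shifts=rng.uniform(*shift_range_s, size),
        freqs=rng.uniform(*freq_range_hz, size),
        scale_range_s=tuple(scale_range_s),
        shift_range_s=tuple(shift_range_s),
        freq_range_hz=tuple(freq_range_hz),
        rng_seed=rng_seed,
    )


def _build_matrix(dictionary: Dictionary, times: np.ndarray, chunk: int = 4096):
    n = dictionary.size
    t = times.astype(np.float32)
    mat = np.zeros((2 * n, times.size), dtype=np.float32)
    gram = np.empty((n, 3))
    for i0 in range(0, n, chunk):
        i1 = min(i0 + chunk, n)
        sig = dictionary.scales[i0:i1, None].astype(np.float32)
        tt = t[None, :] - dictionary.shifts[i0:i1, None].astype(np.float32)
        env = np.exp(-(tt**2) / (2 * sig**2))
        env[np.abs(tt) > 4 * sig] = 0.0
        arg = (2 * np.pi) * dictionary.freqs[i0:i1, None].astype(np.float32) * tt
        qc = env * np.cos(arg)
        qs = env * np.sin(arg)
        mat[2 * i0 : 2 * i1 : 2] = qc
        mat[2 * i0 + 1 : 2 * i1 + 1 : 2] = qs
        qc64 = qc.astype(np.float64)
        qs64 = qs.astype(np.float64)
        gram[i0:i1, 0] = np.einsum("ij,ij->i", qc64, qc64)
        gram[i0:i1, 1] = np.einsum("ij,ij->i", qc64, qs64)
        gram[i0:i1, 2] = np.einsum("ij,ij->i", qs64, qs64)
    return mat, gram


def _solve_quadrature(gcc, gcs, gss, pc, ps):
    """Best-phase projection from raw quadrature Grams/projections.

    Returns (coeff^2, alpha, beta) where the optimal unnormalized atom is
    alpha*qc + beta*qs and coeff^2 = p^T G^-1 p. Falls back to the pure
    cosine (Gaussian at xi~0) projection when the pair is degenerate.
    """
    det = gcc * gss - gcs * gcs
    if det <= _DET_RTOL * gcc * max(gss, gcc) or gss <= 0:
        if gcc <= 0:
            return 0.0, 1.0, 0.0
        return pc * pc / gcc, pc / gcc, 0.0
    alpha = (gss * pc - gcs * ps) / det
    beta = (gcc * ps - gcs * pc) / det
    return pc * alpha + ps * beta, alpha, beta


def best_fit_coefficient(
    residue: np.ndarray,
    scale_s: float,
    shift_u: float,
    freq_xi: float,
    fs: float,
    t0_index: int = 0,
) -> tuple[float, float]:
    """Optimal phase and signed coefficient of one Gabor triple against a residue.

    The phase maximizing |<residue, unit atom(phase)>| has a closed form from
    the two quadrature projections; the returned coefficient is the inner
    product with the unit-energy atom at that phase (non-negative, the sign
    being absorbed into the phase).
    """
    times = (np.arange(residue.size) - t0_index) / fs
    sl, qc, qs = _quadrature_pair(times, scale_s, shift_u, freq_xi)
    r = residue[sl]
    gcc = float(np.dot(qc, qc))
    gcs = float(np.dot(qc, qs))
    gss = float(np.dot(qs, qs))
    pc = float(np.dot(r, qc))
    ps = float(np.dot(r, qs))
    c2, alpha, beta = _solve_quadrature(gcc, gcs, gss, pc, ps)
    if c2 <= 0:
        return 0.0, 0.0
    phase = math.atan2(-beta, alpha) % (2 * math.pi)
    return phase, math.sqrt(c2)


def _refine_atom(residue, times, scale_s, shift_u, freq_xi, dictionary: Dictionary):
    """Continuous local optimization of the selected atom's (scale, shift, freq).

    The stochastic dictionary quantizes the parameter space; a short
    Nelder-Mead ascent on the best-phase projection energy around the winning
    atom recovers the continuous optimum, removing the residual "fragment"
    energy that a finite dictionary leaves behind. Scale stays within the
    dictionary's scale range; frequency is clamped non-negative.
    """
    s_lo, s_hi = dictionary.scale_range_s
    f_lo, f_hi = dictionary.freq_range_hz

    def neg_c2(p):
        s = min(max(math.exp(p[0]), s_lo), s_hi)
        u = p[1]
        xi = min(max(p[2], f_lo), f_hi)
        sl, qc, qs = _quadrature_pair(times, s, u, xi)
        if sl.stop - sl.start < 2:
            return 0.0
        r = residue[sl]
        c2, _, _ = _solve_quadrature(
            float(np.dot(qc, qc)),
            float(np.dot(qc, qs)),
            float(np.dot(qs, qs)),
            float(np.dot(r, qc)),
            float(np.dot(r, qs)),
        )
        return -c2

    x0 = np.array([math.log(scale_s), shift_u, freq_xi])
    simplex = np.vstack([x0, x0 + [0.25, 0, 0], x0 + [0, 0.5 * scale_s, 0], x0 + [0, 0, 0.5 / scale_s]])
    res = optimize.minimize(
        neg_c2,
        x0,
        method="Nelder-Mead",
        options={"initial_simplex": simplex, "maxfev": 250, "xatol": 1e-5, "fatol": 1e-12},
    )
    best = res.x if res.fun <= neg_c2(x0) else x0
    return (
        min(max(math.exp(best[0]), s_lo), s_hi),
        float(best[1]),
        min(max(float(best[2]), f_lo), f_hi),
    )


def mp_decompose_batch(
    signals: np.ndarray,
    dictionary: Dictionary,
    fs: float,
    t0_index: int = 0,
    max_iter: int = 100,
    energy_stop_frac: float = 0.05,
    refine: bool = False,
) -> list[list[AtomRecord]]:
    """Greedy MP decomposition of several trials sharing one dictionary.

    Stops per trial at ``max_iter`` iterations or when the residue energy
    falls below ``energy_stop_frac`` of the input energy. With
    ``refine=True`` the winning atom's parameters are locally optimized in
    the continuous parameter space before subtraction. Returns one
    AtomRecord list per row of ``signals``.
    """
    signals = np.atleast_2d(np.asarray(signals, dtype=float))
    if not np.isfinite(signals).all():
        raise ValueError("signals must be finite")
    n_trials, n_samples = signals.shape
    times = (np.arange(n_samples) - t0_index) / fs
    mat, gram = dictionary.design_matrix(times)
    gcc, gcs, gss = gram[:, 0], gram[:, 1], gram[:, 2]
    det = gcc * gss - gcs * gcs
    degen = (det <= _DET_RTOL * gcc * np.maximum(gss, gcc)) | (gss <= 0)
    safe_det = np.where(degen, 1.0, det)
    safe_gcc = np.where(gcc > 0, gcc, 1.0)

    residues = signals.T.copy()  # (T, K) float64
    e0 = np.einsum("tk,tk->k", residues, residues)
    energies = e0.copy()
    records: list[list[AtomRecord]] = [[] for _ in range(n_trials)]
    active = np.flatnonzero(e0 > 0)

    for it in range(max_iter):
        if active.size == 0:
            break
        proj = mat @ residues[:, active].astype(np.float32)  # (2N, k)
        pc = proj[0::2].astype(np.float64)
        ps = proj[1::2].astype(np.float64)
        score_full = (pc * pc * gss[:, None] - 2 * pc * ps * gcs[:, None] + ps * ps * gcc[:, None]) / safe_det[:, None]
        score_degen = pc * pc / safe_gcc[:, None]
        score = np.where(degen[:, None], score_degen, score_full)
        best = np.argmax(score, axis=0)

        still = []
        for col, trial in enumerate(active):
            scale_s, shift_u, freq_xi = dictionary.params(int(best[col]))
            if refine:
                scale_s, shift_u, freq_xi = _refine_atom(
                    residues[:, trial], times, scale_s, shift_u, freq_xi, dictionary
                )
            sl, qc, qs = _quadrature_pair(times, scale_s, shift_u, freq_xi)
            r = residues[sl, trial]
            c2, alpha, beta = _solve_quadrature(
                float(np.dot(qc, qc)),
                float(np.dot(qc, qs)),
                float(np.dot(qs, qs)),
                float(np.dot(r, qc)),
                float(np.dot(r, qs)),
            )
            if c2 <= 0:
                continue  # residue orthogonal to every atom (degenerate); trial done
            g = alpha * qc + beta * qs
            norm = math.sqrt(float(np.dot(g, g)))
            ghat = g / norm
            coeff = float(np.dot(r, ghat))
            residues[sl, trial] -= coeff * ghat
            energies[trial] = float(np.einsum("t,t->", residues[:, trial], residues[:, trial]))
            phase = math.atan2(-beta, alpha) % (2 * math.pi)
            peak_amp = coeff * math.hypot(alpha, beta) / norm
            records[trial].append(
                AtomRecord(
                    atom=GaborParams(scale_s, shift_u, freq_xi, phase=phase, amplitude=peak_amp),
                    coefficient=coeff,
                    iteration_index=it,
                    residual_energy_after=float(energies[trial] / e0[trial]),
                )
            )
            if energies[trial] / e0[trial] >= energy_stop_frac:
                still.append(trial)
        active = np.array(still, dtype=int)
    return records


def mp_decompose(
    signal: np.ndarray,
    dictionary: Dictionary,
    fs: float,
    t0_index: int = 0,
    max_iter: int = 100,
    energy_stop_frac: float = 0.05,
    refine: bool = False,
) -> list[AtomRecord]:
    """Single-trial MP decomposition (thin wrapper over the batched path)."""
    return mp_decompose_batch(
        np.atleast_2d(signal),
        dictionary,
        fs,
        t0_index=t0_index,
        max_iter=max_iter,
        energy_stop_frac=energy_stop_frac,
        refine=refine,
    )[0]
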