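# Methods

## The problem

Cortical gamma oscillations (30–80 Hz, here analyzed in a 40–60 Hz band) are
often reported to occur in very short bursts (~100 ms). A large part of that
burstiness is an artifact of the spectral estimator: single-trial spectrogram
power of even a perfectly stationary Gaussian process is approximately
exponentially distributed across time, so its coefficient of variation (CV)
is ~1 and a few large values always stand out against many small ones.
Any detector that thresholds such a power estimate and measures the
supra-threshold extent will chop a sustained rhythm into short fragments.

`burstlab` implements a duration estimator that avoids this: a matching
pursuit (MP) decomposition over Gabor atoms, where the burst duration is read
off the *scale* of the selected atom rather than off threshold crossings of a
noisy power series. The package also implements the four window-based
estimators this approach is compared against, a synthetic benchmark with
known injected bursts, and the variability diagnostics that motivate the
whole exercise.

## Signal model and conventions

A burst is a Gabor atom

    g(t) = a · exp(−(t − u)² / (2σ²)) · cos(2πξ(t − u) + φ)

with scale σ (s), shift u (s, relative to stimulus onset), center frequency ξ
(Hz), phase φ and peak amplitude a. **Burst duration is defined as 4σ**
throughout — injection ground truth, MP read-out, and benchmark tables all
use this convention. (Whether ±2σ covers "~95%" of the atom's envelope area
or >99% of its energy is a matter of which quantity one integrates; the 4σ
convention is adopted regardless.) The Gaussian envelope uses the standard
exp(−t²/(2σ²)) convention uniformly across the injector, the CGT window, the
Morlet wavelet and the MP dictionary, so every method sees the same object.

Trials are (n_trials × n_samples) matrices at a fixed sampling rate (default
250 Hz, 4-s trials), with stimulus onset at time 0, a baseline epoch
(−1.5, 0) s and a stimulus epoch (0.5, 2.0) s that excludes onset/offset
transients.

## Synthetic LFP generator

The generator emulates injecting known bursts into spontaneous cortical LFP:

- **Background**: zero-mean Gaussian noise with a 1/f^α power spectrum
  (α = 2 by default, flattened below 1 Hz, unit sample variance). Real
  spontaneous LFP is not available to this package; since only the 40–60 Hz
  band is ever calibrated, any realistic broadband floor serves. What the
  background does *not* emulate: occasional genuine spontaneous gamma
  events, non-Gaussian heavy tails, and stimulus-onset broadband transients.
  A green benchmark therefore establishes estimator behavior under
  stationary Gaussian background plus known bursts — not under every
  property of real recordings.
- **Injections**: per trial either exactly one burst or a Poisson count with
  mean (stimulus length)/(burst length); centers uniform subject to the full
  [u − 2σ, u + 2σ] extent lying inside the stimulus window; ξ ~
  Uniform(40, 60) Hz; amplitude ~ Normal(mean, 0.1·mean) truncated at zero
  (a negative amplitude is just a phase flip); φ ~ Uniform(0, 2π).
  Overlapping bursts are removed in generation order (the later one is
  dropped).
- **Calibration**: burst amplitudes (only) are scaled by a constant k so
  that the stimulus/baseline band-power ratio in 40–60 Hz hits a target
  (default 14, matching a strong visual-stimulation condition; 3.5 for the
  weak-rhythm condition). Because the periodogram band power of
  background + k·bursts is an exact quadratic in k, k is solved in closed
  form from three band-power measurements rather than iterated. Outside the
  injection band the spectrum stays at the background level.

## Matching pursuit

MP greedily approximates the signal as a sum of atoms: at each iteration it
selects the atom with the largest inner product against the current residue,
subtracts its projection and repeats. The dictionary is *stochastic*:
(σ, u, ξ) triples sampled uniformly over σ ∈ [6.25 ms, 1 s] (durations 25 ms
to 4 s), u over the whole trial (atoms may extend beyond the stimulus
window), ξ over 0–Nyquist. A dyadic dictionary would quantize durations to
powers of two, which is exactly the quantity of interest — hence uniform
sampling.

For real signals the optimal phase per triple has a closed form: project the
residue on the cosine/sine quadrature pair and solve the 2×2 Gram system
(coefficient² = pᵀG⁻¹p). At ξ ≈ 0 the pair degenerates and the code falls
back to the pure Gaussian projection. Implementation: both quadrature
waveforms of every atom (support truncated at ±4σ; truncation error
< 1e−7 of atom energy) are pre-rendered into one dense float32 matrix, so
each iteration is a single BLAS product; the selected atom is re-projected
in float64 before subtraction, keeping the energy ledger (input energy =
Σ coefficients² + residue energy) accurate to ~1e−12 relative.

**Local refinement.** A 300,000-atom dictionary leaves a quantization
residue: the best atom for an off-grid burst captures ~96–98% of its energy,
and the remainder is refit as spurious "fragment" atoms with coefficients
~15–20% of the burst's. The reference analyses resolved this by brute
density (2.5 million atoms); a dense matrix that size does not fit in this
package's memory budget, so the equivalent is achieved by locally optimizing
the winning atom's (σ, u, ξ) in the continuous parameter space (Nelder–Mead
on the best-phase projection energy, ~100–250 evaluations) before
subtraction. Refinement never decreases the inner product, preserves exact
recovery of dictionary atoms, and is enabled in the benchmark pipeline
(`refine=True`); the raw argmax-over-dictionary behavior remains the default
for `mp_decompose` and is what the dictionary-density tests probe.

**Pre-filter and stopping.** Signals are band-passed 30–70 Hz (4th-order
Butterworth, forward–backward, zero phase) before decomposition so that
iterations are not spent on the 1/f bulk; an unfiltered mode exists. The
decomposition stops at `max_iter` (default 100 for the core API; 20 in the
benchmark) or when the residue falls below `energy_stop_frac` of the input
energy. For *detection* the benchmark additionally truncates each trial's
atom list at the noise floor: the band-passed baseline-epoch energy,
extrapolated to the whole trial, estimates the background energy, and atoms
extracted after the residue reaches it are fits to the noise rather than to
stimulus-induced activity. Without this cut the number of "detected" bursts
grows with the iteration budget — an arbitrary knob — and any threshold
below the baseline maximum coefficient admits an unbounded tail of
noise atoms.

## Competitor estimators and detectors

- **CGT** (continuous Gabor transform): complex Gaussian-windowed filtering,
  window σ = 25 ms (12.5 ms variant available). Detection: supra-threshold
  power regions seed a phase walk — the burst extends while the unwrapped
  phase at the seed's frequency row stays within 45° of the linear trend
  2πf(t − t_seed) + φ_seed. The "delinearization" slope uses the seed row's
  frequency; the frequency grid is 1 Hz, so an off-grid rhythm drifts out of
  tolerance at a rate set by the sub-bin mismatch, which (together with
  estimator phase noise) is what saturates CGT duration estimates.
- **Envelope** (band-pass → square → Hann smooth): the Hann length is twice
  the period of the lowest band frequency (50 ms for 40–60 Hz), which
  suppresses power variability at low center frequencies but not in the
  gamma range. The original 3×/1.5×-median thresholds are available as a
  compatibility mode; the unified scheme below is the default.
- **Hilbert**: squared magnitude of the analytic signal of the band-passed
  trial (computed full-length, edges marked invalid).
- **Wavelet**: Morlet with constant Q = 9 (envelope σ_t = Q/(2πf) ≈ 28.6 ms
  at 50 Hz), unit-energy kernels. Detection is power-only: one event per
  connected supra-threshold region, duration measured along the seed's
  frequency row down to half the threshold.
- **Sliding single-taper** spectrogram (100-ms first Slepian taper stepped
  one sample at a time) is provided for the variability diagnostics.

All convolutional estimators mark half-support edge regions invalid, and all
statistics are computed on the interior.

**Unified threshold.** For the power-based detectors the threshold is
`fraction × (mean stimulus band power / mean baseline band power)`, in units
of mean baseline band power (fraction 0.5 at a 14-fold ratio gives ~7×
baseline; the alternative `fraction × (ratio − 1)` reading is exposed as a
config switch). Burst edges sit at 50% of the threshold. For MP the
threshold applies to amplitudes: `sqrt(fraction) × mean over trials of the
largest in-band baseline-window coefficient`. Seeds are deduplicated by
connected supra-threshold region (the region maximum wins) for both 2-D
detectors; for 1-D series, runs above the edge level containing a seed merge
into one event. MP atoms longer than 2 s are excluded from the duration
statistics (logged), as such atoms reflect the Gaussian-taper model bridging
separate transients.

## Benchmark

`run_duration_benchmark` simulates one condition per injected duration
(default 25 trials), runs every requested detector, pools detected durations
across trials and reports the median with a bootstrap SE (1,000 resamples).
A per-trial median variant is available. `run_threshold_sweep` shares one
simulated set and one MP decomposition across threshold fractions, since the
fraction enters MP only at atom selection. Everything is reproducible from a
single seed; derived seeds stay below 2³¹.

Expected behavior at the desk scale (all computed, see the test suite):
MP medians land within a few percent of 100/500/1000-ms injections at
threshold fraction 0.5 and stay put across fractions; CGT saturates beyond
~200 ms; the envelope/Hilbert/wavelet methods are roughly accurate at
fraction 0.5 but collapse toward very short durations and inflated counts at
fractions ≤ 0.1.

## Numerical choices and edge cases

- Degenerate quadrature pairs (ξ ≈ 0): relative-determinant guard at 1e−9,
  Gaussian-projection fallback.
- All-zero signals decompose to an empty atom list; zero baseline power is
  an error everywhere it would be divided by.
- A trial with no in-band baseline atom contributes 0 to the MP threshold
  (with a warning) rather than being dropped.
- Bootstrap SE uses the plain standard deviation of resampled medians.
- Histogram of normalized power: 50 equal bins on [0, 8] after unit-mean
  normalization, compared against the Exp(1) density.
- Per-trial CVs use the sample standard deviation (ddof = 1). On stationary
  noise the measured power CV comes out ~0.92–0.96 rather than exactly 1:
  the finite 1-s window contains only ~10–30 effective independent power
  samples per frequency, which biases the sample CV slightly downward. The
  same bias affects any implementation of this recipe.

## Known limitations

- The background generator does not model spontaneous gamma events; real
  baselines make the MP threshold more conservative than the Gaussian world
  does.
- MP detection counts depend on the noise-floor cut described above; with an
  unbounded iteration budget and no cut, sub-baseline-max thresholds admit
  arbitrarily many noise atoms (a property of the threshold definition, not
  of this implementation).
- The wavelet detector attributes a multi-row burst to its seed row only; no
  cross-row frequency integration is attempted.
- Runtime: the dense-dictionary design trades ~2.4 GB of memory (300k atoms
  × 1000 samples, float32) for BLAS-speed iterations; dictionaries much
  beyond 700k atoms at this trial length will not fit in an 8 GB budget.
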