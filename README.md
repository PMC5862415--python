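# burstlab

Duration estimation for neural-oscillation bursts in LFP-like signals.

Single-trial spectrogram power is a high-variance estimate: for a perfectly
stationary Gaussian process it is approximately exponentially distributed
across time (CV ≈ 1), so *any* rhythm thresholded in the time–frequency
plane appears to come in short bursts. `burstlab` implements a
matching-pursuit (MP) alternative that reads burst duration off the scale of
a fitted Gabor atom instead of off threshold crossings of a noisy power
series, together with the four window-based detectors it is compared
against, and a calibrated synthetic benchmark that quantifies the
difference. It is intended for electrophysiologists and methods developers
who need burst-duration statistics they can trust.

## The core method

A burst is modeled as a Gabor atom
`g(t) = a·exp(−(t−u)²/(2σ²))·cos(2πξ(t−u)+φ)` with duration defined as 4σ.
MP greedily decomposes the (30–70 Hz band-passed) signal over a *stochastic*
dictionary — (σ, u, ξ) sampled uniformly, so durations are not quantized to
powers of two:

    f = Σₙ ⟨Rⁿf, g_γₙ⟩ g_γₙ + Rᵐf,   g_γₙ = argmax_γ |⟨Rⁿf, g_γ⟩|

Atoms with center frequency in the analysis band (40–60 Hz), center inside
the stimulus window, and coefficient above `√fraction ×` (mean largest
spontaneous coefficient) are accepted as bursts; duration = 4σ of the atom.
The competitor detectors (continuous Gabor transform with a 45° phase-
consistency walk; band-pass/square/Hann envelope; Hilbert analytic power;
constant-Q Morlet wavelet) share a unified threshold: a fraction of the
stimulus/spontaneous band-power ratio. See `docs/methods.md` for the full
model, parameter table and design rationale.

## Worked example

```python
from burstlab import BenchmarkConfig, run_duration_benchmark

cfg = BenchmarkConfig(n_trials=25, dict_size=300_000)
table = run_duration_benchmark(
    durations_ms=[100.0, 500.0, 1000.0],
    methods=("cgt", "feingold", "wavelet", "hilbert", "mp"),
    threshold_fractions=(0.5,),
    seed=1,
    config=cfg,
)
print(table[["method", "injected_duration_ms", "median_estimated_ms",
             "bootstrap_se_ms", "n_bursts_mean"]].to_string(index=False))
```

This simulates 25 four-second trials per condition — 1/f² background plus
one injected Gabor burst per trial, gamma band power calibrated to a 14-fold
stimulus/spontaneous ratio — then detects bursts with every method at
threshold fraction 0.5. Output from the run above (seed 1):

```
  method  injected_duration_ms  median_estimated_ms  bootstrap_se_ms  n_bursts_mean
     cgt                 100.0           180.000000         5.827186           1.32
feingold                 100.0           152.000000         7.633441           1.00
 wavelet                 100.0           166.000000         8.139503           1.20
 hilbert                 100.0           144.000000         7.805758           1.04
      mp                 100.0           104.970549         1.005261           1.00
     cgt                 500.0           472.000000        51.510025           1.44
feingold                 500.0           448.000000        11.739693           1.00
 wavelet                 500.0           496.000000        16.590849           1.08
 hilbert                 500.0           444.000000        10.057021           1.08
      mp                 500.0           500.489716         4.740846           1.08
     cgt                1000.0           512.000000        68.904298           1.32
feingold                1000.0           776.000000        22.867283           1.08
 wavelet                1000.0           856.000000        16.460784           1.12
 hilbert                1000.0           736.000000        36.300555           1.32
      mp                1000.0           994.272707        13.144265           1.08
```

Read: the MP medians track the injected durations within a few percent at
every length, with about one detected burst per trial. The CGT estimate
saturates — a 1,000-ms burst reads as ~510 ms because the phase-consistency
walk terminates long before the burst does — and the envelope/Hilbert
methods undershoot long bursts. Dropping the threshold fraction to 0.1
collapses all the window-based medians to ≲150 ms while MP is unchanged.

The same pipeline is scriptable from the shell:

```
burstlab simulate --n-trials 25 --duration-ms 400 --gamma-ratio 14 --seed 1 --out sim.h5
burstlab decompose --dict-size 300000 --in sim.h5 --out atoms.csv
burstlab detect --method mp --in sim.h5 --atoms atoms.csv --out events.csv
burstlab benchmark --durations-ms 100,500,1000 --out table.csv
```

## Acceptance script

`scripts/acceptance.py` recomputes the package's headline simulation numbers
from scratch — the across-time CV of single-trial CGT power on stationary
Gaussian noise, and the MP median duration for 100/500/1,000-ms injected
bursts at gamma ratio 14 and threshold fraction 0.5 (25 trials, 300,000-atom
dictionary) — and writes them as JSON:

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

Runtime is a few minutes on one CPU; ~3 GB of RAM is needed for the
dictionary matrix.
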