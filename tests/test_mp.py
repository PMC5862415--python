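"""Matching pursuit core: waveforms, dictionary, phase fit, decomposition."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from burstlab.mp import (
    best_fit_coefficient,
    build_stochastic_dictionary,
    gabor_waveform,
    mp_decompose,
    mp_decompose_batch,
)
from burstlab.synthetic import GaborParams

FS = 250.0
N = 1000
T0 = 500


class TestGaborWaveform:
    @given(
        st.floats(0.01, 0.5),
        st.floats(-1.0, 1.0),
        st.floats(0.0, 120.0),
        st.floats(0.0, 2 * np.pi),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_unit_energy(self, scale, shift, freq, phase):
        w = gabor_waveform(GaborParams(scale, shift, freq, phase), N, FS, t0_index=T0)
        assert np.sum(w**2) == pytest.approx(1.0, abs=1e-10)

    def test_zero_frequency_is_gaussian(self):
        w = gabor_waveform(GaborParams(0.1, 0.0, 0.0, 0.0), N, FS, t0_index=T0)
        support = w[np.abs(w) > 0]
        assert np.all(support > 0)  # no zero crossings

    def test_phase_pi_negates(self):
        a = gabor_waveform(GaborParams(0.05, 0.2, 50.0, 0.7), N, FS, t0_index=T0)
        b = gabor_waveform(GaborParams(0.05, 0.2, 50.0, 0.7 + np.pi), N, FS, t0_index=T0)
        np.testing.assert_allclose(a, -b, atol=1e-12)

    def test_subsample_scale_rejected(self):
        with pytest.raises(ValueError):
            gabor_waveform(GaborParams(0.5 / FS, 0.0, 50.0), N, FS, t0_index=T0)


class TestDictionary:
    def test_exact_size_and_determinism(self):
        d1 = build_stochastic_dictionary(5000, N, FS, rng_seed=1, t0_index=T0)
        d2 = build_stochastic_dictionary(5000, N, FS, rng_seed=1, t0_index=T0)
        assert d1.size == 5000
        np.testing.assert_array_equal(d1.scales, d2.scales)
        np.testing.assert_array_equal(d1.freqs, d2.freqs)

    @pytest.mark.parametrize("field", ["scales", "shifts", "freqs"])
    def test_marginals_uniform(self, field):
        d = build_stochastic_dictionary(100_000, N, FS, rng_seed=2, t0_index=T0)
        vals = getattr(d, field)
        counts, _ = np.histogram(vals, bins=20)
        assert stats.chisquare(counts).pvalue > 0.001

    def test_degenerate_range_rejected(self):
        with pytest.raises(ValueError):
            build_stochastic_dictionary(10, N, FS, scale_range_s=(0.1, 0.1))


class TestBestFitCoefficient:
    def test_self_projection(self):
        params = GaborParams(0.08, 0.3, 47.0, phase=1.1)
        residue = 2.5 * gabor_waveform(params, N, FS, t0_index=T0)
        phase, coeff = best_fit_coefficient(residue, 0.08, 0.3, 47.0, FS, t0_index=T0)
        assert coeff == pytest.approx(2.5, abs=1e-8)
        assert (phase - 1.1) % np.pi == pytest.approx(0.0, abs=1e-6) or (phase - 1.1) % np.pi == pytest.approx(
            np.pi, abs=1e-6
        )

    def test_orthogonal_residue_gives_zero(self):
        residue = np.zeros(N)
        _, coeff = best_fit_coefficient(residue, 0.08, 0.3, 47.0, FS, t0_index=T0)
        assert coeff == 0.0

    def test_matches_phase_grid_search(self):
        # brute-force 3600-point phase grid as the independent oracle
        rng = np.random.default_rng(5)
        residue = rng.standard_normal(N)
        for scale, shift, freq in [(0.05, 0.1, 45.0), (0.2, -0.5, 55.0), (0.1, 0.0, 3.0)]:
            phase, coeff = best_fit_coefficient(residue, scale, shift, freq, FS, t0_index=T0)
            grid = np.linspace(0, 2 * np.pi, 3600, endpoint=False)
            best = max(
                abs(float(residue @ gabor_waveform(GaborParams(scale, shift, freq, p), N, FS, t0_index=T0)))
                for p in grid
            )
            assert coeff == pytest.approx(best, rel=1e-4)


class TestDecompose:
    def test_exact_dictionary_atom_recovered(self, tiny_dictionary):
        d = tiny_dictionary
        i = 137
        scale, shift, freq = d.params(i)
        sig = 3.0 * gabor_waveform(GaborParams(scale, shift, freq, 0.9), N, FS, t0_index=T0)
        recs = mp_decompose(sig, d, FS, t0_index=T0, max_iter=3)
        first = recs[0]
        assert first.atom.scale_s == pytest.approx(scale)
        assert first.atom.shift_u == pytest.approx(shift)
        assert first.atom.freq_xi == pytest.approx(freq)
        assert first.coefficient == pytest.approx(3.0, rel=1e-8)
        assert first.residual_energy_after < 1e-10

    def test_energy_ledger_every_iteration(self, tiny_dictionary):
        rng = np.random.default_rng(6)
        sig = rng.standard_normal(N)
        e0 = np.sum(sig**2)
        recs = mp_decompose(sig, tiny_dictionary, FS, t0_index=T0, max_iter=25, energy_stop_frac=0.0)
        acc = 0.0
        for r in recs:
            acc += r.coefficient**2
            assert acc + r.residual_energy_after * e0 == pytest.approx(e0, rel=1e-6)

    def test_residual_energy_non_increasing(self, tiny_dictionary):
        rng = np.random.default_rng(7)
        for sig in rng.standard_normal((3, N)):
            recs = mp_decompose(sig, tiny_dictionary, FS, t0_index=T0, max_iter=15, energy_stop_frac=0.0)
            fracs = [r.residual_energy_after for r in recs]
            assert all(b <= a + 1e-12 for a, b in zip(fracs, fracs[1:]))

    def test_two_separated_atoms_recovered(self, tiny_dictionary):
        d = tiny_dictionary
        # pick two dictionary members, well separated in time, distinct freqs
        i = int(np.argmin(np.abs(d.scales - 0.05) + np.abs(d.shifts + 1.0) + np.abs(d.freqs - 45) / 100))
        j = int(np.argmin(np.abs(d.scales - 0.05) + np.abs(d.shifts - 1.0) + np.abs(d.freqs - 60) / 100))
        si, ui, fi = d.params(i)
        sj, uj, fj = d.params(j)
        assert abs(ui - uj) > 6 * max(si, sj)
        sig = 2.0 * gabor_waveform(GaborParams(si, ui, fi, 0.3), N, FS, t0_index=T0) + 1.5 * gabor_waveform(
            GaborParams(sj, uj, fj, 2.1), N, FS, t0_index=T0
        )
        recs = mp_decompose(sig, d, FS, t0_index=T0, max_iter=2)
        got = {(round(r.atom.scale_s, 9), round(r.atom.shift_u, 9)) for r in recs[:2]}
        assert got == {(round(si, 9), round(ui, 9)), (round(sj, 9), round(uj, 9))}

    def test_selection_is_globally_greedy(self):
        # exhaustive check on a small dictionary: chosen atom maximizes the
        # best-phase projection over every dictionary entry
        d = build_stochastic_dictionary(300, N, FS, rng_seed=8, t0_index=T0)
        rng = np.random.default_rng(9)
        sig = rng.standard_normal(N)
        recs = mp_decompose(sig, d, FS, t0_index=T0, max_iter=1, energy_stop_frac=0.0)
        chosen = abs(recs[0].coefficient)
        best = max(abs(best_fit_coefficient(sig, *d.params(i), FS, t0_index=T0)[1]) for i in range(d.size))
        assert chosen == pytest.approx(best, rel=1e-6)

    def test_zero_signal_empty_decomposition(self, tiny_dictionary):
        recs = mp_decompose(np.zeros(N), tiny_dictionary, FS, t0_index=T0)
        assert recs == []

    def test_batch_matches_single(self, tiny_dictionary):
        rng = np.random.default_rng(10)
        sigs = rng.standard_normal((3, N))
        batch = mp_decompose_batch(sigs, tiny_dictionary, FS, t0_index=T0, max_iter=5, energy_stop_frac=0.0)
        for k in range(3):
            single = mp_decompose(sigs[k], tiny_dictionary, FS, t0_index=T0, max_iter=5, energy_stop_frac=0.0)
            assert len(single) == len(batch[k])
            for a, b in zip(single, batch[k]):
                assert a.coefficient == pytest.approx(b.coefficient, rel=1e-10)

    def test_denser_dictionaries_reduce_recovery_error(self):
        # parameter quantization shrinks with dictionary size (no refinement)
        rng = np.random.default_rng(11)
        targets = [GaborParams(rng.uniform(0.05, 0.2), rng.uniform(-0.5, 0.5), rng.uniform(42, 58), rng.uniform(0, 6))
                   for _ in range(8)]
        n = 500
        errors = []
        for size in (1000, 10_000, 100_000):
            d = build_stochastic_dictionary(size, n, FS, rng_seed=12, t0_index=n // 2)
            errs = []
            for tgt in targets:
                sig = gabor_waveform(tgt, n, FS, t0_index=n // 2)
                rec = mp_decompose(sig, d, FS, t0_index=n // 2, max_iter=1)[0]
                errs.append(abs(rec.atom.scale_s - tgt.scale_s) / tgt.scale_s)
            errors.append(np.median(errs))
        assert errors[0] > errors[1] > errors[2]

    def test_refinement_improves_scale_recovery(self, tiny_dictionary):
        tgt = GaborParams(0.11, 0.37, 52.3, 1.2)
        sig = 4.0 * gabor_waveform(tgt, N, FS, t0_index=T0)
        raw = mp_decompose(sig, tiny_dictionary, FS, t0_index=T0, max_iter=1)[0]
        ref = mp_decompose(sig, tiny_dictionary, FS, t0_index=T0, max_iter=1, refine=True)[0]
        assert abs(ref.atom.scale_s - 0.11) <= abs(raw.atom.scale_s - 0.11)
        assert ref.atom.scale_s == pytest.approx(0.11, rel=0.02)
        assert ref.coefficient >= raw.coefficient - 1e-9
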