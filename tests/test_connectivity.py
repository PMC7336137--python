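import math

import numpy as np
import pytest

from _oracles import dwpli_enumeration
from hemimeg.bands import BandSpec, get_band
from hemimeg.beamformer import VirtualElectrodeSet
from hemimeg.connectivity import (
    ConnectivityMatrix,
    band_adjacency,
    band_average,
    connectivity_matrix,
    phase_lag_indices,
    segment_trials,
    trial_cross_spectra,
)


def _ve(data, fs=100.0, trial_indices=None):
    return VirtualElectrodeSet(np.asarray(data, dtype=float), fs,
                               trial_indices=trial_indices)


def _sinusoid_pair(f0, tau, fs=100.0, n=300, n_trials=4):
    t = np.arange(n) / fs
    x = np.cos(2 * np.pi * f0 * t)
    y = np.cos(2 * np.pi * f0 * (t - tau))
    data = np.stack([np.tile(x, (n_trials, 1)), np.tile(y, (n_trials, 1))])
    return _ve(data, fs=fs)


class TestSegmentTrials:
    def test_nine_consecutive_gives_two(self):
        ve = _ve(np.random.default_rng(0).normal(size=(2, 9, 300)),
                 trial_indices=np.arange(9))
        out = segment_trials(ve, 12.0)
        assert out.n_trials == 2
        assert out.n_samples == 1200

    def test_gap_in_indices(self):
        # trials {1,2,3,5,6,7,8,9}: only {5,6,7,8} forms a 12-s trial
        idx = np.array([1, 2, 3, 5, 6, 7, 8, 9])
        rng = np.random.default_rng(1)
        data = rng.normal(size=(1, 8, 300))
        out = segment_trials(_ve(data, trial_indices=idx), 12.0)
        assert out.n_trials == 1
        expect = np.concatenate([data[0, k] for k in (3, 4, 5, 6)])
        np.testing.assert_array_equal(out.data[0, 0], expect)

    def test_already_target_length_is_identity(self):
        ve = _ve(np.random.default_rng(2).normal(size=(2, 3, 1200)))
        out = segment_trials(ve, 12.0)
        np.testing.assert_array_equal(out.data, ve.data)

    def test_sample_quantized_length_passes(self):
        # 2035 samples at 678.17 Hz is a "3-s" trial only up to one sample
        fs = 678.17
        ve = _ve(np.random.default_rng(3).normal(size=(1, 4, 2035)), fs=fs)
        out = segment_trials(ve, 3.0)
        assert out.n_trials == 4

    def test_too_few_consecutive(self):
        ve = _ve(np.zeros((1, 3, 300)), trial_indices=np.array([0, 2, 4]))
        with pytest.raises(ValueError, match="consecutive"):
            segment_trials(ve, 12.0)

    def test_cannot_shorten(self):
        ve = _ve(np.zeros((1, 2, 1200)))
        with pytest.raises(ValueError, match="shorten"):
            segment_trials(ve, 3.0)


class TestCrossSpectra:
    def test_self_pair_zero_imaginary(self):
        ve = _ve(np.random.default_rng(4).normal(size=(2, 3, 300)))
        cs = trial_cross_spectra(ve, [(0, 0)])
        assert np.max(np.abs(np.imag(cs.values))) < 1e-10

    def test_shifted_sinusoid_phase(self):
        f0, tau = 10.0, 0.01  # bin frequency for 3-s trials at 1/3 Hz spacing
        cs = trial_cross_spectra(_sinusoid_pair(f0, tau), [(0, 1)])
        b = np.argmin(np.abs(cs.freqs - f0))
        phases = np.angle(cs.values[0, :, b])
        np.testing.assert_allclose(phases, 2 * np.pi * f0 * tau, atol=1e-2)

    def test_pair_swap_conjugates(self):
        ve = _ve(np.random.default_rng(5).normal(size=(2, 3, 300)))
        ab = trial_cross_spectra(ve, [(0, 1)]).values
        ba = trial_cross_spectra(ve, [(1, 0)]).values
        np.testing.assert_allclose(ab, np.conj(ba), atol=1e-12)

    def test_pair_out_of_range(self):
        ve = _ve(np.zeros((2, 2, 100)))
        with pytest.raises((IndexError, ValueError)):
            trial_cross_spectra(ve, [(0, 5)])


class TestEstimators:
    def _cs_from_im(self, im):
        """CrossSpectrumSet stand-in with prescribed imaginary parts."""
        ve = _ve(np.random.default_rng(6).normal(size=(2, len(im), 300)))
        cs = trial_cross_spectra(ve, [(0, 1)])
        vals = np.zeros_like(cs.values)
        vals[0, :, :] = 1j * np.asarray(im, dtype=float)[:, None]
        cs.values[...] = vals
        return cs

    def test_constant_quarter_cycle_lag(self):
        cs = self._cs_from_im([2.0, 0.5, 1.0, 3.0])  # all positive Im
        for est in ("pli", "wpli", "dwpli"):
            vals = phase_lag_indices(cs, est)
            np.testing.assert_allclose(vals, 1.0, atol=1e-12)

    def test_zero_imaginary_gives_zero(self):
        cs = self._cs_from_im([0.0, 0.0, 0.0])
        for est in ("pli", "wpli", "dwpli"):
            np.testing.assert_array_equal(phase_lag_indices(cs, est), 0.0)

    def test_four_trial_hand_case(self):
        # Im s over 4 trials = (+1, +1, -1, +1): PLI = |mean sign| = 0.5;
        # dwPLI numerator (sum)^2 - sum of squares = 4 - 4 = 0, so dwPLI = 0
        # (enumeration over the 12 ordered pairs agrees).
        im = [1.0, 1.0, -1.0, 1.0]
        cs = self._cs_from_im(im)
        np.testing.assert_allclose(phase_lag_indices(cs, "pli"), 0.5)
        np.testing.assert_allclose(phase_lag_indices(cs, "wpli"), 0.5)
        expect = dwpli_enumeration(im)
        assert expect == 0.0
        np.testing.assert_allclose(phase_lag_indices(cs, "dwpli"), expect,
                                   atol=1e-12)

    def test_dwpli_matches_enumeration_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            im = rng.normal(size=rng.integers(2, 12))
            cs = self._cs_from_im(im)
            got = phase_lag_indices(cs, "dwpli")[0, 0]
            assert got == pytest.approx(dwpli_enumeration(im), abs=1e-12)

    def test_dwpli_amplitude_invariance(self):
        rng = np.random.default_rng(8)
        data = rng.normal(size=(2, 8, 300))
        ve1 = _ve(data)
        scaled = data.copy()
        scaled[0] *= 13.7
        scaled[1] *= 0.002
        ve2 = _ve(scaled)
        v1 = phase_lag_indices(trial_cross_spectra(ve1, [(0, 1)]), "dwpli")
        v2 = phase_lag_indices(trial_cross_spectra(ve2, [(0, 1)]), "dwpli")
        np.testing.assert_allclose(v1, v2, atol=1e-10)

    def test_zero_lag_mixture_near_zero(self):
        # two channels as instantaneous mixtures of one source: no lagged
        # coupling, dwPLI must vanish despite high coherence
        rng = np.random.default_rng(9)
        s = rng.normal(size=(100, 300))
        n1 = 0.05 * rng.normal(size=(100, 300))
        n2 = 0.05 * rng.normal(size=(100, 300))
        ve = _ve(np.stack([1.0 * s + n1, 0.5 * s + n2]))
        band = get_band("theta")
        m = connectivity_matrix(ve, band).matrix
        assert m[0, 1] < 0.01

    def test_dwpli_needs_two_trials(self):
        ve = _ve(np.random.default_rng(10).normal(size=(2, 1, 300)))
        cs = trial_cross_spectra(ve, [(0, 1)])
        with pytest.raises(ValueError, match="2 trials"):
            phase_lag_indices(cs, "dwpli")

    def test_unknown_estimator(self):
        ve = _ve(np.zeros((2, 2, 100)))
        cs = trial_cross_spectra(ve, [(0, 1)])
        with pytest.raises(ValueError, match="estimator"):
            phase_lag_indices(cs, "coh")


class TestBandAveraging:
    def test_constant_bins_average_to_constant(self):
        band = get_band("theta")
        n_bins = 31
        freqs = np.arange(n_bins) / 3.0
        per_bin = np.full((2, n_bins), 0.37)
        out = band_average(per_bin, freqs, band, 3.0)
        np.testing.assert_allclose(out, 0.37)

    def test_theta_bin_grid(self):
        # theta on 3-s trials uses exactly the 1/3 Hz bins in [4, 7]
        freqs = np.fft.rfftfreq(300, 1.0 / 100.0)
        band = get_band("theta")
        mask = (freqs >= band.f_low - 1e-12) & (freqs <= band.f_high + 1e-12)
        expect = np.arange(12, 22) / 3.0  # 4.0, 4.333..., ..., 7.0
        np.testing.assert_allclose(freqs[mask], expect, atol=1e-12)
        assert mask.sum() == 10

    def test_delta_on_3s_trials_rejected(self):
        freqs = np.fft.rfftfreq(300, 1.0 / 100.0)
        per_bin = np.zeros((1, freqs.size))
        with pytest.raises(ValueError, match="12-s trials|requires"):
            band_average(per_bin, freqs, get_band("delta"), 3.0)

    def test_band_adjacency_contract(self):
        freqs = np.fft.rfftfreq(300, 1.0 / 100.0)
        band = get_band("theta")
        pairs = [(0, 1), (0, 2), (1, 2)]
        per_bin = np.full((3, freqs.size), -0.2)  # negative -> clipped
        cm = band_adjacency(per_bin, freqs, pairs, band, 3, 3.0)
        assert cm.matrix.shape == (3, 3)
        np.testing.assert_array_equal(cm.matrix, 0.0)
        np.testing.assert_array_equal(np.diag(cm.matrix), 0.0)

    def test_connectivity_matrix_matches_pairwise_path(self):
        rng = np.random.default_rng(11)
        ve = _ve(rng.normal(size=(4, 10, 300)))
        band = get_band("alpha")
        m = connectivity_matrix(ve, band).matrix
        cs = trial_cross_spectra(ve, [(i, j) for i in range(4) for j in range(i + 1, 4)])
        per_bin = phase_lag_indices(cs, "dwpli")
        expect = band_adjacency(per_bin, cs.freqs, cs.pairs, band, 4, 3.0).matrix
        np.testing.assert_allclose(m, expect, atol=1e-10)
        assert np.allclose(m, m.T)
        np.testing.assert_array_equal(np.diag(m), 0.0)

    def test_connectivity_matrix_save_load(self, tmp_path):
        rng = np.random.default_rng(12)
        ve = _ve(rng.normal(size=(3, 6, 300)))
        cm = connectivity_matrix(ve, get_band("theta"))
        p = tmp_path / "m.tsv"
        cm.save(p)
        again = ConnectivityMatrix.load(p, get_band("theta"))
        np.testing.assert_allclose(again.matrix, cm.matrix, atol=1e-7)
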