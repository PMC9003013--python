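"""Connectivity estimators: identities, oracles and invariances."""

import numpy as np
import pytest

from eegdynet.connectivity import (ConnectivityMatrix, SpectralParams,
                                   _coherency, connectivity_matrix, icoh, msc,
                                   pearson_abs, pli)
from eegdynet.io import BandSpec, EEGRecording
from eegdynet.synthetic import CohortConfig, generate_record

from oracles import msc_reference

FULL = BandSpec("Full", 0.5, 45.0)
ALPHA1 = BandSpec("Alpha-1", 8.0, 10.0)
FS = 100.0


def _noise(n, seed):
    return np.random.default_rng(seed).standard_normal(n)


class TestIdentities:
    def test_msc_self_is_one(self, rng):
        x = rng.standard_normal(3000)
        assert msc(x, x, FS, FULL) == pytest.approx(1.0, abs=1e-9)

    def test_icoh_self_is_zero(self, rng):
        x = rng.standard_normal(3000)
        assert icoh(x, x, FS, FULL) == pytest.approx(0.0, abs=1e-9)

    def test_icoh_zero_lag_mixing_is_zero(self, rng):
        x = rng.standard_normal(3000)
        assert icoh(x, 2.0 * x, FS, FULL) == pytest.approx(0.0, abs=1e-9)

    def test_pli_self_is_zero(self, rng):
        x = rng.standard_normal(3000)
        assert pli(x, x) == pytest.approx(0.0, abs=1e-12)

    def test_pli_constant_lead_is_one(self, sine_pair):
        x, y, _ = sine_pair
        assert pli(x, y) == pytest.approx(1.0, abs=1e-12)

    def test_pearson_anticorrelated(self, rng):
        x = rng.standard_normal(500)
        assert pearson_abs(x, -3.0 * x) == pytest.approx(1.0, abs=1e-12)

    def test_pearson_location_invariant(self, rng):
        x = rng.standard_normal(500)
        assert pearson_abs(x, x + 7.5) == pytest.approx(1.0, abs=1e-9)


class TestMSC:
    def test_independent_noise_low(self):
        vals = [msc(_noise(10000, 2 * s), _noise(10000, 2 * s + 1), FS, FULL)
                for s in range(5)]
        assert max(vals) < 0.2

    def test_delayed_scaled_copy_high(self, rng):
        # a pure delay has population coherence 1; Welch segments misalign the
        # two signals by the delay, biasing the estimate down by the squared
        # window autocorrelation at that lag, so longer segments are needed to
        # see the limit
        x = rng.standard_normal(10000)
        y = 0.5 * np.roll(x, 3)
        sp = SpectralParams(segment_len=4.0)
        assert msc(x[100:-100], y[100:-100], FS, FULL, sp) > 0.99

    def test_welch_delay_bias_matches_window_autocorrelation(self, rng):
        from scipy.signal import get_window
        x = rng.standard_normal(50000)
        y = np.roll(x, 3)
        est = msc(x[100:-100], y[100:-100], FS, FULL)
        w = get_window("hann", 100)
        rho = np.sum(w[:-3] * w[3:]) / np.sum(w * w)
        assert est == pytest.approx(rho**2, abs=0.005)

    @pytest.mark.parametrize("seed", [11, 22, 33])
    def test_direct_dft_oracle(self, seed):
        r = np.random.default_rng(seed)
        x = r.standard_normal(2000)
        y = 0.4 * x + r.standard_normal(2000)
        ours = msc(x, y, FS, FULL)
        ref = msc_reference(x, y, FS, FULL.low, FULL.high)
        assert ours == pytest.approx(ref, abs=1e-6)

    def test_length_mismatch(self, rng):
        with pytest.raises(ValueError, match="length"):
            msc(rng.standard_normal(500), rng.standard_normal(400), FS, FULL)

    def test_too_short(self, rng):
        with pytest.raises(ValueError, match="short"):
            msc(rng.standard_normal(50), rng.standard_normal(50), FS, FULL)


class TestICOH:
    def test_quadrature_delay_high_in_band(self, rng):
        t = np.arange(0, 100, 1 / FS)
        x = np.sin(2 * np.pi * 10 * t) + 0.05 * rng.standard_normal(len(t))
        shift = int(round(0.025 * FS))  # quarter cycle of 10 Hz
        y = np.roll(x, shift)
        assert icoh(x[50:-50], y[50:-50], FS, ALPHA1) > 0.9

    def test_imag_bounded_by_modulus(self, rng):
        data = rng.standard_normal((4, 4000))
        data[1] += 0.5 * np.roll(data[0], 2)
        _, K = _coherency(data, FS, SpectralParams())
        assert np.all(np.abs(np.imag(K)) <= np.abs(K) + 1e-12)


class TestPLI:
    def test_independent_narrowband_low(self):
        from eegdynet.io import bandpass
        vals = []
        for s in range(6):
            r = np.random.default_rng(100 + s)
            rec = EEGRecording(r.standard_normal((2, 10000)), fs=FS)
            f = bandpass(rec, BandSpec("a", 8.0, 12.0))
            vals.append(pli(f.data[0], f.data[1]))
        assert np.mean(vals) < 0.1

    def test_amplitude_invariance(self, sine_pair, rng):
        x, y, _ = sine_pair
        x = x + 0.1 * rng.standard_normal(len(x))
        assert pli(3.7 * x, 0.2 * y) == pytest.approx(pli(x, y), abs=1e-12)


class TestPearson:
    def test_independent_noise_small(self):
        r = np.random.default_rng(0)
        assert pearson_abs(r.standard_normal(10**4), r.standard_normal(10**4)) < 0.05

    def test_zero_variance_error(self):
        with pytest.raises(ValueError, match="variance"):
            pearson_abs(np.ones(100), np.arange(100.0))

    def test_amplitude_invariance(self, rng):
        x = rng.standard_normal(500)
        y = rng.standard_normal(500)
        assert pearson_abs(2 * x, 5 * y) == pytest.approx(pearson_abs(x, y),
                                                          abs=1e-12)


class TestMatrix:
    def _rec(self, seed=4, duration=10.0):
        cfg = CohortConfig(n_per_group=(2, 2), duration=duration, seed=seed)
        return generate_record(cfg, "PC", seed)

    @pytest.mark.parametrize("method", ["MSC", "ICOH", "PLI", "CORR"])
    def test_symmetric_zero_diag_in_range(self, method):
        mat = connectivity_matrix(self._rec(), method, FULL)
        w = mat.weights
        assert w.shape == (19, 19)
        np.testing.assert_array_equal(w, w.T)
        assert np.all(np.diag(w) == 0)
        assert w.min() >= 0 and w.max() <= 1
        iu = np.triu_indices(19, 1)
        assert len(w[iu]) == 171

    def test_pair_count(self):
        mat = connectivity_matrix(self._rec(), "CORR", FULL)
        assert mat.to_edgelist().shape[0] == 171

    def test_shared_source_corr_near_one(self):
        cfg = CohortConfig(n_per_group=(2, 2), duration=10.0, coupling_pc=1.0,
                           noise_sd=0.0, max_phase_offset=0.0,
                           coupling_subject_sd=0.0, coupling_tv_sd=0.0, seed=9)
        rec = generate_record(cfg, "PC", 9)
        mat = connectivity_matrix(rec, "CORR", FULL)
        iu = np.triu_indices(19, 1)
        assert mat.weights[iu].min() > 0.999

    def test_matrix_matches_pairwise_estimator(self):
        rec = self._rec(duration=5.0)
        mat = connectivity_matrix(rec, "MSC", ALPHA1)
        direct = msc(rec.data[2], rec.data[7], rec.fs, ALPHA1)
        assert mat.weights[2, 7] == pytest.approx(direct, abs=1e-12)

    def test_unknown_method(self):
        with pytest.raises(ValueError, match="PLI"):
            connectivity_matrix(self._rec(duration=2.0), "granger", FULL)

    def test_estimator_range_on_random_pairs(self):
        sp = SpectralParams(segment_len=1.0)
        fs = 32.0
        band = BandSpec("b", 2.0, 14.0)
        r = np.random.default_rng(77)
        for _ in range(250):
            x = r.standard_normal(128)
            y = r.standard_normal(128) + r.uniform(-1, 1) * x
            for v in (msc(x, y, fs, band, sp), icoh(x, y, fs, band, sp),
                      pli(x, y), pearson_abs(x, y)):
                assert 0.0 <= v <= 1.0


class TestContainer:
    def test_rejects_asymmetric(self):
        w = np.zeros((3, 3))
        w[0, 1] = 0.5
        with pytest.raises(ValueError, match="symmetric"):
            ConnectivityMatrix(w, "CORR", FULL, ["a", "b", "c"])

    def test_rejects_out_of_range(self):
        w = np.full((2, 2), 1.5)
        np.fill_diagonal(w, 0)
        with pytest.raises(ValueError):
            ConnectivityMatrix(w, "CORR", FULL, ["a", "b"])
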