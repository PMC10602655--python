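"""Connectivity measures against analytic values and independent
brute-force oracles, plus matrix-level invariants."""

import numpy as np
import pytest
from scipy.signal import hilbert

from eegfc.bands import ALPHA, BROADBAND, LOW_GAMMA
from eegfc.connectivity import (aec, amplitude_envelope, connectivity_matrix,
                                imcoh, instantaneous_phase, pearson_corr, psi,
                                psi_from_phases)
from eegfc.preprocessing import bandpass_array

from conftest import make_epoch

FS = 500.0
T = np.arange(1000) / FS


# ---------------------------------------------------------------------------
# independent oracles (deliberately naive; no shared code with the package)

def oracle_psi(phi_x, phi_y):
    total = 0j
    for a, b in zip(phi_x, phi_y):
        total += np.exp(1j * (a - b))
    return abs(total) / len(phi_x)


def oracle_corr(x, y):
    mx, my = sum(x) / len(x), sum(y) / len(y)
    cov = sum((a - mx) * (b - my) for a, b in zip(x, y)) / len(x)
    sx = (sum((a - mx) ** 2 for a in x) / len(x)) ** 0.5
    sy = (sum((b - my) ** 2 for b in y) / len(y)) ** 0.5
    return cov / (sx * sy)


def oracle_imcoh(x, y, band, fs):
    """Single long-FFT cross-spectrum estimate of band-averaged ImCoh."""
    fx, fy = np.fft.rfft(x), np.fft.rfft(y)
    freqs = np.fft.rfftfreq(len(x), 1 / fs)
    pxy = fx * np.conj(fy)
    pxx, pyy = np.abs(fx) ** 2, np.abs(fy) ** 2
    keep = (freqs > band.low_hz) & (freqs < band.high_hz)
    vals = np.abs(np.imag(pxy[keep])) / np.sqrt(pxx[keep] * pyy[keep])
    return float(vals.mean())


def oracle_aec(x, y, band, fs):
    """Direct |Hilbert| envelopes correlated sample by sample; the outer
    5% is excluded on both sides so filter/Hilbert edge transients do not
    swamp the comparison."""
    ex = np.abs(hilbert(bandpass_array(np.asarray(x, float), band, fs)))
    ey = np.abs(hilbert(bandpass_array(np.asarray(y, float), band, fs)))
    k = len(ex) // 20
    return oracle_corr(ex[k:-k], ey[k:-k])


class TestInstantaneousPhase:
    def test_tone_phase_slope(self):
        phi = np.unwrap(instantaneous_phase(np.cos(2 * np.pi * 10 * T)))
        mid = slice(100, -100)
        slope = np.polyfit(T[mid], phi[mid], 1)[0]
        assert slope == pytest.approx(2 * np.pi * 10, rel=0.01)

    def test_quadrature_offset(self):
        a = instantaneous_phase(np.cos(2 * np.pi * 10 * T))
        b = instantaneous_phase(np.sin(2 * np.pi * 10 * T))
        d = np.angle(np.exp(1j * (a - b)))[100:-100]
        np.testing.assert_allclose(d, np.pi / 2, atol=1e-3)

    def test_zero_signal_rejected(self):
        with pytest.raises(ValueError):
            instantaneous_phase(np.zeros(100))


class TestPsi:
    def test_identical_phases_lock_exactly(self):
        phi = np.random.default_rng(0).uniform(0, 2 * np.pi, 500)
        assert psi_from_phases(phi, phi) == 1.0

    def test_cancelling_phasors(self):
        d = np.repeat([0, np.pi / 2, np.pi, 3 * np.pi / 2], 25)
        assert psi_from_phases(d, np.zeros_like(d)) == pytest.approx(0, abs=1e-12)

    def test_two_point_mixture(self):
        d = np.repeat([0, np.pi / 2], 50)
        assert psi_from_phases(d, np.zeros_like(d)) == pytest.approx(
            np.sqrt(2) / 2, abs=1e-12)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            psi(np.ones(10), np.ones(11))


class TestPearson:
    def test_linear_relations(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(200)
        assert pearson_corr(x, 2 * x) == pytest.approx(1.0)
        assert pearson_corr(x, -x) == pytest.approx(-1.0)

    def test_hand_computed_value(self):
        assert pearson_corr([1, 2, 3, 4], [1, 3, 2, 4]) == pytest.approx(0.8)

    def test_constant_rejected(self):
        with pytest.raises(ValueError):
            pearson_corr(np.ones(10), np.arange(10.0))


class TestImcoh:
    def test_self_coherency_vanishes(self):
        x = np.cos(2 * np.pi * 10 * np.arange(5000) / FS)
        assert imcoh(x, x.copy(), ALPHA, FS) == pytest.approx(0, abs=1e-9)

    def test_quarter_period_delay_detected(self):
        t = np.arange(5000) / FS
        rng = np.random.default_rng(0)
        x = np.cos(2 * np.pi * 10 * t) + 1e-6 * rng.standard_normal(5000)
        y = np.cos(2 * np.pi * 10 * (t - 0.025)) + 1e-6 * rng.standard_normal(5000)
        assert imcoh(x, y, ALPHA, FS) > 0.9

    def test_printed_normalization_variant_differs(self):
        t = np.arange(5000) / FS
        rng = np.random.default_rng(1)
        x = np.cos(2 * np.pi * 10 * t) + 0.1 * rng.standard_normal(5000)
        y = np.sin(2 * np.pi * 10 * t) + 0.1 * rng.standard_normal(5000)
        with_sqrt = imcoh(x, y, ALPHA, FS)
        without = imcoh(x, y, ALPHA, FS, sqrt_normalization=False)
        assert with_sqrt != without

    def test_zero_power_rejected(self):
        with pytest.raises(ValueError):
            imcoh(np.zeros(2000), np.ones(2000), ALPHA, FS)


class TestEnvelope:
    def test_unit_tone_envelope(self):
        env = amplitude_envelope(np.sin(2 * np.pi * 10 * T))
        assert np.abs(env[100:-100] - 1).max() < 0.02

    def test_tracks_amplitude_ramp(self):
        ramp = np.linspace(0.5, 2.0, len(T))
        env = amplitude_envelope(ramp * np.sin(2 * np.pi * 10 * T))
        mid = slice(200, -200)
        assert np.abs(env[mid] / ramp[mid] - 1).max() < 0.05

    def test_zero_signal_zero_envelope(self):
        np.testing.assert_array_equal(amplitude_envelope(np.zeros(100)), 0)


class TestAec:
    def test_self_correlation(self):
        rng = np.random.default_rng(0)
        x = np.sin(2 * np.pi * 10 * T) * (1 + 0.3 * np.sin(2 * np.pi * 0.5 * T)) \
            + 0.01 * rng.standard_normal(len(T))
        assert aec(x, x.copy(), ALPHA, FS) == pytest.approx(1.0, abs=1e-9)

    def test_shared_modulator_across_carriers(self):
        t = np.arange(5000) / FS
        mod = 1 + 0.5 * np.sin(2 * np.pi * 0.5 * t)
        x = mod * np.cos(2 * np.pi * 35 * t)
        y = mod * np.cos(2 * np.pi * 40 * t)
        assert aec(x, y, LOW_GAMMA, FS) > 0.95

    def test_anticorrelated_modulators(self):
        t = np.arange(5000) / FS
        x = (1 + 0.5 * np.sin(2 * np.pi * 0.5 * t)) * np.cos(2 * np.pi * 35 * t)
        y = (1 - 0.5 * np.sin(2 * np.pi * 0.5 * t)) * np.cos(2 * np.pi * 40 * t)
        assert aec(x, y, LOW_GAMMA, FS) < -0.95


class TestOracleEquivalence:
    """Each measure against its naive reference on 3-channel toys."""

    def test_psi_matches_direct_summation(self, toy_epoch):
        f = bandpass_array(toy_epoch.data, ALPHA, FS)
        m = connectivity_matrix(toy_epoch, "psi", ALPHA)
        for i, j in ((0, 1), (0, 2), (1, 2)):
            expect = oracle_psi(np.angle(hilbert(f[i])), np.angle(hilbert(f[j])))
            assert m.values[i, j] == pytest.approx(expect, abs=1e-6)

    def test_corr_matches_direct_covariance(self, toy_epoch):
        f = bandpass_array(toy_epoch.data, ALPHA, FS)
        m = connectivity_matrix(toy_epoch, "corr", ALPHA)
        for i, j in ((0, 1), (0, 2), (1, 2)):
            assert m.values[i, j] == pytest.approx(oracle_corr(f[i], f[j]),
                                                   abs=1e-6)

    def test_imcoh_matches_long_fft_estimate(self):
        # mutually delayed copies of one broadband noise source: high
        # coherence at every in-band bin, where Welch and single-FFT
        # estimators must agree (on incoherent noise both estimators are
        # dominated by their own variance, so agreement is no contract)
        rng = np.random.default_rng(5)
        base = rng.standard_normal(1000)
        mk = lambda lag: np.roll(base, lag) + 1e-3 * rng.standard_normal(1000)
        ep = make_epoch(np.vstack([mk(0), mk(12), mk(6)]))
        m = connectivity_matrix(ep, "imcoh", ALPHA)
        for i, j in ((0, 1), (0, 2), (1, 2)):
            expect = oracle_imcoh(ep.data[i], ep.data[j], ALPHA, FS)
            assert m.values[i, j] == pytest.approx(expect, abs=0.05)

    def test_aec_matches_direct_envelope_correlation(self):
        t = np.arange(5000) / FS   # 10 s: several modulation cycles
        mod = 1 + 0.5 * np.sin(2 * np.pi * 0.7 * t)
        ep = make_epoch(np.vstack([
            mod * np.cos(2 * np.pi * 10 * t),
            mod * np.cos(2 * np.pi * 10.5 * t),
            (2 - mod) * np.cos(2 * np.pi * 9.5 * t),
        ]))
        m = connectivity_matrix(ep, "aec", ALPHA)
        for i, j in ((0, 1), (0, 2), (1, 2)):
            expect = oracle_aec(ep.data[i], ep.data[j], ALPHA, FS)
            assert m.values[i, j] == pytest.approx(expect, abs=0.05)


class TestMatrixInvariants:
    def test_shape_symmetry_diagonal(self, toy_epoch):
        for method, diag in (("psi", 1), ("imcoh", 0), ("corr", 1), ("aec", 1)):
            m = connectivity_matrix(toy_epoch, method, ALPHA)
            assert m.values.shape == (3, 3)
            np.testing.assert_allclose(m.values, m.values.T, atol=1e-9)
            np.testing.assert_allclose(np.diag(m.values), diag)

    def test_two_channel_anticorrelation(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(1000)
        ep = make_epoch(np.vstack([x, -x]))
        m = connectivity_matrix(ep, "corr", BROADBAND)
        assert m.values[0, 1] == pytest.approx(-1.0, abs=1e-6)

    def test_permutation_equivariance(self, toy_epoch):
        perm = [2, 0, 1]
        permuted = make_epoch(toy_epoch.data[perm])
        for method in ("psi", "imcoh", "corr", "aec"):
            m = connectivity_matrix(toy_epoch, method, ALPHA).values
            mp = connectivity_matrix(permuted, method, ALPHA).values
            np.testing.assert_allclose(mp, m[np.ix_(perm, perm)], atol=1e-9)

    def test_scale_invariance(self, toy_epoch):
        scaled = make_epoch(toy_epoch.data * np.array([[3.0], [0.1], [7.5]]))
        for method in ("psi", "imcoh", "corr", "aec"):
            a = connectivity_matrix(toy_epoch, method, ALPHA).values
            b = connectivity_matrix(scaled, method, ALPHA).values
            np.testing.assert_allclose(a, b, atol=1e-9)

    def test_planted_pair_is_strongest(self):
        from eegfc.synth import single_pair_templates, simulate_recording
        tpl = single_pair_templates(5, (1, 3), kappa=1.0, rho=0.9,
                                    noise_sd=0.02)
        rec = simulate_recording(tpl, 10, 500, seed=2)
        ep = make_epoch(rec.data.astype(float))
        m = connectivity_matrix(ep, "psi", ALPHA).values
        off = m[np.triu_indices(5, 1)]
        assert m[1, 3] == off.max()

    def test_bounds_over_random_pairs(self):
        rng = np.random.default_rng(7)
        t = np.arange(1000) / FS
        for _ in range(250):
            kind = rng.integers(0, 3)
            if kind == 0:
                x = rng.standard_normal(1000)
                y = rng.standard_normal(1000)
            elif kind == 1:
                f1, f2 = rng.uniform(9, 11, 2)
                x = np.sin(2 * np.pi * f1 * t + rng.uniform(0, 6))
                y = np.sin(2 * np.pi * f2 * t + rng.uniform(0, 6))
                x += 0.1 * rng.standard_normal(1000)
                y += 0.1 * rng.standard_normal(1000)
            else:
                x = (1 + 0.5 * np.sin(2 * np.pi * 0.7 * t)) * rng.standard_normal(1000)
                y = (1 + 0.5 * np.cos(2 * np.pi * 0.7 * t)) * rng.standard_normal(1000)
            assert 0 <= psi(x, y) <= 1
            assert 0 <= imcoh(x, y, ALPHA, FS) <= 1
            assert -1 <= pearson_corr(x, y) <= 1
            assert -1 <= aec(x, y, ALPHA, FS) <= 1
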