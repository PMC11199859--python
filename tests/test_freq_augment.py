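"""Spectral transforms and frequency bank: exactness, symmetry, counts."""

import numpy as np
import pytest

from tffusion.freq_augment import (FreqAugConfig, SpectrumBatch, add_frequency,
                                   apply_freq_bank, forward_transform,
                                   inverse_transform, lowpass, phase_shift,
                                   remove_frequency)


def imag_residual(F: SpectrumBatch) -> float:
    """Rebuild the full two-sided spectrum and measure the imaginary part
    of its inverse DFT, relative to the signal norm (conjugate-symmetry
    oracle, independent of irfft)."""
    T = F.origin_length
    coeffs = F.coeffs
    if T % 2 == 0:
        body = coeffs[..., 1:-1]
    else:
        body = coeffs[..., 1:]
    full = np.concatenate([coeffs, np.conj(body[..., ::-1])], axis=-1)
    sig = np.fft.ifft(full, axis=-1)
    return float(np.abs(sig.imag).max() / (np.abs(sig).max() + 1e-300))


@pytest.fixture
def X(rng):
    return rng.normal(size=(4, 2, 33))  # odd T on purpose


@pytest.fixture
def Xe(rng):
    return rng.normal(size=(4, 2, 32))  # even T


class TestTransforms:
    def test_constant_signal_is_dc_only(self):
        T = 20
        F = forward_transform(np.full((1, 1, T), 2.5))
        assert np.isclose(F.coeffs[0, 0, 0].real, 2.5 * T)
        assert np.allclose(F.coeffs[0, 0, 1:], 0.0, atol=1e-10)

    def test_cosine_hits_single_bin_with_magnitude_T_over_2(self):
        T, m = 64, 5
        t = np.arange(T)
        F = forward_transform(np.cos(2 * np.pi * m * t / T)[None, None])
        mags = np.abs(F.coeffs[0, 0])
        assert np.isclose(mags[m], T / 2)
        assert np.allclose(np.delete(mags, m), 0.0, atol=1e-9)

    @pytest.mark.parametrize("fixture", ["X", "Xe"])
    def test_round_trip_identity(self, fixture, request):
        x = request.getfixturevalue(fixture)
        back = inverse_transform(forward_transform(x))
        assert np.max(np.abs(back - x)) / np.max(np.abs(x)) < 1e-9

    def test_parseval_energy_equality(self, Xe):
        F = forward_transform(Xe)
        T = Xe.shape[-1]
        # one-sided sum: double the interior bins
        w = np.full(F.n_bins, 2.0)
        w[0] = 1.0
        w[-1] = 1.0
        lhs = (np.abs(F.coeffs) ** 2 * w).sum() / T
        assert np.isclose(lhs, (Xe ** 2).sum(), rtol=1e-9)

    def test_dc_only_spectrum_inverts_to_constant(self):
        K = 17
        coeffs = np.zeros((1, 1, K), complex)
        coeffs[0, 0, 0] = 3.0 * 32
        sig = inverse_transform(SpectrumBatch(coeffs, 32))
        assert np.allclose(sig, 3.0)

    def test_inconsistent_bins_rejected(self):
        with pytest.raises(ValueError):
            SpectrumBatch(np.zeros((1, 1, 10), complex), 32)

    def test_non_finite_input_rejected(self):
        x = np.zeros((1, 1, 8))
        x[0, 0, 0] = np.nan
        with pytest.raises(ValueError):
            forward_transform(x)


class TestLowpass:
    def test_full_cutoff_is_identity(self, X):
        F = forward_transform(X)
        assert np.array_equal(lowpass(F, 1.0).coeffs, F.coeffs)

    def test_near_zero_cutoff_keeps_only_the_mean(self, X):
        F = lowpass(forward_transform(X), 1e-9)
        sig = inverse_transform(F)
        assert np.allclose(sig, X.mean(axis=2, keepdims=True))

    def test_cosine_above_cutoff_is_removed(self):
        T, m = 64, 20
        x = np.cos(2 * np.pi * m * np.arange(T) / T)[None, None]
        out = inverse_transform(lowpass(forward_transform(x), 0.25))
        assert np.max(np.abs(out)) < 1e-9


class TestPhaseShift:
    def test_zero_noise_zero_shift_is_identity(self, X, monkeypatch):
        F = forward_transform(X)

        class NoShift:
            def normal(self, *a, **k):
                raise AssertionError("no per-bin noise expected")

            def uniform(self, lo, hi, size=None):
                return np.zeros(size)

        out = phase_shift(F, 0.0, NoShift())
        assert np.allclose(out.coeffs, F.coeffs)

    @pytest.mark.parametrize("fixture", ["X", "Xe"])
    def test_magnitudes_preserved_bin_by_bin(self, fixture, request, rng):
        x = request.getfixturevalue(fixture)
        F = forward_transform(x)
        out = phase_shift(F, 0.5, rng)
        assert np.allclose(np.abs(out.coeffs), np.abs(F.coeffs))

    @pytest.mark.parametrize("fixture", ["X", "Xe"])
    def test_inverse_stays_real(self, fixture, request, rng):
        x = request.getfixturevalue(fixture)
        out = phase_shift(forward_transform(x), 0.5, rng)
        assert imag_residual(out) < 1e-9

    def test_negative_sd_rejected(self, X, rng):
        with pytest.raises(ValueError):
            phase_shift(forward_transform(X), -0.1, rng)


class TestRemoveAdd:
    def test_zero_fraction_identities(self, X, rng):
        F = forward_transform(X)
        assert np.array_equal(remove_frequency(F, 0.0, rng).coeffs, F.coeffs)
        assert np.array_equal(add_frequency(F, 0.0, 0.1, rng).coeffs, F.coeffs)

    def test_zero_scale_add_is_identity(self, X, rng):
        F = forward_transform(X)
        assert np.array_equal(add_frequency(F, 0.5, 0.0, rng).coeffs, F.coeffs)

    def test_remove_zeroes_exactly_floor_fraction_K_bins(self, rng):
        x = rng.normal(size=(5, 2, 38)) + 5.0  # K = 20, no accidental zeros
        F = forward_transform(x)
        out = remove_frequency(F, 0.1, rng)
        changed = out.coeffs != F.coeffs
        assert (changed.sum(axis=2) == 2).all()
        assert (out.coeffs[changed] == 0).all()

    def test_remove_never_increases_energy(self, X, rng):
        F = forward_transform(X)
        out = remove_frequency(F, 0.3, rng)
        assert (np.abs(out.coeffs) ** 2).sum() <= (np.abs(F.coeffs) ** 2).sum()

    def test_add_perturbs_exactly_floor_fraction_K_bins(self, rng):
        x = rng.normal(size=(5, 2, 38))
        F = forward_transform(x)
        out = add_frequency(F, 0.1, 0.1, rng)
        changed = out.coeffs != F.coeffs
        assert (changed.sum(axis=2) == 2).all()

    @pytest.mark.parametrize("fixture", ["X", "Xe"])
    def test_add_keeps_inverse_real(self, fixture, request, rng):
        x = request.getfixturevalue(fixture)
        out = add_frequency(forward_transform(x), 0.5, 0.5, rng)
        assert imag_residual(out) < 1e-9


class TestBank:
    def test_p_zero_is_round_trip_identity(self, X):
        cfg = FreqAugConfig(p_apply=0.0, seed=1)
        out = apply_freq_bank(X, cfg)
        assert np.max(np.abs(out - X)) < 1e-9

    @pytest.mark.parametrize("T", [32, 33])
    def test_output_real_and_shape_preserved(self, T, rng):
        x = rng.normal(size=(6, 2, T))
        out = apply_freq_bank(x, FreqAugConfig(p_apply=1.0, seed=2))
        assert out.shape == x.shape
        assert np.isrealobj(out) and np.all(np.isfinite(out))

    def test_fixed_seed_is_deterministic(self, X):
        cfg = FreqAugConfig(seed=7)
        assert np.array_equal(apply_freq_bank(X, cfg), apply_freq_bank(X, cfg))
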