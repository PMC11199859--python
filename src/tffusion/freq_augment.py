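"""Spectral transforms and the frequency-domain augmentation bank.

Windows are carried into the frequency domain with the one-sided real
FFT (K = T//2 + 1 bins), perturbed there, and brought back with the
inverse transform so the augmented view re-enters the pipeline as a real
time series. Using the one-sided representation keeps conjugate symmetry
(and hence a real inverse) automatic; the DC bin and, for even T, the
Nyquist bin are kept real under phase edits for the same reason.

Operators: brick-wall low-pass, phase perturbation (per-bin Gaussian
noise plus one uniform(-pi, pi) shift per window), random bin removal,
random bin addition. Each fires per window with probability ``p_apply``
(default 0.25).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import WindowBatch
from .time_augment import window_rng

__all__ = ["SpectrumBatch", "FreqAugConfig", "forward_transform",
           "inverse_transform", "lowpass", "phase_shift",
           "remove_frequency", "add_frequency", "apply_freq_bank"]


@dataclass
class SpectrumBatch:
    """One-sided complex spectra (N x S x K) with the original length T."""

    coeffs: np.ndarray
    origin_length: int

    def __post_init__(self):
        self.coeffs = np.asarray(self.coeffs, dtype=np.complex128)
        if self.coeffs.ndim != 3:
            raise ValueError("coeffs must be (n_windows, n_channels, n_bins)")
        if self.coeffs.shape[2] != self.origin_length // 2 + 1:
            raise ValueError(
                f"{self.coeffs.shape[2]} bins inconsistent with "
                f"origin_length {self.origin_length}")

    @property
    def n_bins(self) -> int:
        return self.coeffs.shape[2]

    def copy(self) -> "SpectrumBatch":
        return SpectrumBatch(self.coeffs.copy(), self.origin_length)


@dataclass
class FreqAugConfig:
    p_apply: float = 0.25
    cutoff_fraction: float = 0.5
    phase_noise_sd: float = 0.1
    remove_fraction: float = 0.10
    add_fraction: float = 0.10
    add_noise_scale: float = 0.1
    seed: int = 0

    def __post_init__(self):
        for name in ("p_apply", "cutoff_fraction", "remove_fraction", "add_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.phase_noise_sd < 0 or self.add_noise_scale < 0:
            raise ValueError("noise scales must be non-negative")


def forward_transform(X) -> SpectrumBatch:
    """One-sided DFT along the time axis, per window and channel."""
    arr = X.X if isinstance(X, WindowBatch) else np.asarray(X, dtype=np.float64)
    if arr.shape[-1] < 2:
        raise ValueError("window length must be at least 2")
    if not np.all(np.isfinite(arr)):
        raise ValueError("input contains non-finite values")
    return SpectrumBatch(np.fft.rfft(arr, axis=-1), arr.shape[-1])


def inverse_transform(F: SpectrumBatch) -> np.ndarray:
    """Real time-domain signal of the original length, (N, S, T)."""
    return np.fft.irfft(F.coeffs, n=F.origin_length, axis=-1)


def lowpass(F: SpectrumBatch, cutoff_fraction: float) -> SpectrumBatch:
    """Brick-wall filter: zero all bins with index >= ceil(cutoff * K)."""
    if not 0.0 <= cutoff_fraction <= 1.0:
        raise ValueError("cutoff_fraction must be in [0, 1]")
    out = F.copy()
    keep = int(np.ceil(cutoff_fraction * F.n_bins))
    out.coeffs[:, :, keep:] = 0.0
    return out


def phase_shift(F: SpectrumBatch, noise_sd: float,
                rng: np.random.Generator) -> SpectrumBatch:
    """Perturb phases, leaving the magnitude spectrum untouched.

    Per bin: Gaussian noise of sd ``noise_sd``; per window: one global
    shift drawn uniformly from (-pi, pi), shared across channels and
    bins. The DC bin and (for even T) the Nyquist bin keep their phase so
    the inverse stays real.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    out = F.copy()
    N, S, K = out.coeffs.shape
    mag = np.abs(out.coeffs)
    ang = np.angle(out.coeffs)
    eps = rng.normal(0.0, noise_sd, size=(N, S, K)) if noise_sd > 0 else 0.0
    delta = rng.uniform(-np.pi, np.pi, size=(N, 1, 1))
    new_ang = ang + eps + delta
    new_ang[:, :, 0] = ang[:, :, 0]
    if F.origin_length % 2 == 0:
        new_ang[:, :, -1] = ang[:, :, -1]
    out.coeffs = mag * np.exp(1j * new_ang)
    return out


def remove_frequency(F: SpectrumBatch, fraction: float,
                     rng: np.random.Generator) -> SpectrumBatch:
    """Zero exactly floor(fraction * K) bins per window-channel."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    out = F.copy()
    N, S, K = out.coeffs.shape
    m = int(np.floor(fraction * K))
    if m == 0:
        return out
    for i in range(N):
        for s in range(S):
            idx = rng.choice(K, size=m, replace=False)
            out.coeffs[i, s, idx] = 0.0
    return out


def add_frequency(F: SpectrumBatch, fraction: float, noise_scale: float,
                  rng: np.random.Generator) -> SpectrumBatch:
    """Add complex perturbations to floor(fraction * K) bins per window-channel.

    Each selected bin receives a component of magnitude
    ``noise_scale * max_k |coeffs[i, s, k]|`` at a uniform random phase;
    on the DC/Nyquist bins the perturbation is projected to its real part
    so the inverse stays real.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    if noise_scale < 0:
        raise ValueError("noise_scale must be non-negative")
    out = F.copy()
    N, S, K = out.coeffs.shape
    m = int(np.floor(fraction * K))
    if m == 0 or noise_scale == 0:
        return out
    real_bins = {0} | ({K - 1} if F.origin_length % 2 == 0 else set())
    for i in range(N):
        for s in range(S):
            idx = rng.choice(K, size=m, replace=False)
            amp = noise_scale * np.max(np.abs(F.coeffs[i, s]))
            theta = rng.uniform(0.0, 2.0 * np.pi, size=m)
            pert = amp * np.exp(1j * theta)
            for j, k in enumerate(idx):
                if k in real_bins:
                    out.coeffs[i, s, k] += amp * np.cos(theta[j])
                else:
                    out.coeffs[i, s, k] += pert[j]
    return out


def apply_freq_bank(X, cfg: FreqAugConfig, epoch: int = 0,
                    indices: np.ndarray | None = None):
    """FFT -> per-window stochastic bank -> inverse FFT.

    Per window, each operator fires with probability ``cfg.p_apply`` in
    the fixed order lowpass -> phase_shift -> remove -> add, using the
    same (seed, epoch, window index) substream scheme as the time bank.
    """
    arr = X.X if isinstance(X, WindowBatch) else np.asarray(X, dtype=np.float64)
    N = arr.shape[0]
    if indices is None:
        indices = np.arange(N)
    F = forward_transform(arr)
    out = F.coeffs.copy()
    for i in range(N):
        rng = window_rng(cfg.seed ^ 0x1F2E3D, epoch, indices[i])
        fires = rng.random(4) < cfg.p_apply
        sub = SpectrumBatch(F.coeffs[i:i + 1].copy(), F.origin_length)
        if fires[0]:
            sub = lowpass(sub, cfg.cutoff_fraction)
        if fires[1]:
            sub = phase_shift(sub, cfg.phase_noise_sd, rng)
        if fires[2]:
            sub = remove_frequency(sub, cfg.remove_fraction, rng)
        if fires[3]:
            sub = add_frequency(sub, cfg.add_fraction, cfg.add_noise_scale, rng)
        out[i] = sub.coeffs[0]
    sig = inverse_transform(SpectrumBatch(out, F.origin_length))
    if isinstance(X, WindowBatch):
        return WindowBatch(sig, X.y, dict(X.metadata))
    return sig
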