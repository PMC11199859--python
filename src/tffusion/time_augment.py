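"""Time-domain augmentation bank: jitter, scaling, permutation, masking.

Each operator is applied to a window with probability ``p_apply`` (default
0.25, i.e. one of the four operators fires per window in expectation).
The bank draws a dedicated RNG substream per window from
``(seed, epoch, window_index)``, so results do not depend on how a dataset
is partitioned into batches.

Defaults follow the experimental setting this bank models: Gaussian
jitter with sd 0.01, scaling factors uniform on (0.9, 1.1), masking of
10% of the time points with value 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import WindowBatch

__all__ = ["TimeAugConfig", "jitter", "scale", "permute", "mask",
           "apply_time_bank"]


@dataclass
class TimeAugConfig:
    p_apply: float = 0.25
    jitter_sd: float = 0.01
    scale_low: float = 0.9
    scale_high: float = 1.1
    n_segments: int = 4
    mask_fraction: float = 0.10
    mask_value: float = 0.0
    per_channel_mask: bool = False
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.p_apply <= 1.0:
            raise ValueError("p_apply must be in [0, 1]")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be non-negative")
        if self.scale_low > self.scale_high:
            raise ValueError("scale_low must not exceed scale_high")
        if self.n_segments < 1:
            raise ValueError("n_segments must be at least 1")
        if not 0.0 <= self.mask_fraction <= 1.0:
            raise ValueError("mask_fraction must be in [0, 1]")


def _unwrap(X):
    if isinstance(X, WindowBatch):
        return X.X, X
    return np.asarray(X, dtype=np.float64), None


def _rewrap(arr, src):
    if src is None:
        return arr
    return WindowBatch(arr, src.y, dict(src.metadata))


def jitter(X, sd: float, rng: np.random.Generator):
    """Add i.i.d. Gaussian noise of standard deviation ``sd`` elementwise."""
    if sd < 0:
        raise ValueError("sd must be non-negative")
    arr, src = _unwrap(X)
    if sd == 0:
        return _rewrap(arr.copy(), src)
    return _rewrap(arr + rng.normal(0.0, sd, size=arr.shape), src)


def scale(X, low: float, high: float, rng: np.random.Generator):
    """Multiply each window by one scalar drawn uniformly from [low, high]."""
    if low > high:
        raise ValueError("low must not exceed high")
    arr, src = _unwrap(X)
    factors = rng.uniform(low, high, size=arr.shape[0])
    return _rewrap(arr * factors[:, None, None], src)


def _segment_bounds(T: int, n_segments: int) -> np.ndarray:
    # near-equal contiguous intervals, sizes differing by at most 1
    return np.linspace(0, T, n_segments + 1).round().astype(int)


def permute(X, n_segments: int, rng: np.random.Generator):
    """Cut the time axis into near-equal segments and shuffle their order.

    The permutation is drawn per window and applied identically across
    channels, so the per-channel multiset of values is preserved.
    """
    arr, src = _unwrap(X)
    T = arr.shape[2]
    if not 1 <= n_segments <= T:
        raise ValueError("n_segments must be in [1, window length]")
    if n_segments == 1:
        return _rewrap(arr.copy(), src)
    bounds = _segment_bounds(T, n_segments)
    out = np.empty_like(arr)
    for i in range(arr.shape[0]):
        order = rng.permutation(n_segments)
        pieces = [arr[i, :, bounds[j]:bounds[j + 1]] for j in order]
        out[i] = np.concatenate(pieces, axis=1)
    return _rewrap(out, src)


def mask(X, fraction: float, value: float, rng: np.random.Generator,
         per_channel: bool = False):
    """Set exactly ``floor(fraction * T)`` time indices per window to ``value``.

    Masked indices are drawn uniformly without replacement and, by
    default, shared across channels (point-in-time dropout).
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    arr, src = _unwrap(X)
    N, S, T = arr.shape
    m = int(np.floor(fraction * T))
    out = arr.copy()
    if m == 0:
        return _rewrap(out, src)
    for i in range(N):
        if per_channel:
            for s in range(S):
                idx = rng.choice(T, size=m, replace=False)
                out[i, s, idx] = value
        else:
            idx = rng.choice(T, size=m, replace=False)
            out[i, :, idx] = value
    return _rewrap(out, src)


def window_rng(seed: int, epoch: int, index: int) -> np.random.Generator:
    """The dedicated RNG substream for one window of one augmentation epoch."""
    return np.random.default_rng(
        np.random.SeedSequence((int(seed), int(epoch), int(index))))


def apply_time_bank(X, cfg: TimeAugConfig, epoch: int = 0,
                    indices: np.ndarray | None = None):
    """Apply the full bank window-by-window.

    For each window, each operator independently fires with probability
    ``cfg.p_apply``, composed in the fixed order
    jitter -> scale -> permute -> mask.
    """
    arr, src = _unwrap(X)
    N = arr.shape[0]
    if indices is None:
        indices = np.arange(N)
    out = np.empty_like(arr)
    for i in range(N):
        rng = window_rng(cfg.seed, epoch, indices[i])
        fires = rng.random(4) < cfg.p_apply
        w = arr[i:i + 1]
        if fires[0]:
            w = jitter(w, cfg.jitter_sd, rng)
        if fires[1]:
            w = scale(w, cfg.scale_low, cfg.scale_high, rng)
        if fires[2]:
            w = permute(w, cfg.n_segments, rng)
        if fires[3]:
            w = mask(w, cfg.mask_fraction, cfg.mask_value, rng,
                     per_channel=cfg.per_channel_mask)
        out[i] = w[0]
    return _rewrap(out, src)
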