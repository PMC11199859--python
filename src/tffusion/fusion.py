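"""Kernel-PCA fusion of the time- and frequency-augmented views.

The two augmented views of a window are flattened (channel-major), each
flattened matrix is passed through its own kernel PCA (fitted once per
pre-training run on a capped, seeded subsample of augmented pretrain
windows), and the two C-dimensional score vectors are concatenated:

    fused = KernelPCA_time(flat_time) (+) KernelPCA_freq(flat_freq)

The 2C-vector is zero-padded to a multiple of the channel count S and
reshaped to (S, ceil(2C/S)) so it can re-enter the encoder, whose
adaptive pooling accepts any window length.
"""

from __future__ import annotations

import warnings

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.decomposition import KernelPCA
from sklearn.exceptions import NotFittedError

from .data import WindowBatch

__all__ = ["flatten_windows", "unflatten_windows", "KernelPCAFusion"]


def flatten_windows(X) -> np.ndarray:
    """(N, S, T) -> (N, S*T), channel-major (channel 0's samples first)."""
    arr = X.X if isinstance(X, WindowBatch) else np.asarray(X)
    if arr.ndim == 2:
        return arr
    n = arr.shape[0]
    return arr.reshape(n, -1)


def unflatten_windows(M: np.ndarray, n_channels: int, window: int) -> np.ndarray:
    return np.asarray(M).reshape(-1, n_channels, window)


def _fix_signs(kpca: KernelPCA) -> None:
    # sign convention: largest-magnitude loading of each eigenvector positive
    vec = kpca.eigenvectors_
    flip = np.sign(vec[np.abs(vec).argmax(axis=0), np.arange(vec.shape[1])])
    flip[flip == 0] = 1.0
    kpca.eigenvectors_ *= flip[None, :]


class KernelPCAFusion(BaseEstimator):
    """Paired kernel PCAs (time branch, frequency branch) plus concatenation.

    Parameters
    ----------
    n_components : int or None
        Components per branch; ``None`` picks ``min(floor(S*T/2), n_fit-1)``
        at fit time.
    kernel : str
        Any sklearn KernelPCA kernel; default ``"rbf"``.
    gamma : float or None
        RBF bandwidth; ``None`` means ``1 / (S*T)``.
    fit_cap : int
        Maximum number of rows used to fit each branch; larger fit sets
        are subsampled with ``random_state``.
    """

    def __init__(self, n_components: int | None = None, kernel: str = "rbf",
                 gamma: float | None = None, fit_cap: int = 1000,
                 random_state: int | None = 0):
        self.n_components = n_components
        self.kernel = kernel
        self.gamma = gamma
        self.fit_cap = fit_cap
        self.random_state = random_state

    def fit(self, time_views, freq_views):
        """Fit both branches on (possibly 3-D) augmented views."""
        Mt = flatten_windows(time_views)
        Mf = flatten_windows(freq_views)
        if Mt.shape[0] != Mf.shape[0]:
            raise ValueError("branches must be fitted on the same windows")
        rng = np.random.default_rng(self.random_state)
        n = Mt.shape[0]
        if n > self.fit_cap:
            sel = rng.choice(n, size=self.fit_cap, replace=False)
            Mt, Mf = Mt[sel], Mf[sel]
            n = self.fit_cap
        d = Mt.shape[1]
        C = self.n_components
        if C is None:
            C = min(d // 2, n - 1)
        if C < 1:
            raise ValueError("need at least one component")
        if C > n - 1:
            warnings.warn(
                f"n_components={C} exceeds fit sample rank bound {n - 1}; reduced")
            C = n - 1
        self.n_components_ = C
        self.fit_sample_size_ = n
        self.time_kpca_ = self._make(C, Mt.shape[1]).fit(Mt)
        self.freq_kpca_ = self._make(C, Mf.shape[1]).fit(Mf)
        for k in (self.time_kpca_, self.freq_kpca_):
            _fix_signs(k)
        return self

    def _make(self, C: int, d: int) -> KernelPCA:
        gamma = self.gamma if self.gamma is not None else 1.0 / d
        return KernelPCA(n_components=C, kernel=self.kernel, gamma=gamma)

    def _check_fitted(self):
        if not hasattr(self, "time_kpca_"):
            raise NotFittedError("KernelPCAFusion is not fitted")

    def transform_time(self, views) -> np.ndarray:
        self._check_fitted()
        return self.time_kpca_.transform(flatten_windows(views))

    def transform_freq(self, views) -> np.ndarray:
        self._check_fitted()
        return self.freq_kpca_.transform(flatten_windows(views))

    def fuse(self, t_aug, f_aug):
        """Concatenate branch scores and reshape to (N, S, ceil(2C/S)).

        ``t_aug`` and ``f_aug`` are the augmented views of the same
        windows; the channel count S is taken from the inputs (2-D input
        is treated as single-channel).
        """
        self._check_fitted()
        arr = t_aug.X if isinstance(t_aug, WindowBatch) else np.asarray(t_aug)
        S = arr.shape[1] if arr.ndim == 3 else 1
        zt = self.transform_time(t_aug)
        zf = self.transform_freq(f_aug)
        z = np.concatenate([zt, zf], axis=1)
        width = z.shape[1]
        out_len = -(-width // S)  # ceil
        padded = np.zeros((z.shape[0], S * out_len))
        padded[:, :width] = z
        fused = padded.reshape(-1, S, out_len)
        if isinstance(t_aug, WindowBatch):
            return WindowBatch(fused, t_aug.y, dict(t_aug.metadata))
        return fused
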