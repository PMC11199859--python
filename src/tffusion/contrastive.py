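"""NT-Xent contrastive loss and self-supervised pre-training.

The loss for a positive pair (i, j) inside a pool of 2N projection
vectors is

    L_{i,j} = -log[ exp(sim(z_i, z_j)/tau)
                    / sum_{k != i} exp(sim(z_i, z_k)/tau) ]

with cosine similarity ``sim`` and temperature ``tau``; the batch loss
averages the symmetrized pair losses over the N instances. Gradients
with respect to the raw (unnormalized) projections are computed
analytically and checked against finite differences in the tests.

Pre-training pairs each original window with a mode-dependent augmented
view: the kernel-PCA fusion of its time- and frequency-augmented
versions (``tf-fc``), or a single-domain view (``time-only`` /
``freq-only``) for ablations. Negatives are all other windows' views in
the same batch. Augmentations are re-drawn every epoch from per-(epoch,
window) RNG substreams, and incomplete trailing batches are dropped so
every denominator sees a fixed 2N pool.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.exceptions import NotFittedError

from . import nn
from .data import WindowBatch
from .encoder import EncoderConfig, build_encoder, build_projector
from .freq_augment import FreqAugConfig, apply_freq_bank
from .fusion import KernelPCAFusion
from .time_augment import TimeAugConfig, apply_time_bank

__all__ = ["nt_xent_pair", "nt_xent_batch", "nt_xent_batch_with_grad",
           "ContrastiveEncoder", "pretrain"]

MODES = ("tf-fc", "time-only", "freq-only")

# epoch tag reserved for the fusion-fitting augmentation draw
_FUSION_EPOCH = 999_983


def _normalize_rows(Z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    norms = np.linalg.norm(Z, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise ValueError("cosine similarity undefined for zero-norm vectors")
    return Z / norms, norms


def nt_xent_pair(all_z: np.ndarray, i: int, j: int, tau: float) -> float:
    """The pair loss L_{i,j} given the full 2N pool of projections."""
    if tau <= 0:
        raise ValueError("temperature must be positive")
    U, _ = _normalize_rows(np.asarray(all_z, dtype=np.float64))
    sims = U @ U[i] / tau
    others = np.delete(sims, i)
    m = others.max()
    log_denom = m + np.log(np.exp(others - m).sum())
    return float(log_denom - sims[j])


def nt_xent_batch(view_a: np.ndarray, view_b: np.ndarray, tau: float) -> float:
    """Mean symmetrized NT-Xent loss over N positive pairs."""
    loss, _, _ = nt_xent_batch_with_grad(view_a, view_b, tau)
    return loss


def nt_xent_batch_with_grad(view_a: np.ndarray, view_b: np.ndarray, tau: float):
    """Batch loss plus gradients w.r.t. the raw projections of both views."""
    if tau <= 0:
        raise ValueError("temperature must be positive")
    Za = np.asarray(view_a, dtype=np.float64)
    Zb = np.asarray(view_b, dtype=np.float64)
    if Za.shape != Zb.shape:
        raise ValueError("views must have identical shapes")
    N = Za.shape[0]
    Z = np.vstack([Za, Zb])
    U, norms = _normalize_rows(Z)
    S = (U @ U.T) / tau
    M = 2 * N
    idx = np.arange(M)
    pos = (idx + N) % M
    # log-softmax over k != i
    S_masked = S.copy()
    S_masked[idx, idx] = -np.inf
    row_max = S_masked.max(axis=1, keepdims=True)
    expS = np.exp(S_masked - row_max)
    denom = expS.sum(axis=1, keepdims=True)
    log_denom = (row_max + np.log(denom)).ravel()
    loss = float(np.mean(log_denom - S[idx, pos]))
    # gradient w.r.t. similarity matrix
    P = expS / denom
    G = P / M
    G[idx, pos] -= 1.0 / M
    G[idx, idx] = 0.0
    dU = ((G + G.T) @ U) / tau
    dZ = (dU - U * (U * dU).sum(axis=1, keepdims=True)) / norms
    return loss, dZ[:N], dZ[N:]


class ContrastiveEncoder(BaseEstimator, TransformerMixin):
    """Self-supervised 1-D ResNet encoder trained with NT-Xent.

    ``fit`` pre-trains on unlabeled windows; ``transform`` maps windows
    to D-dimensional embeddings with the frozen encoder (evaluation
    mode). The projection head is used only inside ``fit``.

    Parameters mirror the pre-training setup this model family uses:
    Adam (lr 1e-4, betas 0.9/0.99), L2 penalty 1e-5, 100 epochs,
    temperature 0.2, batch size 128; all overridable.
    """

    def __init__(self, mode: str = "tf-fc", temperature: float = 0.2,
                 batch_size: int = 128, epochs: int = 100,
                 learning_rate: float = 1e-4, beta1: float = 0.9,
                 beta2: float = 0.99, l2: float = 1e-5,
                 channels: tuple = (32, 64, 128), kernel_size: int = 7,
                 embed_dim: int = 128, proj_dim: int = 64,
                 time_aug: TimeAugConfig | None = None,
                 freq_aug: FreqAugConfig | None = None,
                 fusion_kernel: str = "rbf", fusion_gamma: float | None = None,
                 fusion_components: int | None = None, fusion_fit_cap: int = 1000,
                 random_state: int = 0):
        self.mode = mode
        self.temperature = temperature
        self.batch_size = batch_size
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.beta1 = beta1
        self.beta2 = beta2
        self.l2 = l2
        self.channels = channels
        self.kernel_size = kernel_size
        self.embed_dim = embed_dim
        self.proj_dim = proj_dim
        self.time_aug = time_aug
        self.freq_aug = freq_aug
        self.fusion_kernel = fusion_kernel
        self.fusion_gamma = fusion_gamma
        self.fusion_components = fusion_components
        self.fusion_fit_cap = fusion_fit_cap
        self.random_state = random_state

    # -- internals ---------------------------------------------------------

    def _aug_configs(self, seed_t: int, seed_f: int):
        t = self.time_aug if self.time_aug is not None else TimeAugConfig()
        f = self.freq_aug if self.freq_aug is not None else FreqAugConfig()
        # rebuild with run-derived seeds so the user config stays untouched
        t = TimeAugConfig(**{**t.__dict__, "seed": seed_t})
        f = FreqAugConfig(**{**f.__dict__, "seed": seed_f})
        return t, f

    def _augmented_view(self, X: np.ndarray, epoch: int, indices: np.ndarray):
        if self.mode == "time-only":
            return apply_time_bank(X, self._tcfg, epoch=epoch, indices=indices)
        if self.mode == "freq-only":
            return apply_freq_bank(X, self._fcfg, epoch=epoch, indices=indices)
        t = apply_time_bank(X, self._tcfg, epoch=epoch, indices=indices)
        f = apply_freq_bank(X, self._fcfg, epoch=epoch, indices=indices)
        return self.fusion_.fuse(t, f)

    # -- estimator API -----------------------------------------------------

    def fit(self, X, y=None):
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        arr = X.X if isinstance(X, WindowBatch) else np.asarray(X, dtype=np.float64)
        if arr.ndim != 3:
            raise ValueError("X must be (n_windows, n_channels, window_length)")
        n, S, T = arr.shape
        if n < self.batch_size:
            raise ValueError("need at least one full batch of windows")
        ss = np.random.SeedSequence(self.random_state)
        seed_w, seed_shuf, seed_t, seed_f, seed_fu = [
            int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(5)]
        self._tcfg, self._fcfg = self._aug_configs(seed_t, seed_f)

        self.encoder_cfg_ = EncoderConfig(
            channels=self.channels, kernel_size=self.kernel_size,
            embed_dim=self.embed_dim, proj_dim=self.proj_dim, in_channels=S)
        wrng = np.random.default_rng(seed_w)
        self.encoder_net_ = build_encoder(self.encoder_cfg_, wrng)
        self.projector_ = build_projector(self.encoder_cfg_, wrng)

        if self.mode == "tf-fc":
            t_fit = apply_time_bank(arr, self._tcfg, epoch=_FUSION_EPOCH)
            f_fit = apply_freq_bank(arr, self._fcfg, epoch=_FUSION_EPOCH)
            self.fusion_ = KernelPCAFusion(
                n_components=self.fusion_components, kernel=self.fusion_kernel,
                gamma=self.fusion_gamma, fit_cap=self.fusion_fit_cap,
                random_state=seed_fu).fit(t_fit, f_fit)
        else:
            self.fusion_ = None

        params = self.encoder_net_.params() + self.projector_.params()
        opt = nn.Adam(params, lr=self.learning_rate,
                      betas=(self.beta1, self.beta2), l2=self.l2)
        shuffle_rng = np.random.default_rng(seed_shuf)
        history = []
        n_batches = n // self.batch_size
        for epoch in range(self.epochs):
            order = shuffle_rng.permutation(n)
            epoch_losses = []
            for b in range(n_batches):
                sel = order[b * self.batch_size:(b + 1) * self.batch_size]
                xa = arr[sel]
                xb = self._augmented_view(xa, epoch, sel)
                if isinstance(xb, WindowBatch):
                    xb = xb.X
                za = self.projector_.forward(
                    self.encoder_net_.forward(xa, train=True), train=True)
                zb = self.projector_.forward(
                    self.encoder_net_.forward(xb, train=True), train=True)
                loss, dza, dzb = nt_xent_batch_with_grad(za, zb, self.temperature)
                opt.zero_grad()
                # layer caches currently hold view B; backprop it first,
                # then re-run the forward pass on A to restore its caches
                self.encoder_net_.backward(self.projector_.backward(dzb))
                self.projector_.forward(
                    self.encoder_net_.forward(xa, train=True), train=True)
                self.encoder_net_.backward(self.projector_.backward(dza))
                opt.step()
                epoch_losses.append(loss)
            history.append(float(np.mean(epoch_losses)))
        self.loss_history_ = history
        self.n_channels_ = S
        return self

    def transform(self, X) -> np.ndarray:
        if not hasattr(self, "encoder_net_"):
            raise NotFittedError("ContrastiveEncoder is not fitted")
        arr = X.X if isinstance(X, WindowBatch) else np.asarray(X, dtype=np.float64)
        return self.encoder_net_.forward(arr, train=False)


def pretrain(data, mode: str = "tf-fc", **kwargs) -> ContrastiveEncoder:
    """Functional wrapper: pre-train a :class:`ContrastiveEncoder` on data."""
    return ContrastiveEncoder(mode=mode, **kwargs).fit(data)
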