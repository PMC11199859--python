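"""Supervised fine-tuning on the labeled split, and evaluation metrics.

``FineTuneClassifier`` attaches the two-hidden-layer softmax head
(256/128 neurons, ReLU, dropout 0.2) to a pre-trained encoder and trains
with cross-entropy; by default the whole network is updated, optionally
only the head (``freeze_encoder``). Without a pre-trained encoder it
fine-tunes from random initialization, which is the no-pretraining
baseline.

``evaluate`` reports accuracy, macro-averaged precision/recall/F1 and
the confusion matrix (rows = true class, columns = predicted class).
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.exceptions import NotFittedError
from sklearn.metrics import (accuracy_score, confusion_matrix,
                             precision_recall_fscore_support)

from . import nn
from .contrastive import ContrastiveEncoder
from .data import WindowBatch
from .encoder import EncoderConfig, HeadConfig, build_encoder, build_head

__all__ = ["FineTuneClassifier", "MetricsReport", "evaluate"]


@dataclass
class MetricsReport:
    accuracy: float
    precision: float
    recall: float
    f1: float
    confusion: np.ndarray  # (C, C) counts, rows = truth
    averaging: str = "macro"

    def to_dict(self) -> dict:
        return {"accuracy": self.accuracy, "precision": self.precision,
                "recall": self.recall, "f1": self.f1,
                "confusion": np.asarray(self.confusion).tolist(),
                "averaging": self.averaging}

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


class FineTuneClassifier(BaseEstimator, ClassifierMixin):
    """Encoder + softmax head trained with cross-entropy.

    Parameters
    ----------
    encoder : fitted ContrastiveEncoder or None
        Pre-trained encoder to start from (its weights are deep-copied,
        so fine-tuning never mutates the pre-trained object). ``None``
        builds a randomly initialized encoder with the geometry given by
        ``channels`` / ``kernel_size`` / ``embed_dim``.
    freeze_encoder : bool
        If True only the head is trained.
    patience : int
        Early stopping on the fine-tune-split loss: stop after this many
        epochs without improvement and restore the best weights.
    """

    def __init__(self, encoder: ContrastiveEncoder | None = None,
                 epochs: int = 50, learning_rate: float = 1e-4,
                 beta1: float = 0.9, beta2: float = 0.99, l2: float = 0.0,
                 batch_size: int = 32, hidden: tuple = (256, 128),
                 dropout: float = 0.2, freeze_encoder: bool = False,
                 patience: int = 10, channels: tuple = (32, 64, 128),
                 kernel_size: int = 7, embed_dim: int = 128,
                 random_state: int = 0):
        self.encoder = encoder
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.beta1 = beta1
        self.beta2 = beta2
        self.l2 = l2
        self.batch_size = batch_size
        self.hidden = hidden
        self.dropout = dropout
        self.freeze_encoder = freeze_encoder
        self.patience = patience
        self.channels = channels
        self.kernel_size = kernel_size
        self.embed_dim = embed_dim
        self.random_state = random_state

    def fit(self, X, y=None):
        arr, labels = _unpack(X, y)
        self.classes_, y_idx = np.unique(labels, return_inverse=True)
        if len(self.classes_) < 2:
            raise ValueError("need at least 2 classes")
        ss = np.random.SeedSequence((int(self.random_state), 0xF17E))
        seed_w, seed_shuf, seed_drop = [
            int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(3)]

        if self.encoder is not None:
            if not hasattr(self.encoder, "encoder_net_"):
                raise NotFittedError("the supplied encoder is not pre-trained")
            if self.encoder.n_channels_ != arr.shape[1]:
                raise ValueError("encoder channel count does not match the data")
            self.encoder_net_ = copy.deepcopy(self.encoder.encoder_net_)
            self.encoder_cfg_ = self.encoder.encoder_cfg_
        else:
            self.encoder_cfg_ = EncoderConfig(
                channels=self.channels, kernel_size=self.kernel_size,
                embed_dim=self.embed_dim,
                proj_dim=min(self.embed_dim, 64), in_channels=arr.shape[1])
            self.encoder_net_ = build_encoder(
                self.encoder_cfg_, np.random.default_rng(seed_w))

        self.head_cfg_ = HeadConfig(n_classes=len(self.classes_),
                                    hidden=self.hidden, dropout=self.dropout)
        drop_rng = np.random.default_rng(seed_drop)
        self.head_ = build_head(self.encoder_cfg_.embed_dim, self.head_cfg_,
                                np.random.default_rng(seed_w + 1))
        for layer in self.head_.layers:
            if isinstance(layer, nn.Dropout):
                layer.rng = drop_rng

        params = self.head_.params()
        if not self.freeze_encoder:
            params = self.encoder_net_.params() + params
        opt = nn.Adam(params, lr=self.learning_rate,
                      betas=(self.beta1, self.beta2), l2=self.l2)
        shuffle_rng = np.random.default_rng(seed_shuf)
        n = arr.shape[0]
        bs = min(self.batch_size, n)
        history: list[float] = []
        best = (np.inf, None)
        stall = 0
        for _ in range(self.epochs):
            order = shuffle_rng.permutation(n)
            losses = []
            for start in range(0, n, bs):
                sel = order[start:start + bs]
                z = self.encoder_net_.forward(
                    arr[sel], train=not self.freeze_encoder)
                logits = self.head_.forward(z, train=True)
                loss, dlogits = nn.softmax_cross_entropy(logits, y_idx[sel])
                opt.zero_grad()
                dz = self.head_.backward(dlogits)
                if not self.freeze_encoder:
                    self.encoder_net_.backward(dz)
                opt.step()
                losses.append(loss)
            epoch_loss = float(np.mean(losses))
            history.append(epoch_loss)
            if epoch_loss < best[0] - 1e-6:
                best = (epoch_loss, [p.value.copy() for p in params])
                stall = 0
            else:
                stall += 1
                if stall >= self.patience:
                    break
        if best[1] is not None:
            for p, v in zip(params, best[1]):
                p.value[...] = v
        self.loss_history_ = history
        return self

    def _check_fitted(self):
        if not hasattr(self, "head_"):
            raise NotFittedError("FineTuneClassifier is not fitted")

    def predict_proba(self, X) -> np.ndarray:
        self._check_fitted()
        arr, _ = _unpack(X, None)
        z = self.encoder_net_.forward(arr, train=False)
        return nn.softmax(self.head_.forward(z, train=False))

    def predict(self, X) -> np.ndarray:
        return self.classes_[self.predict_proba(X).argmax(axis=1)]


def _unpack(X, y):
    if isinstance(X, WindowBatch):
        return X.X, X.y if y is None else np.asarray(y)
    return np.asarray(X, dtype=np.float64), None if y is None else np.asarray(y)


def evaluate(model, X, y=None) -> MetricsReport:
    """Score a fitted classifier on a labeled evaluation set."""
    arr, labels = _unpack(X, y)
    if labels is None:
        raise ValueError("evaluation requires labels")
    if arr.shape[0] == 0:
        raise ValueError("evaluation set is empty")
    pred = model.predict(arr)
    classes = np.unique(np.concatenate([np.unique(labels), model.classes_]))
    prec, rec, f1, _ = precision_recall_fscore_support(
        labels, pred, labels=classes, average="macro", zero_division=0)
    return MetricsReport(
        accuracy=float(accuracy_score(labels, pred)),
        precision=float(prec), recall=float(rec), f1=float(f1),
        confusion=confusion_matrix(labels, pred, labels=classes),
        averaging="macro")
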