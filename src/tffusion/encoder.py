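"""1-D residual encoder, contrastive projection head, classification head.

The encoder is three residual blocks (conv-BN-ReLU-conv-BN with an
identity or 1x1-projection shortcut) followed by adaptive average
pooling to one bin and a linear map to the embedding dimension D. The
pooling step is what lets a single encoder digest windows of any length,
including the reshaped kernel-PCA-fused views.

The projection head (used only by the contrastive loss) is
FC -> BN -> ReLU -> FC. The classification head is
FC(256) -> ReLU -> dropout -> FC(128) -> ReLU -> dropout -> FC(C) -> softmax.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from . import nn

__all__ = ["EncoderConfig", "HeadConfig", "build_encoder", "build_projector",
           "build_head", "encode", "project", "classify",
           "save_checkpoint", "load_checkpoint"]


@dataclass
class EncoderConfig:
    channels: tuple = (32, 64, 128)
    kernel_size: int = 7
    embed_dim: int = 128
    proj_dim: int = 64
    in_channels: int = 1
    residual: bool = True

    def __post_init__(self):
        self.channels = tuple(self.channels)
        if len(self.channels) != 3:
            raise ValueError("the encoder uses exactly 3 blocks")
        if not self.embed_dim >= self.proj_dim >= 2:
            raise ValueError("need embed_dim >= proj_dim >= 2")


@dataclass
class HeadConfig:
    n_classes: int = 2
    hidden: tuple = (256, 128)
    dropout: float = 0.2

    def __post_init__(self):
        self.hidden = tuple(self.hidden)
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")


def build_encoder(cfg: EncoderConfig, rng: np.random.Generator) -> nn.Sequential:
    layers: list[nn.Layer] = []
    c_in = cfg.in_channels
    for c_out in cfg.channels:
        if cfg.residual:
            layers.append(nn.ResidualBlock1d(c_in, c_out, cfg.kernel_size, rng))
        else:
            layers.append(nn.Conv1d(c_in, c_out, cfg.kernel_size, rng))
            layers.append(nn.BatchNorm(c_out))
            layers.append(nn.ReLU())
        c_in = c_out
    layers.append(nn.GlobalAvgPool1d())
    layers.append(nn.Dense(c_in, cfg.embed_dim, rng))
    return nn.Sequential(layers)


def build_projector(cfg: EncoderConfig, rng: np.random.Generator) -> nn.Sequential:
    return nn.Sequential([
        nn.Dense(cfg.embed_dim, cfg.embed_dim, rng),
        nn.BatchNorm(cfg.embed_dim),
        nn.ReLU(),
        nn.Dense(cfg.embed_dim, cfg.proj_dim, rng),
    ])


def build_head(embed_dim: int, cfg: HeadConfig,
               rng: np.random.Generator) -> nn.Sequential:
    h1, h2 = cfg.hidden
    return nn.Sequential([
        nn.Dense(embed_dim, h1, rng),
        nn.ReLU(),
        nn.Dropout(cfg.dropout, rng),
        nn.Dense(h1, h2, rng),
        nn.ReLU(),
        nn.Dropout(cfg.dropout, rng),
        nn.Dense(h2, cfg.n_classes, rng),
    ])


def _check_channels(net: nn.Sequential, X: np.ndarray) -> None:
    first = net.layers[0]
    conv = first.conv1 if isinstance(first, nn.ResidualBlock1d) else first
    expect = conv.W.value.shape[1]
    if X.shape[1] != expect:
        raise ValueError(f"input has {X.shape[1]} channels, encoder expects {expect}")


def encode(net: nn.Sequential, X: np.ndarray, train: bool = False) -> np.ndarray:
    """Map (N, S, T) windows to (N, D) embeddings."""
    X = np.asarray(X, dtype=np.float64)
    _check_channels(net, X)
    return net.forward(X, train=train)


def project(projector: nn.Sequential, z: np.ndarray, train: bool = False) -> np.ndarray:
    """Embeddings -> projection space; NOT length-normalized here (the
    contrastive loss's cosine similarity does its own normalization)."""
    return projector.forward(np.asarray(z, dtype=np.float64), train=train)


def classify(head: nn.Sequential, z: np.ndarray, train: bool = False) -> np.ndarray:
    """Embeddings -> class probabilities (rows sum to 1)."""
    logits = head.forward(np.asarray(z, dtype=np.float64), train=train)
    return nn.softmax(logits)


# -- checkpointing ---------------------------------------------------------

def _collect_state(net: nn.Sequential, prefix: str) -> dict:
    state = {}
    for i, p in enumerate(net.params()):
        state[f"{prefix}.p{i}"] = p.value
    for i, bn in enumerate(_batchnorms(net)):
        state[f"{prefix}.bn{i}.mean"] = bn.running_mean
        state[f"{prefix}.bn{i}.var"] = bn.running_var
    return state


def _batchnorms(layer: nn.Layer) -> list[nn.BatchNorm]:
    found = []
    if isinstance(layer, nn.BatchNorm):
        found.append(layer)
    elif isinstance(layer, nn.Sequential):
        for sub in layer.layers:
            found.extend(_batchnorms(sub))
    elif isinstance(layer, nn.ResidualBlock1d):
        found.extend([layer.bn1, layer.bn2])
        if layer.shortcut is not None:
            found.extend(_batchnorms(layer.shortcut))
    return found


def _restore_state(net: nn.Sequential, prefix: str, state: dict) -> None:
    for i, p in enumerate(net.params()):
        p.value[...] = state[f"{prefix}.p{i}"]
    for i, bn in enumerate(_batchnorms(net)):
        bn.running_mean[...] = state[f"{prefix}.bn{i}.mean"]
        bn.running_var[...] = state[f"{prefix}.bn{i}.var"]


def save_checkpoint(path, encoder_cfg: EncoderConfig, nets: dict,
                    extra: dict | None = None) -> None:
    """Write configs plus named networks to a single .npz archive."""
    arrays = {"config_json": np.frombuffer(
        json.dumps(asdict(encoder_cfg)).encode(), dtype=np.uint8),
        "extra_json": np.frombuffer(
            json.dumps(extra or {}).encode(), dtype=np.uint8)}
    for name, net in nets.items():
        arrays.update(_collect_state(net, name))
    np.savez(path, **arrays)


def load_checkpoint(path, builders: dict):
    """Rebuild networks from an archive; returns (config, nets, extra).

    ``builders`` maps net name -> callable(cfg, rng) -> Sequential; the
    rng only sets initial weights, which are then overwritten.
    """
    with np.load(path) as z:
        state = {k: z[k] for k in z.files}
    cfg = EncoderConfig(**json.loads(bytes(state.pop("config_json")).decode()))
    extra = json.loads(bytes(state.pop("extra_json")).decode())
    rng = np.random.default_rng(0)
    nets = {}
    for name, builder in builders.items():
        net = builder(cfg, rng)
        _restore_state(net, name, state)
        nets[name] = net
    return cfg, nets, extra
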