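"""Attention-augmented 1D CNN-GRU seizure classifier and its training loop.

Architecture (five learned layers by default): two conv+max-pool blocks
(kernel 3, length-preserving padding) -> scaled dot-product self-attention
over the pooled feature sequence -> GRU whose final hidden state feeds a
dropout + single-logit sigmoid head. Binary cross-entropy accepts soft
labels so mixup targets train without rounding.
"""
from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field

import numpy as np

from . import nn
from .eeg_io import ValidationError, WindowSet

logger = logging.getLogger(__name__)

__all__ = ["ModelConfig", "ConfigurationError", "SeizureModel", "build", "train", "predict"]


class ConfigurationError(ValueError):
    pass


@dataclass
class ModelConfig:
    """Hyperparameters; the reference defaults are conv kernel 3, max
    pooling, 128 GRU units, dropout 0.5, Adam at lr 0.001, 50 epochs,
    batch size 256. All overridable."""

    conv_kernel: int = 3
    conv_channels: tuple[int, ...] = (32, 64)
    pool_size: int = 2
    attention_dim: int = 64
    gru_units: int = 128
    dropout: float = 0.5
    lr: float = 0.001
    epochs: int = 50
    batch_size: int = 256
    seed: int = 0
    attention: bool = True  # False => ablation: attention layer bypassed
    gru_mirror: bool = False

    def pooling_factor(self) -> int:
        return self.pool_size ** len(self.conv_channels)


class SeizureModel:
    """Parameter set theta with a differentiable loss J(theta, x, y).

    ``forward`` maps a ``(batch, channels, samples)`` window tensor to
    seizure probabilities in [0, 1]; ``input_gradient`` exposes dJ/dx as
    required by adversarial augmentation.
    """

    def __init__(self, cfg: ModelConfig, n_channels: int, window_samples: int) -> None:
        if window_samples % cfg.pooling_factor() != 0:
            raise ConfigurationError(
                f"window_samples={window_samples} not divisible by cumulative "
                f"pooling factor {cfg.pooling_factor()}"
            )
        self.cfg = cfg
        self.n_channels = n_channels
        self.window_samples = window_samples
        self.trained = False
        rng = np.random.default_rng(cfg.seed)
        layers: list[nn.Layer] = []
        c_in = n_channels
        for c_out in cfg.conv_channels:
            layers.append(nn.Conv1dSame(c_in, c_out, cfg.conv_kernel, rng))
            layers.append(nn.ReLU())
            layers.append(nn.MaxPool1d(cfg.pool_size))
            c_in = c_out
        if cfg.attention:
            layers.append(nn.SelfAttention(c_in, cfg.attention_dim, rng))
            gru_in = cfg.attention_dim
        else:
            gru_in = c_in
        layers.append(nn.GRULast(gru_in, cfg.gru_units, rng, mirror=cfg.gru_mirror))
        layers.append(nn.Dropout(cfg.dropout))
        layers.append(nn.Dense(cfg.gru_units, 1, rng))
        self.layers = layers

    # -- parameter bookkeeping ------------------------------------------------
    def parameters(self) -> dict[str, np.ndarray]:
        out = {}
        for i, layer in enumerate(self.layers):
            for name, arr in layer.params.items():
                out[f"layer{i}.{name}"] = arr
        return out

    def gradients(self) -> dict[str, np.ndarray]:
        out = {}
        for i, layer in enumerate(self.layers):
            for name, arr in layer.grads.items():
                out[f"layer{i}.{name}"] = arr
        return out

    def param_count(self) -> int:
        return int(sum(v.size for v in self.parameters().values()))

    # -- forward / backward ---------------------------------------------------
    def _check_input(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float64)
        if x.ndim == 2:
            x = x[None]
        if x.ndim != 3 or x.shape[1] != self.n_channels or x.shape[2] != self.window_samples:
            raise ValidationError(
                f"expected windows of shape (*, {self.n_channels}, "
                f"{self.window_samples}), got {x.shape}"
            )
        return x

    def forward_logits(self, x: np.ndarray, training: bool = False, rng=None) -> np.ndarray:
        x = self._check_input(x)
        h = x.transpose(0, 2, 1)  # -> (batch, time, channels)
        for layer in self.layers:
            h = layer.forward(h, training=training, rng=rng)
        return h[:, 0]

    def forward(self, x: np.ndarray, training: bool = False, rng=None) -> np.ndarray:
        return nn.sigmoid(self.forward_logits(x, training=training, rng=rng))

    def loss(self, x: np.ndarray, y: np.ndarray, training: bool = False, rng=None) -> float:
        logits = self.forward_logits(x, training=training, rng=rng)
        value, _ = nn.bce_with_logits(logits, y)
        return value

    def _backward_from_logits(self, dlogits: np.ndarray) -> np.ndarray:
        dh = dlogits[:, None]
        for layer in reversed(self.layers):
            dh = layer.backward(dh)
        return dh.transpose(0, 2, 1)  # back to (batch, channels, samples)

    def loss_and_gradients(
        self, x: np.ndarray, y: np.ndarray, training: bool = False, rng=None
    ) -> tuple[float, dict[str, np.ndarray], np.ndarray]:
        """Mean BCE loss, parameter gradients, and input gradient dJ/dx."""
        logits = self.forward_logits(x, training=training, rng=rng)
        value, dlogits = nn.bce_with_logits(logits, np.asarray(y, dtype=np.float64))
        dx = self._backward_from_logits(dlogits)
        return value, self.gradients(), dx

    def input_gradient(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Gradient of the mean BCE loss with respect to the input windows.

        Computed in inference mode (dropout off) so it is deterministic.
        """
        _, _, dx = self.loss_and_gradients(x, y, training=False)
        return dx

    def predict_proba(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        x = self._check_input(x)
        chunks = [
            self.forward(x[i : i + batch_size]) for i in range(0, len(x), batch_size)
        ]
        return np.concatenate(chunks) if chunks else np.empty(0)

    # -- persistence ----------------------------------------------------------
    def save(self, weights_path, manifest_path=None) -> None:
        np.savez(weights_path, **self.parameters())
        if manifest_path is not None:
            manifest = {
                "config": asdict(self.cfg),
                "n_channels": self.n_channels,
                "window_samples": self.window_samples,
                "param_count": self.param_count(),
                "trained": self.trained,
            }
            with open(manifest_path, "w") as fh:
                json.dump(manifest, fh, indent=2, default=list)

    @classmethod
    def load(cls, weights_path, cfg: ModelConfig, n_channels: int, window_samples: int) -> "SeizureModel":
        model = cls(cfg, n_channels, window_samples)
        with np.load(weights_path) as data:
            params = model.parameters()
            for key in params:
                params[key][...] = data[key]
        model.trained = True
        return model


def build(cfg: ModelConfig, n_channels: int, window_samples: int) -> SeizureModel:
    model = SeizureModel(cfg, n_channels, window_samples)
    logger.info(
        "built model: %d channels x %d samples, %d parameters",
        n_channels, window_samples, model.param_count(),
    )
    return model


def _data_arrays(data) -> tuple[np.ndarray, np.ndarray]:
    windows = np.asarray(data.windows, dtype=np.float64)
    labels = np.asarray(data.labels, dtype=np.float64)
    return windows, labels


def train(model: SeizureModel, data, cfg: ModelConfig | None = None) -> list[dict]:
    """Train in place on a WindowSet or AugmentedSet; returns the epoch log.

    Shuffled mini-batches, Adam, mean BCE (soft labels allowed). Seeded:
    two runs from the same initial parameters, data and seed produce
    identical trajectories on the same hardware/thread settings.
    """
    cfg = cfg or model.cfg
    x, y = _data_arrays(data)
    if len(x) == 0:
        raise ValidationError("training data is empty")
    if np.any((y < 0) | (y > 1)):
        raise ValidationError("labels must lie in [0, 1]")
    rng = np.random.default_rng(cfg.seed + 1)
    optim = nn.Adam(model.parameters(), lr=cfg.lr)
    log: list[dict] = []
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(x))
        total, correct, seen = 0.0, 0, 0
        for start in range(0, len(x), cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            xb, yb = x[idx], y[idx]
            logits = model.forward_logits(xb, training=True, rng=rng)
            loss, dlogits = nn.bce_with_logits(logits, yb)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, batch starting at {start} "
                    f"(batch indices {idx[:5].tolist()}...)"
                )
            model._backward_from_logits(dlogits)
            optim.step(model.gradients())
            total += loss * len(idx)
            correct += int(((logits >= 0) == (yb >= 0.5)).sum())
            seen += len(idx)
        entry = {"epoch": epoch, "loss": total / seen, "train_acc": correct / seen}
        log.append(entry)
        logger.debug("epoch %d: loss=%.4f acc=%.3f", epoch, entry["loss"], entry["train_acc"])
    model.trained = True
    return log


def predict(model: SeizureModel, windows: WindowSet, threshold: float = 0.5) -> tuple[np.ndarray, np.ndarray]:
    """Probabilities and hard labels for a (normalized) WindowSet."""
    if windows.windows.shape[1] != model.n_channels:
        raise ValidationError(
            f"channel-count mismatch: model expects {model.n_channels}, "
            f"got {windows.windows.shape[1]}"
        )
    probs = model.predict_proba(windows.windows, batch_size=model.cfg.batch_size)
    return probs, (probs >= threshold).astype(np.int64)
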