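"""Model assembly, Adam training loop and prediction for the 1DCNN family."""

from __future__ import annotations

import json
import time
from dataclasses import asdict
from pathlib import Path
from typing import Optional, Union

import numpy as np

from ..dataset import SpectrumTable
from ..errors import ShapeError, ValidationError
from .config import DeepConfig, EcaSpec
from .layers import (
    ECA,
    Conv1d,
    Dense,
    GlobalAveragePool,
    Layer,
    MaxPool1d,
    MultiHeadSelfAttention,
    Param,
    ReLU,
    ToSequence,
    softmax,
)
from .lstm import LSTMStack

__all__ = ["SpectralNet", "build_model", "train", "predict", "save_checkpoint", "load_checkpoint"]


class SpectralNet:
    """Sequential network over spectra: conv front end, optional LSTM /
    multi-head attention / ECA, global average pooling and a linear head."""

    def __init__(self, cfg: DeepConfig):
        self.cfg = cfg
        dtype = np.dtype(cfg.dtype)
        rng = np.random.default_rng(cfg.rng_seed)
        layers: list[Layer] = [
            Conv1d(1, cfg.conv_channels, cfg.kernel_size, cfg.padding, rng, dtype),
            ReLU(),
            MaxPool1d(cfg.pool_width),
            ToSequence(),
        ]
        if cfg.use_lstm:
            layers.append(LSTMStack(cfg.conv_channels, cfg.lstm_hidden, cfg.lstm_layers, rng, dtype))
        if cfg.use_attention:
            layers.append(MultiHeadSelfAttention(cfg.d_model, cfg.attn_heads, rng, dtype))
        if cfg.use_eca:
            layers.append(ECA(EcaSpec(cfg.d_model, cfg.eca_gamma, cfg.eca_b), dtype))
        layers.append(GlobalAveragePool())
        layers.append(Dense(cfg.d_model, cfg.n_classes, rng, dtype))
        self.layers = layers
        self.dtype = dtype
        # Per-band input standardization fitted on the training table; spectra
        # (derivative spectra especially) are orders of magnitude away from
        # unit scale, which stalls optimisation without this conditioning.
        self.input_mean: Optional[np.ndarray] = None
        self.input_sd: Optional[np.ndarray] = None

    def fit_input_scaling(self, table: SpectrumTable) -> None:
        self.input_mean = table.spectra.mean(axis=0)
        self.input_sd = np.sqrt(np.maximum(table.spectra.var(axis=0), 1e-12))

    # -- plumbing ----------------------------------------------------------
    def params(self) -> list[Param]:
        return [p for layer in self.layers for p in layer.params()]

    def n_parameters(self) -> int:
        return sum(p.value.size for p in self.params())

    def zero_grad(self) -> None:
        for p in self.params():
            p.grad[...] = 0.0

    # -- passes ------------------------------------------------------------
    def forward_logits(self, rows: np.ndarray) -> np.ndarray:
        rows = np.atleast_2d(np.asarray(rows))
        if rows.shape[1] != self.cfg.n_bands:
            raise ShapeError(f"expected {self.cfg.n_bands} bands, got {rows.shape[1]}")
        if self.input_mean is not None:
            rows = (rows - self.input_mean) / self.input_sd
        x = rows.astype(self.dtype)[:, None, :]  # (N, 1, B)
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def loss_and_backward(self, rows: np.ndarray, labels: np.ndarray) -> float:
        """Mean cross-entropy on a batch; accumulates parameter gradients."""
        logits = self.forward_logits(rows)
        n = logits.shape[0]
        probs = softmax(logits.astype(np.float64), axis=1)
        idx = np.asarray(labels, dtype=int) - 1
        loss = float(-np.log(np.maximum(probs[np.arange(n), idx], 1e-12)).mean())
        self.last_batch_correct = int((probs.argmax(axis=1) == idx).sum())
        dlogits = probs.copy()
        dlogits[np.arange(n), idx] -= 1.0
        dlogits /= n
        dy = dlogits.astype(self.dtype)
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return loss


def build_model(cfg: DeepConfig) -> SpectralNet:
    """Instantiate the ablation variant selected by the config flags."""
    return SpectralNet(cfg)


class Adam:
    def __init__(self, params: list[Param], lr: float, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value, dtype=np.float64) for p in params]
        self.v = [np.zeros_like(p.value, dtype=np.float64) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad.astype(np.float64)
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            update = self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
            p.value -= update.astype(p.value.dtype)


def train(
    model: SpectralNet,
    table: SpectrumTable,
    cfg: Optional[DeepConfig] = None,
    eval_table: Optional[SpectrumTable] = None,
) -> tuple[SpectralNet, list[dict]]:
    """Adam / mini-batch / cross-entropy training with seeded shuffling.

    Returns the trained model and a per-epoch trace of mean batch loss,
    training accuracy and (if ``eval_table`` is given) test accuracy, for
    loss-curve artifacts.
    """
    cfg = cfg or model.cfg
    if table.labels.min() < 1 or table.labels.max() > cfg.n_classes:
        raise ValidationError("labels must lie in 1..n_classes")
    rng = np.random.default_rng([cfg.rng_seed, 1])
    if model.input_mean is None:
        model.fit_input_scaling(table)
    opt = Adam(model.params(), cfg.learning_rate)
    n = table.n_samples
    trace: list[dict] = []
    for epoch in range(cfg.epochs):
        t0 = time.perf_counter()
        order = rng.permutation(n)
        losses = []
        correct = 0
        for start in range(0, n, cfg.batch_size):
            batch = order[start : start + cfg.batch_size]
            model.zero_grad()
            loss = model.loss_and_backward(table.spectra[batch], table.labels[batch])
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, batch {start // cfg.batch_size}; "
                    "lower the learning rate"
                )
            opt.step()
            losses.append(loss)
            correct += model.last_batch_correct
        record = {
            "epoch": epoch,
            "loss": float(np.mean(losses)),
            "train_accuracy": correct / n,  # running, pre-update per batch
            "seconds": time.perf_counter() - t0,
        }
        if eval_table is not None:
            record["test_accuracy"] = _accuracy(model, eval_table)
        trace.append(record)
    return model, trace


def _accuracy(model: SpectralNet, table: SpectrumTable, batch: int = 256) -> float:
    pred, _ = predict(model, table.spectra, batch=batch)
    return float((pred == table.labels).mean())


def predict(
    model: SpectralNet, rows: np.ndarray, batch: int = 256
) -> tuple[np.ndarray, np.ndarray]:
    """Labels (1-based; argmax, ties to the smaller label) and softmax probabilities."""
    rows = np.atleast_2d(np.asarray(rows))
    probs = np.empty((rows.shape[0], model.cfg.n_classes))
    for start in range(0, rows.shape[0], batch):
        logits = model.forward_logits(rows[start : start + batch]).astype(np.float64)
        probs[start : start + batch] = softmax(logits, axis=1)
    return probs.argmax(axis=1) + 1, probs


def save_checkpoint(model: SpectralNet, trace: list[dict], out_dir: Union[str, Path]) -> None:
    """Write named parameter arrays plus the JSON config and trace."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    arrays = {f"{i:03d}_{p.name}": p.value for i, p in enumerate(model.params())}
    if model.input_mean is not None:
        arrays["input_mean"] = model.input_mean
        arrays["input_sd"] = model.input_sd
    np.savez(out / "checkpoint.npz", **arrays)
    (out / "config.json").write_text(json.dumps(asdict(model.cfg), indent=2))
    (out / "trace.json").write_text(json.dumps(trace, indent=2))


def load_checkpoint(out_dir: Union[str, Path]) -> SpectralNet:
    out = Path(out_dir)
    cfg = DeepConfig(**json.loads((out / "config.json").read_text()))
    model = SpectralNet(cfg)
    with np.load(out / "checkpoint.npz") as data:
        for i, p in enumerate(model.params()):
            p.value[...] = data[f"{i:03d}_{p.name}"]
        if "input_mean" in data:
            model.input_mean = data["input_mean"]
            model.input_sd = data["input_sd"]
    return model
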