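"""Evaluation metrics, confusion matrices, grid/ablation runner and reports.

Accuracy, precision and recall come from per-class one-vs-rest counts on the
confusion matrix; precision and recall are macro-averaged (unweighted class
means), the natural choice for the exactly balanced class design.  The loss
is mean cross-entropy in nats.
"""

from __future__ import annotations

import itertools
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .classical import KNNConfig, RFConfig, elm_fit, elm_predict, knn_predict, rf_fit_predict
from .dataset import NormalizationSpec, SpectrumTable, fit_apply_normalization
from .errors import ShapeError, ValidationError
from .preprocess import PreprocessSpec, apply_preprocess

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "confusion",
    "metrics_from_confusion",
    "cross_entropy",
    "evaluate_predictions",
    "run_grid",
    "run_ablation",
]


@dataclass
class ConfusionMatrix:
    """V x V counts; rows index the true class, columns the predicted class."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValidationError("confusion matrix must be square")
        if (self.counts < 0).any():
            raise ValidationError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def n_classes(self) -> int:
        return self.counts.shape[0]


@dataclass
class MetricsReport:
    accuracy: float
    macro_precision: float
    macro_recall: float
    per_class_precision: np.ndarray
    per_class_recall: np.ndarray
    confusion: ConfusionMatrix
    mean_loss: Optional[float] = None
    metadata: dict = field(default_factory=dict)


def confusion(true_labels, predicted_labels, n_classes: int) -> ConfusionMatrix:
    """Tally ``counts[i, j] = #{true == i+1 and predicted == j+1}``."""
    t = np.asarray(true_labels, dtype=int)
    p = np.asarray(predicted_labels, dtype=int)
    if t.shape != p.shape:
        raise ShapeError("true and predicted label vectors differ in length")
    counts = np.zeros((n_classes, n_classes), dtype=int)
    if t.size:
        if t.min() < 1 or t.max() > n_classes or p.min() < 1 or p.max() > n_classes:
            raise ValueError(f"labels must lie in 1..{n_classes}")
        np.add.at(counts, (t - 1, p - 1), 1)
    return ConfusionMatrix(counts)


def metrics_from_confusion(cm: ConfusionMatrix) -> MetricsReport:
    """Accuracy plus macro precision/recall from one-vs-rest counts.

    A class never predicted has precision 0/0, reported as 0 with a warning
    so macro means stay defined.
    """
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    counts = cm.counts.astype(float)
    tp = np.diag(counts)
    fp = counts.sum(axis=0) - tp
    fn = counts.sum(axis=1) - tp
    pred_pos = tp + fp
    undefined = pred_pos == 0
    if undefined.any():
        warnings.warn(
            f"{int(undefined.sum())} class(es) never predicted; precision set to 0"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(undefined, 0.0, tp / np.maximum(pred_pos, 1e-300))
        recall = np.where(tp + fn == 0, 0.0, tp / np.maximum(tp + fn, 1e-300))
    return MetricsReport(
        accuracy=float(tp.sum() / cm.total),
        macro_precision=float(precision.mean()),
        macro_recall=float(recall.mean()),
        per_class_precision=precision,
        per_class_recall=recall,
        confusion=cm,
    )


def cross_entropy(probabilities: np.ndarray, one_hot_labels: np.ndarray) -> float:
    """Mean cross-entropy in nats: -(1/N) sum_i sum_c y_ic log p_ic."""
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(one_hot_labels, dtype=float)
    if p.shape != y.shape:
        raise ShapeError("probabilities and one-hot labels differ in shape")
    sums = p.sum(axis=1)
    if not np.allclose(sums, 1.0, atol=1e-6):
        raise ValidationError("probability rows must sum to 1 within 1e-6")
    return float(-(y * np.log(np.clip(p, 1e-12, None))).sum() / p.shape[0])


def evaluate_predictions(
    true_labels, predicted_labels, n_classes: int,
    probabilities: Optional[np.ndarray] = None, **metadata
) -> MetricsReport:
    """Convenience: confusion + metrics (+ loss when probabilities are given)."""
    report = metrics_from_confusion(confusion(true_labels, predicted_labels, n_classes))
    if probabilities is not None:
        t = np.asarray(true_labels, dtype=int)
        one_hot = (t[:, None] == np.arange(1, n_classes + 1)[None, :]).astype(float)
        report.mean_loss = cross_entropy(probabilities, one_hot)
    report.metadata = metadata
    return report


# ---------------------------------------------------------------------------
# Grid / ablation runner
# ---------------------------------------------------------------------------

def _fit_eval_cell(model: str, params: dict, train_t: SpectrumTable,
                   test_t: SpectrumTable, seed: int) -> tuple[np.ndarray, Optional[np.ndarray]]:
    """Fit one grid cell and return (test predictions, probabilities or None)."""
    if model == "knn":
        norm = NormalizationSpec(params.get("normalization", "NONE"))
        cfg = KNNConfig(k=params.get("k", 5), metric=params.get("metric", "EUCLIDEAN"),
                        normalization=norm)
        tr, te, _ = fit_apply_normalization(train_t, test_t, norm)
        return knn_predict(tr, te.spectra, cfg), None
    if model == "elm":
        m = elm_fit(train_t, n_hidden=params.get("n_hidden", 150),
                    ridge=params.get("ridge", 1e-6), rng_seed=seed)
        return elm_predict(m, test_t.spectra), None
    if model == "rf":
        cfg = RFConfig(n_trees=params.get("n_trees", 100),
                       min_leaf=params.get("min_leaf", 1), rng_seed=seed)
        return rf_fit_predict(train_t, test_t, cfg), None
    if model == "deep":
        from .deepnet import DeepConfig, build_model, predict as deep_predict, train as deep_train

        cfg = DeepConfig(n_classes=train_t.n_varieties, n_bands=train_t.n_bands,
                         rng_seed=seed, **params)
        net, _ = deep_train(build_model(cfg), train_t)
        labels, probs = deep_predict(net, test_t.spectra)
        return labels, probs
    raise ValidationError(f"unknown model {model!r}")


def run_grid(
    train_table: SpectrumTable,
    test_table: SpectrumTable,
    preprocess_methods: list[PreprocessSpec],
    model_grids: dict[str, list[dict]],
    seed: int = 0,
) -> pd.DataFrame:
    """Evaluate every (preprocess x model x hyperparameter) cell.

    Returns one row per cell with metrics and wall-clock time; a failing
    cell is recorded with its error message and the run continues.
    """
    rows = []
    for pp, (model, grid) in itertools.product(
        preprocess_methods, model_grids.items()
    ):
        tr = apply_preprocess(train_table, pp)
        te = apply_preprocess(test_table, pp)
        for params in grid:
            record = {
                "preprocess": pp.method,
                "model": model,
                "params": str(params),
                "seed": seed,
            }
            t0 = time.perf_counter()
            try:
                pred, probs = _fit_eval_cell(model, params, tr, te, seed)
                rep = evaluate_predictions(te.labels, pred, te.n_varieties, probs)
                record.update(
                    accuracy=rep.accuracy,
                    macro_precision=rep.macro_precision,
                    macro_recall=rep.macro_recall,
                    loss=rep.mean_loss,
                    error="",
                )
            except Exception as exc:  # keep the sweep alive
                record.update(accuracy=np.nan, macro_precision=np.nan,
                              macro_recall=np.nan, loss=np.nan, error=str(exc))
            record["time_s"] = time.perf_counter() - t0
            rows.append(record)
    return pd.DataFrame(rows)


def run_ablation(
    train_table: SpectrumTable,
    test_table: SpectrumTable,
    base_params: Optional[dict] = None,
    seed: int = 0,
) -> pd.DataFrame:
    """The four-variant ablation: 1DCNN, +LSTM, +ATTENTION, +ECA (CLA-CA)."""
    from .deepnet import DeepConfig, build_model, predict as deep_predict, train as deep_train

    flag_sets = [
        (False, False, False),
        (True, False, False),
        (True, True, False),
        (True, True, True),
    ]
    rows = []
    for use_lstm, use_attention, use_eca in flag_sets:
        params = dict(base_params or {})
        # The plain CNN baseline traditionally runs narrower than the full model.
        if not use_lstm:
            params.setdefault("conv_channels", 32)
        cfg = DeepConfig(
            n_classes=train_table.n_varieties, n_bands=train_table.n_bands,
            use_lstm=use_lstm, use_attention=use_attention, use_eca=use_eca,
            rng_seed=seed, **params,
        )
        t0 = time.perf_counter()
        net, trace = deep_train(build_model(cfg), train_table)
        pred, probs = deep_predict(net, test_table.spectra)
        rep = evaluate_predictions(test_table.labels, pred, test_table.n_varieties, probs)
        rows.append({
            "model": cfg.ablation_name(),
            "accuracy": rep.accuracy,
            "macro_precision": rep.macro_precision,
            "macro_recall": rep.macro_recall,
            "loss": rep.mean_loss,
            "final_train_loss": trace[-1]["loss"],
            "time_s": time.perf_counter() - t0,
            "n_parameters": net.n_parameters(),
            "seed": seed,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Figure writers
# ---------------------------------------------------------------------------

def plot_confusion(cm: ConfusionMatrix, path: Union[str, Path], title: str = "") -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 6))
    im = ax.imshow(cm.counts, cmap="Blues")
    ax.set_xlabel("predicted class")
    ax.set_ylabel("true class")
    if title:
        ax.set_title(title)
    fig.colorbar(im, ax=ax)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_loss_curves(trace: list[dict], path: Union[str, Path], title: str = "") -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    ax.plot([r["epoch"] for r in trace], [r["loss"] for r in trace], label="train loss")
    ax.set_xlabel("epoch")
    ax.set_ylabel("cross-entropy (nats)")
    if title:
        ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
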