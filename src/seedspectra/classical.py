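"""Classical baselines: K-nearest neighbours, extreme learning machine, random forest.

KNN and the ELM are implemented directly because their hyperparameter grids
(distance metrics, feature normalisations, hidden-node counts) are part of
the evaluation protocol; the random forest is an off-the-shelf baseline and
delegates to scikit-learn.

Distances available to KNN: Euclidean, Manhattan, Spearman
(1 - rank correlation) and correlation (1 - Pearson).  Votes are majority
over the k nearest training spectra, ties broken by smaller mean distance
within the tied labels, then by smaller label.

The ELM is a single-hidden-layer network whose input weights and biases are
drawn uniform[-1, 1] once and frozen; only the output weights are fitted, by
ridge-regularised least squares onto one-hot labels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg
from scipy.spatial.distance import cdist
from scipy.stats import rankdata
from sklearn.ensemble import RandomForestClassifier

from .dataset import NormalizationSpec, SpectrumTable
from .errors import ShapeError, ValidationError

__all__ = [
    "KNNConfig",
    "knn_predict",
    "ELMModel",
    "elm_fit",
    "elm_predict",
    "RFConfig",
    "rf_fit_predict",
]

KNN_METRICS = ("EUCLIDEAN", "MANHATTAN", "SPEARMAN", "CORRELATION")
_MAX_CORR_DIST = 2.0  # 1 - r with r in [-1, 1]


@dataclass(frozen=True)
class KNNConfig:
    k: int = 5
    metric: str = "EUCLIDEAN"
    normalization: NormalizationSpec = field(default_factory=NormalizationSpec)

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValidationError("k must be >= 1")
        if self.metric not in KNN_METRICS:
            raise ValidationError(f"metric must be one of {KNN_METRICS}")


def _distances(train: np.ndarray, queries: np.ndarray, metric: str) -> np.ndarray:
    if metric == "EUCLIDEAN":
        return cdist(queries, train, metric="euclidean")
    if metric == "MANHATTAN":
        return cdist(queries, train, metric="cityblock")
    if metric == "SPEARMAN":
        train = rankdata(train, axis=1)
        queries = rankdata(queries, axis=1)
        metric = "CORRELATION"
    with np.errstate(invalid="ignore", divide="ignore"):
        d = cdist(queries, train, metric="correlation")
    bad = ~np.isfinite(d)
    if bad.any():
        warnings.warn(
            f"{int(bad.sum())} undefined correlation distance(s) (constant spectrum); "
            "treated as maximal distance"
        )
        d[bad] = _MAX_CORR_DIST
    return d


def knn_predict(train: SpectrumTable, query_rows: np.ndarray, cfg: KNNConfig) -> np.ndarray:
    """Majority vote over the k nearest training spectra.

    Any feature normalisation is assumed to have been fitted on ``train`` and
    already applied to both inputs (see
    :func:`seedspectra.dataset.fit_apply_normalization`).
    """
    query_rows = np.atleast_2d(np.asarray(query_rows, dtype=float))
    if query_rows.shape[1] != train.n_bands:
        raise ShapeError("query band count differs from training table")
    if cfg.k > train.n_samples:
        raise ValidationError("k exceeds the number of training spectra")
    dist = _distances(train.spectra, query_rows, cfg.metric)
    labels = train.labels
    out = np.empty(len(query_rows), dtype=int)
    for i, row in enumerate(dist):
        nn = np.argpartition(row, cfg.k - 1)[: cfg.k]
        nn_labels = labels[nn]
        candidates, counts = np.unique(nn_labels, return_counts=True)
        best = candidates[counts == counts.max()]
        if len(best) > 1:
            mean_d = np.array([row[nn[nn_labels == lab]].mean() for lab in best])
            best = best[np.flatnonzero(mean_d == mean_d.min())]
        out[i] = best.min()
    return out


@dataclass
class ELMModel:
    """Extreme learning machine with frozen random hidden layer."""

    n_hidden: int = 150
    ridge: float = 1e-6
    rng_seed: int = 0
    input_weights: np.ndarray | None = None  # (n_hidden, B), frozen
    biases: np.ndarray | None = None  # (n_hidden,), frozen
    output_weights: np.ndarray | None = None  # (n_hidden, V), fitted
    classes: np.ndarray | None = None

    def hidden(self, x: np.ndarray) -> np.ndarray:
        """Sigmoid hidden activations H = s(X W^T + b)."""
        z = x @ self.input_weights.T + self.biases
        return 1.0 / (1.0 + np.exp(-z))


def elm_fit(train: SpectrumTable, n_hidden: int = 150, ridge: float = 1e-6, rng_seed: int = 0) -> ELMModel:
    """Draw the frozen hidden layer and solve the output weights.

    ``W, b ~ uniform[-1, 1]`` from ``rng_seed``; output weights are the
    ridge-regularised least-squares solution of ``H beta = Y`` with one-hot
    ``Y``.  With ``ridge = 0`` and singular normal equations the solve falls
    back to the pseudoinverse with a warning.
    """
    if n_hidden < 1:
        raise ValidationError("n_hidden must be >= 1")
    if ridge < 0:
        raise ValidationError("ridge must be >= 0")
    rng = np.random.default_rng(rng_seed)
    model = ELMModel(
        n_hidden=n_hidden,
        ridge=ridge,
        rng_seed=rng_seed,
        input_weights=rng.uniform(-1.0, 1.0, (n_hidden, train.n_bands)),
        biases=rng.uniform(-1.0, 1.0, n_hidden),
    )
    model.classes = np.unique(train.labels)
    y = (train.labels[:, None] == model.classes[None, :]).astype(float)
    h = model.hidden(train.spectra)
    gram = h.T @ h + ridge * np.eye(n_hidden)
    try:
        model.output_weights = linalg.solve(gram, h.T @ y, assume_a="pos")
    except linalg.LinAlgError:
        warnings.warn("singular normal equations; falling back to pseudoinverse")
        model.output_weights = np.linalg.pinv(h) @ y
    return model


def elm_predict(model: ELMModel, query_rows: np.ndarray) -> np.ndarray:
    """Argmax over output scores; ties resolve to the smaller label."""
    if model.output_weights is None:
        raise ValidationError("model is not fitted")
    query_rows = np.atleast_2d(np.asarray(query_rows, dtype=float))
    if query_rows.shape[1] != model.input_weights.shape[1]:
        raise ShapeError("query band count differs from the fitted model")
    scores = model.hidden(query_rows) @ model.output_weights
    return model.classes[np.argmax(scores, axis=1)]


@dataclass(frozen=True)
class RFConfig:
    n_trees: int = 100
    min_leaf: int = 1
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1 or self.min_leaf < 1:
            raise ValidationError("n_trees and min_leaf must be >= 1")


def rf_fit_predict(train: SpectrumTable, test: SpectrumTable, cfg: RFConfig) -> np.ndarray:
    """Bagged decision-tree ensemble (scikit-learn), majority vote, seeded."""
    if train.n_samples == 0:
        raise ValidationError("training table is empty")
    forest = RandomForestClassifier(
        n_estimators=cfg.n_trees,
        min_samples_leaf=cfg.min_leaf,
        random_state=cfg.rng_seed,
        n_jobs=1,
    )
    forest.fit(train.spectra, train.labels)
    return forest.predict(test.spectra).astype(int)
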