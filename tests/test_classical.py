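"""KNN against exhaustive-enumeration oracles, the ELM against a closed-form
least-squares solve, and the random-forest contract."""

import numpy as np
import pytest
from scipy import stats

from seedspectra.classical import (
    ELMModel,
    KNNConfig,
    RFConfig,
    elm_fit,
    elm_predict,
    knn_predict,
    rf_fit_predict,
)
from seedspectra.dataset import SpectrumTable, SplitSpec, split
from seedspectra.errors import ShapeError, ValidationError


def _table(x, y, names=None):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=int)
    v = int(y.max())
    return SpectrumTable(x, y, names or [f"V{i}" for i in range(1, v + 1)],
                         np.arange(x.shape[1], dtype=float))


class TestKNN:
    def test_training_row_is_its_own_nearest_neighbour(self, small_table):
        for metric in ("EUCLIDEAN", "MANHATTAN", "SPEARMAN", "CORRELATION"):
            cfg = KNNConfig(k=1, metric=metric)
            pred = knn_predict(small_table, small_table.spectra[:10], cfg)
            assert (pred == small_table.labels[:10]).all()

    def test_hand_enumerated_toy_vote(self):
        """Class A at {0.0, 0.1}, B at {1.0, 1.1}; query 0.05 with k=3.

        Distances: 0.05, 0.05 (A), 0.95, 1.05 (B) -> neighbours {A, A, B} -> A.
        """
        train = _table([[0.0, 0.0], [0.1, 0.1], [1.0, 1.0], [1.1, 1.1]], [1, 1, 2, 2])
        pred = knn_predict(train, [[0.05, 0.05]], KNNConfig(k=3, metric="EUCLIDEAN"))
        assert pred[0] == 1

    def test_correlation_metric_is_affine_invariant(self, small_table):
        q = 2.0 * small_table.spectra[3] + 5.0
        pred = knn_predict(small_table, [q], KNNConfig(k=1, metric="CORRELATION"))
        assert pred[0] == small_table.labels[3]

    @pytest.mark.parametrize("metric", ["EUCLIDEAN", "MANHATTAN", "SPEARMAN", "CORRELATION"])
    @pytest.mark.parametrize("k", [1, 3, 5])
    def test_agrees_with_exhaustive_enumeration_oracle(self, metric, k, rng):
        """Independent oracle: distances from scipy.stats / plain arithmetic,
        full sort, explicit majority vote with the documented tie-breaks."""
        train = _table(rng.random((30, 12)), rng.integers(1, 5, 30))
        queries = rng.random((12, 12))
        pred = knn_predict(train, queries, KNNConfig(k=k, metric=metric))
        for qi, q in enumerate(queries):
            dists = []
            for row in train.spectra:
                if metric == "EUCLIDEAN":
                    d = float(np.sqrt(((q - row) ** 2).sum()))
                elif metric == "MANHATTAN":
                    d = float(np.abs(q - row).sum())
                elif metric == "SPEARMAN":
                    d = 1.0 - stats.spearmanr(q, row).statistic
                else:
                    d = 1.0 - stats.pearsonr(q, row).statistic
                dists.append(d)
            dists = np.array(dists)
            nn = np.argsort(dists, kind="stable")[:k]
            labs, counts = np.unique(train.labels[nn], return_counts=True)
            winners = labs[counts == counts.max()]
            if len(winners) > 1:
                means = np.array([dists[nn[train.labels[nn] == w]].mean() for w in winners])
                winners = winners[means == means.min()]
            assert pred[qi] == winners.min()

    def test_constant_spectrum_under_correlation_warns(self):
        train = _table([[1.0, 1.0, 1.0], [0.0, 1.0, 2.0]], [1, 2])
        with pytest.warns(UserWarning, match="undefined correlation"):
            pred = knn_predict(train, [[0.0, 0.5, 1.0]], KNNConfig(k=1, metric="CORRELATION"))
        assert pred[0] == 2  # the constant row is pushed to maximal distance

    def test_band_mismatch_rejected(self, small_table):
        with pytest.raises(ShapeError):
            knn_predict(small_table, np.zeros((1, 3)), KNNConfig(k=1))


class TestELM:
    def test_matches_closed_form_least_squares_oracle(self, rng):
        """Re-derive H and the ridge solution independently (lstsq on the
        ridge-augmented system) and compare predicted scores."""
        train = _table(rng.random((40, 10)), rng.integers(1, 4, 40))
        ridge = 1e-3
        model = elm_fit(train, n_hidden=20, ridge=ridge, rng_seed=5)
        gen = np.random.default_rng(5)
        w = gen.uniform(-1, 1, (20, 10))
        b = gen.uniform(-1, 1, 20)
        h = 1.0 / (1.0 + np.exp(-(train.spectra @ w.T + b)))
        y = (train.labels[:, None] == np.unique(train.labels)[None, :]).astype(float)
        aug_a = np.vstack([h, np.sqrt(ridge) * np.eye(20)])
        aug_b = np.vstack([y, np.zeros((20, y.shape[1]))])
        beta, *_ = np.linalg.lstsq(aug_a, aug_b, rcond=None)
        assert np.allclose(model.output_weights, beta, atol=1e-8)
        assert (elm_predict(model, train.spectra)
                == np.unique(train.labels)[(h @ beta).argmax(axis=1)]).all()

    def test_same_seed_gives_identical_fits(self, small_table):
        a = elm_fit(small_table, n_hidden=30, rng_seed=3)
        b = elm_fit(small_table, n_hidden=30, rng_seed=3)
        assert np.array_equal(a.output_weights, b.output_weights)

    def test_perfect_on_separable_training_data(self, separable_table):
        model = elm_fit(separable_table, n_hidden=150, rng_seed=0)
        pred = elm_predict(model, separable_table.spectra)
        assert (pred == separable_table.labels).all()

    def test_training_accuracy_nondecreasing_in_hidden_nodes(self, small_table):
        accs = []
        for n_hidden in (100, 150, 200):
            model = elm_fit(small_table, n_hidden=n_hidden, rng_seed=1)
            pred = elm_predict(model, small_table.spectra)
            accs.append(float((pred == small_table.labels).mean()))
        assert accs == sorted(accs)

    def test_band_mismatch_rejected(self, small_table):
        model = elm_fit(small_table, n_hidden=10, rng_seed=0)
        with pytest.raises(ShapeError):
            elm_predict(model, np.zeros((1, 3)))


class TestRandomForest:
    def test_single_class_training_set_predicts_that_class(self, rng):
        train = _table(rng.random((10, 6)), np.ones(10), names=["only"])
        test = _table(rng.random((5, 6)), np.ones(5), names=["only"])
        assert (rf_fit_predict(train, test, RFConfig(n_trees=10)) == 1).all()

    def test_perfect_on_separable_data(self, separable_table):
        train, test = split(separable_table, SplitSpec(rng_seed=0))
        pred = rf_fit_predict(train, test, RFConfig(rng_seed=0))
        assert (pred == test.labels).all()

    def test_same_seed_gives_identical_predictions(self, small_table):
        train, test = split(small_table, SplitSpec(rng_seed=1))
        a = rf_fit_predict(train, test, RFConfig(n_trees=30, rng_seed=5))
        b = rf_fit_predict(train, test, RFConfig(n_trees=30, rng_seed=5))
        assert np.array_equal(a, b)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValidationError):
            RFConfig(n_trees=0)


class TestNoSignalControl:
    def test_all_classical_models_are_at_chance_without_signal(self, nosignal_table):
        """separability = 0: accuracy must sit within binomial noise of 1/V."""
        train, test = split(nosignal_table, SplitSpec(rng_seed=8))
        v = nosignal_table.n_varieties
        chance = 1.0 / v
        bound = chance + 4 * np.sqrt(chance * (1 - chance) / test.n_samples)
        preds = {
            "knn": knn_predict(train, test.spectra, KNNConfig(k=5)),
            "elm": elm_predict(elm_fit(train, n_hidden=100, rng_seed=0), test.spectra),
            "rf": rf_fit_predict(train, test, RFConfig(n_trees=50, rng_seed=0)),
        }
        for name, pred in preds.items():
            acc = float((pred == test.labels).mean())
            assert acc <= bound, f"{name} above chance on no-signal data: {acc:.3f}"
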