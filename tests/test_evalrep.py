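"""Metrics against hand tallies and loop oracles; grid/ablation runner
structure."""

import numpy as np
import pytest

from seedspectra.dataset import SplitSpec, split
from seedspectra.errors import ShapeError, ValidationError
from seedspectra.evalrep import (
    ConfusionMatrix,
    confusion,
    cross_entropy,
    evaluate_predictions,
    metrics_from_confusion,
    run_ablation,
    run_grid,
)
from seedspectra.preprocess import PreprocessSpec

TRUE = [1, 1, 2, 2, 3, 3]
PRED = [1, 2, 2, 2, 3, 1]


class TestConfusion:
    def test_hand_tally(self):
        cm = confusion(TRUE, PRED, 3)
        expected = np.array([[1, 1, 0], [0, 2, 0], [1, 0, 1]])
        assert np.array_equal(cm.counts, expected)

    def test_perfect_predictions_are_diagonal(self):
        cm = confusion([1, 2, 3, 2], [1, 2, 3, 2], 3)
        assert np.array_equal(cm.counts, np.diag([1, 2, 1]))

    def test_empty_input_gives_zero_matrix(self):
        assert confusion([], [], 4).counts.sum() == 0

    def test_out_of_range_label_rejected(self):
        with pytest.raises(ValueError):
            confusion([1, 5], [1, 1], 3)


class TestMetrics:
    def test_hand_derived_values(self):
        """accuracy 4/6; precision (1/2 + 2/3 + 1)/3; recall (1/2 + 1 + 1/2)/3."""
        rep = metrics_from_confusion(confusion(TRUE, PRED, 3))
        assert rep.accuracy == pytest.approx(4 / 6)
        assert rep.macro_precision == pytest.approx((0.5 + 2 / 3 + 1.0) / 3)
        assert rep.macro_recall == pytest.approx((0.5 + 1.0 + 0.5) / 3)

    def test_diagonal_matrix_scores_one_everywhere(self):
        rep = metrics_from_confusion(ConfusionMatrix(np.diag([3, 4, 5])))
        assert rep.accuracy == rep.macro_precision == rep.macro_recall == 1.0

    def test_agrees_with_per_class_loop_oracle(self, rng):
        """Independent oracle: explicit one-vs-rest TP/FP/FN loops."""
        for _ in range(100):
            v = int(rng.integers(2, 8))
            n = int(rng.integers(5, 60))
            t = rng.integers(1, v + 1, n)
            p = rng.integers(1, v + 1, n)
            if len(np.unique(p)) < v:
                continue  # oracle below assumes every class predicted at least once
            rep = metrics_from_confusion(confusion(t, p, v))
            precs, recs = [], []
            for c in range(1, v + 1):
                tp = int(((t == c) & (p == c)).sum())
                fp = int(((t != c) & (p == c)).sum())
                fn = int(((t == c) & (p != c)).sum())
                precs.append(tp / (tp + fp) if tp + fp else 0.0)
                recs.append(tp / (tp + fn) if tp + fn else 0.0)
            assert rep.accuracy == pytest.approx(float((t == p).mean()))
            assert rep.macro_precision == pytest.approx(float(np.mean(precs)))
            assert rep.macro_recall == pytest.approx(float(np.mean(recs)))

    def test_equivariant_under_class_relabeling(self, rng):
        v = 5
        t = rng.integers(1, v + 1, 50)
        p = rng.integers(1, v + 1, 50)
        perm = rng.permutation(v) + 1
        rep = metrics_from_confusion(confusion(t, p, v))
        rep2 = metrics_from_confusion(confusion(perm[t - 1], perm[p - 1], v))
        assert rep.accuracy == pytest.approx(rep2.accuracy)
        assert rep.macro_precision == pytest.approx(rep2.macro_precision)
        assert rep.macro_recall == pytest.approx(rep2.macro_recall)

    def test_never_predicted_class_warns_and_zeroes_precision(self):
        with pytest.warns(UserWarning, match="never predicted"):
            rep = metrics_from_confusion(confusion([1, 2], [1, 1], 2))
        assert rep.per_class_precision[1] == 0.0

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            metrics_from_confusion(ConfusionMatrix(np.zeros((3, 3), dtype=int)))


class TestCrossEntropy:
    def test_uniform_probabilities_give_log_v(self):
        p = np.full((1, 30), 1 / 30)
        y = np.zeros((1, 30))
        y[0, 4] = 1.0
        assert cross_entropy(p, y) == pytest.approx(np.log(30), abs=1e-9)

    def test_certain_correct_prediction_has_zero_loss(self):
        p = np.zeros((2, 4))
        p[[0, 1], [1, 2]] = 1.0
        y = p.copy()
        assert cross_entropy(p, y) == pytest.approx(0.0, abs=1e-9)

    def test_matches_literal_double_sum_oracle(self, rng):
        p = rng.random((20, 6))
        p /= p.sum(axis=1, keepdims=True)
        labels = rng.integers(0, 6, 20)
        y = np.eye(6)[labels]
        total = 0.0
        for i in range(20):
            for c in range(6):
                total += y[i, c] * np.log(max(p[i, c], 1e-12))
        assert cross_entropy(p, y) == pytest.approx(-total / 20, abs=1e-10)

    def test_unnormalised_rows_rejected(self):
        with pytest.raises(ValidationError):
            cross_entropy(np.ones((2, 3)), np.eye(3)[:2])

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ShapeError):
            cross_entropy(np.full((2, 3), 1 / 3), np.eye(4)[:2])


class TestRunners:
    def test_empty_grid_returns_empty_frame(self, separable_table):
        train, test = split(separable_table, SplitSpec(rng_seed=0))
        df = run_grid(train, test, [PreprocessSpec(method="RAW")], {})
        assert len(df) == 0

    def test_grid_rows_cover_cells_and_failures_are_recorded(self, separable_table):
        train, test = split(separable_table, SplitSpec(rng_seed=0))
        grids = {"knn": [{"k": 1}, {"k": 10**6}], "elm": [{"n_hidden": 30}]}
        df = run_grid(train, test, [PreprocessSpec(method="RAW"),
                                    PreprocessSpec(method="D1")], grids, seed=0)
        assert len(df) == 6  # 2 preprocess x (2 knn + 1 elm)
        ok = df[df.error == ""]
        bad = df[df.error != ""]
        assert len(bad) == 2  # k too large fails in both preprocess branches
        assert (ok.accuracy >= 0).all() and (ok.accuracy <= 1).all()

    def test_rerun_with_same_seed_reproduces_accuracies(self, separable_table):
        train, test = split(separable_table, SplitSpec(rng_seed=0))
        grids = {"elm": [{"n_hidden": 30}], "rf": [{"n_trees": 20}]}
        a = run_grid(train, test, [PreprocessSpec(method="RAW")], grids, seed=3)
        b = run_grid(train, test, [PreprocessSpec(method="RAW")], grids, seed=3)
        assert np.array_equal(a.accuracy.to_numpy(), b.accuracy.to_numpy())

    def test_ablation_emits_the_four_variants_in_order(self, separable_table):
        train, test = split(separable_table, SplitSpec(rng_seed=0))
        df = run_ablation(
            train, test,
            base_params=dict(conv_channels=4, lstm_hidden=8, lstm_layers=1,
                             attn_heads=2, pool_width=4, epochs=1),
            seed=0,
        )
        assert df.model.tolist() == [
            "1DCNN", "1DCNN-LSTM", "1DCNN-LSTM-ATTENTION", "CLA-CA"
        ]
        assert df.n_parameters.is_monotonic_increasing
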