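"""Stratified splitting semantics and train-fitted normalization."""

from fractions import Fraction

import numpy as np
import pytest

from seedspectra.dataset import (
    NormalizationSpec,
    SpectrumTable,
    SplitSpec,
    fit_apply_normalization,
    split,
)
from seedspectra.errors import SplitError, ValidationError
from seedspectra.synth import SynthSpec, make_spectrum_table


def _balanced_table(n_classes, per_class, n_bands=8, seed=0):
    rng = np.random.default_rng(seed)
    n = n_classes * per_class
    return SpectrumTable(
        rng.random((n, n_bands)),
        np.repeat(np.arange(1, n_classes + 1), per_class),
        [f"V{i}" for i in range(1, n_classes + 1)],
        np.arange(n_bands, dtype=float),
    )


class TestSplit:
    def test_study_design_counts(self):
        """30 balanced classes of 90 at 4:1 give 2160/540 overall, 72/18 per class."""
        table = _balanced_table(30, 90)
        train, test = split(table, SplitSpec(rng_seed=0))
        assert (train.n_samples, test.n_samples) == (2160, 540)
        assert (train.class_counts() == 72).all()
        assert (test.class_counts() == 18).all()

    def test_single_class_of_ninety(self):
        train, test = split(_balanced_table(1, 90), SplitSpec(rng_seed=1))
        assert (train.n_samples, test.n_samples) == (72, 18)

    def test_ten_per_class_gives_eight_two(self):
        train, test = split(_balanced_table(4, 10), SplitSpec(rng_seed=2))
        assert (train.class_counts() == 8).all()
        assert (test.class_counts() == 2).all()

    def test_partition_is_disjoint_and_exhaustive(self):
        table = _balanced_table(5, 12, seed=3)
        train, test = split(table, SplitSpec(rng_seed=3))
        joined = np.vstack([train.spectra, test.spectra])
        assert joined.shape[0] == table.n_samples
        # every original row appears exactly once
        order = np.lexsort(joined.T)
        orig = np.lexsort(table.spectra.T)
        assert np.allclose(joined[order], table.spectra[orig])

    def test_same_seed_reproduces_partition(self):
        table = _balanced_table(5, 12)
        a = split(table, SplitSpec(rng_seed=9))
        b = split(table, SplitSpec(rng_seed=9))
        assert np.array_equal(a[0].spectra, b[0].spectra)
        assert np.array_equal(a[1].spectra, b[1].spectra)

    def test_tiny_class_rejected_under_stratification(self):
        table = _balanced_table(2, 1)
        with pytest.raises(SplitError):
            split(table, SplitSpec(rng_seed=0))

    def test_train_fraction_bounds_validated(self):
        with pytest.raises(ValidationError):
            SplitSpec(train_fraction=Fraction(5, 4))


class TestNormalization:
    def _tables(self):
        train = SpectrumTable(
            np.array([[2.0], [4.0], [6.0]]), np.array([1, 1, 2]), ["A", "B"], np.array([900.0])
        )
        test = SpectrumTable(
            np.array([[8.0]]), np.array([2]), ["A", "B"], np.array([900.0])
        )
        return train, test

    def test_minmax_maps_train_extremes_to_unit_interval(self):
        train, test = self._tables()
        tr, te, stats = fit_apply_normalization(train, test, NormalizationSpec("MINMAX"))
        assert np.allclose(tr.spectra[:, 0], [0.0, 0.5, 1.0])
        # test value above the train max follows the same affine map, unclipped
        assert te.spectra[0, 0] == pytest.approx((8.0 - 2.0) / 4.0)
        assert te.spectra[0, 0] > 1.0

    def test_standard_centres_train_features(self, small_table):
        train, test = small_table.take(np.arange(60)), small_table.take(np.arange(60, 80))
        tr, te, stats = fit_apply_normalization(train, test, NormalizationSpec("STANDARD"))
        assert np.abs(tr.spectra.mean(axis=0)).max() < 1e-9
        assert np.abs(tr.spectra.std(axis=0) - 1.0).max() < 1e-6

    def test_log_transform_is_monotone(self, rng):
        x = np.sort(rng.normal(size=20))[:, None]
        train = SpectrumTable(x, np.r_[np.ones(10, int), np.full(10, 2)],
                              ["A", "B"], np.array([900.0]))
        tr, _, _ = fit_apply_normalization(train, train, NormalizationSpec("LOG"))
        assert (np.diff(tr.spectra[:, 0]) > 0).all()

    def test_test_rows_never_influence_fitted_statistics(self, small_table, rng):
        train = small_table.take(np.arange(60))
        test_a = small_table.take(np.arange(60, 90))
        test_b = test_a.take(rng.permutation(test_a.n_samples))
        for method in ("STANDARD", "MINMAX", "LOG"):
            tr_a, _, stats_a = fit_apply_normalization(train, test_a, NormalizationSpec(method))
            tr_b, _, stats_b = fit_apply_normalization(train, test_b, NormalizationSpec(method))
            assert np.array_equal(tr_a.spectra, tr_b.spectra)
            for key in stats_a:
                if key != "method":
                    assert np.array_equal(stats_a[key], stats_b[key])

    def test_zero_variance_feature_guarded(self):
        train = SpectrumTable(np.ones((4, 2)), np.array([1, 1, 2, 2]), ["A", "B"],
                              np.array([900.0, 901.0]))
        with pytest.warns(UserWarning, match="zero-variance"):
            tr, _, _ = fit_apply_normalization(train, train, NormalizationSpec("STANDARD"))
        assert np.isfinite(tr.spectra).all()


class TestTableCsv:
    def test_round_trip(self, tmp_path, small_table):
        small_table.to_csv(tmp_path / "t.csv")
        back = SpectrumTable.from_csv(tmp_path / "t.csv")
        assert np.allclose(back.spectra, small_table.spectra)
        assert np.array_equal(back.labels, small_table.labels)
        assert np.allclose(back.wavelengths_nm, small_table.wavelengths_nm)


class TestReplicateHoldout:
    def test_holds_out_one_capture_per_variety(self):
        from seedspectra.dataset import split_by_replicate

        table = _balanced_table(5, 9)  # 3 replicates of 3 rows per class
        train, test = split_by_replicate(table, n_replicates=3, holdout=-1)
        assert (train.class_counts() == 6).all()
        assert (test.class_counts() == 3).all()
        # deterministic and exhaustive
        again = split_by_replicate(table, n_replicates=3, holdout=-1)
        assert np.array_equal(train.spectra, again[0].spectra)
        assert train.n_samples + test.n_samples == table.n_samples

    def test_uneven_replicates_rejected(self):
        from seedspectra.dataset import split_by_replicate
        from seedspectra.errors import SplitError

        with pytest.raises(SplitError):
            split_by_replicate(_balanced_table(2, 10), n_replicates=3)
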