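"""Labeled spectral tables, stratified splitting and feature normalization.

The central exchange object is :class:`SpectrumTable`: an ``N x B`` matrix of
per-seed reflectance spectra with integer variety labels, variety names and a
wavelength axis.  Everything downstream (preprocessing, classical models, the
deep network, reports) consumes and produces this container.

Splitting follows the single stratified 4:1 train/test partition used
throughout: per class, floor(n_class * train_fraction) rows go to training,
the remainder to test, with a seeded shuffle.  Normalization statistics are
always fitted on training rows only and applied unchanged to test rows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .errors import SplitError, ValidationError

__all__ = [
    "SpectrumTable",
    "SplitSpec",
    "NormalizationSpec",
    "split",
    "split_by_replicate",
    "fit_apply_normalization",
]

_EPS_VAR = 1e-12


@dataclass
class SpectrumTable:
    """N spectra x B bands with integer labels in ``1..V``.

    Parameters
    ----------
    spectra
        ``(N, B)`` float array, unitless (reflectance or a transform of it).
    labels
        ``(N,)`` integer array with values in ``1..V``.
    variety_names
        One name per variety id, index ``v - 1`` names variety ``v``.
    wavelengths_nm
        ``(B,)`` strictly ascending wavelength axis in nanometres.
    """

    spectra: np.ndarray
    labels: np.ndarray
    variety_names: list[str]
    wavelengths_nm: np.ndarray

    def __post_init__(self) -> None:
        self.spectra = np.asarray(self.spectra, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        if self.spectra.ndim != 2:
            raise ValidationError("spectra must be a 2-D (N, B) array")
        n, b = self.spectra.shape
        if self.labels.shape != (n,):
            raise ValidationError("labels length must equal number of spectra")
        if self.wavelengths_nm.shape != (b,):
            raise ValidationError("wavelengths length must equal band count")
        if n and (self.labels.min() < 1 or self.labels.max() > len(self.variety_names)):
            raise ValidationError("labels must lie in 1..len(variety_names)")

    # -- basic geometry ----------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.spectra.shape[0]

    @property
    def n_bands(self) -> int:
        return self.spectra.shape[1]

    @property
    def n_varieties(self) -> int:
        return len(self.variety_names)

    def class_counts(self) -> np.ndarray:
        """Number of rows per variety id (length V)."""
        return np.bincount(self.labels, minlength=self.n_varieties + 1)[1:]

    def take(self, idx: np.ndarray) -> "SpectrumTable":
        """Row subset, preserving variety names and wavelengths."""
        return SpectrumTable(
            self.spectra[idx], self.labels[idx], list(self.variety_names), self.wavelengths_nm
        )

    def with_spectra(self, spectra: np.ndarray) -> "SpectrumTable":
        """Same labels/axis, new values (used by preprocessing/normalization)."""
        return SpectrumTable(spectra, self.labels.copy(), list(self.variety_names), self.wavelengths_nm)

    # -- CSV dialect -------------------------------------------------------
    def to_csv(self, path: Union[str, Path]) -> None:
        """Write the shared CSV dialect: label, variety_name, one column per band."""
        cols = {"label": self.labels, "variety_name": [self.variety_names[l - 1] for l in self.labels]}
        frame = pd.DataFrame(cols)
        band_cols = pd.DataFrame(self.spectra, columns=[f"{w:.4f}" for w in self.wavelengths_nm])
        pd.concat([frame, band_cols], axis=1).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: Union[str, Path]) -> "SpectrumTable":
        frame = pd.read_csv(path)
        if "label" not in frame.columns or "variety_name" not in frame.columns:
            raise ValidationError("table CSV must have 'label' and 'variety_name' columns")
        band_cols = [c for c in frame.columns if c not in ("label", "variety_name")]
        wavelengths = np.array([float(c) for c in band_cols])
        labels = frame["label"].to_numpy(dtype=int)
        v = int(labels.max()) if len(labels) else 0
        names = [""] * v
        for lab, name in zip(labels, frame["variety_name"]):
            names[lab - 1] = str(name)
        names = [n if n else f"V{i+1:02d}" for i, n in enumerate(names)]
        return cls(frame[band_cols].to_numpy(dtype=float), labels, names, wavelengths)


@dataclass(frozen=True)
class SplitSpec:
    """Train/test partition description (default: stratified 4:1)."""

    train_fraction: Fraction = Fraction(4, 5)
    stratified: bool = True
    rng_seed: int = 0

    def __post_init__(self) -> None:
        frac = Fraction(self.train_fraction)
        object.__setattr__(self, "train_fraction", frac)
        if not (0 < frac < 1):
            raise ValidationError("train_fraction must lie strictly between 0 and 1")


@dataclass(frozen=True)
class NormalizationSpec:
    """Feature scaling fitted on the training rows only.

    ``STANDARD`` mean-centres to unit variance, ``MINMAX`` maps training
    extremes to [0, 1], ``LOG`` applies ``log(x - train_min + 1)`` (monotone,
    tolerant of the negative values derivative spectra produce), ``NONE`` is
    the identity.
    """

    method: str = "NONE"

    def __post_init__(self) -> None:
        if self.method not in ("NONE", "STANDARD", "MINMAX", "LOG"):
            raise ValidationError(f"unknown normalization method {self.method!r}")


def split(table: SpectrumTable, spec: SplitSpec) -> tuple[SpectrumTable, SpectrumTable]:
    """Disjoint, exhaustive train/test partition, reproducible from the seed.

    Under stratification each class contributes ``floor(n_class * fraction)``
    training rows; without it the whole index set is shuffled and cut at
    ``floor(N * fraction)``.
    """
    rng = np.random.default_rng(spec.rng_seed)
    frac = spec.train_fraction
    n = table.n_samples
    if n == 0:
        raise SplitError("cannot split an empty table")
    if spec.stratified:
        train_idx, test_idx = [], []
        for lab in np.unique(table.labels):
            rows = np.flatnonzero(table.labels == lab)
            if len(rows) < 2:
                raise SplitError(f"class {lab} has {len(rows)} member(s); stratified split needs >= 2")
            rows = rng.permutation(rows)
            k = int(len(rows) * frac.numerator // frac.denominator)
            k = min(max(k, 1), len(rows) - 1)  # keep both sides non-empty per class
            train_idx.append(rows[:k])
            test_idx.append(rows[k:])
        train_idx = np.sort(np.concatenate(train_idx))
        test_idx = np.sort(np.concatenate(test_idx))
    else:
        perm = rng.permutation(n)
        k = int(n * frac.numerator // frac.denominator)
        train_idx = np.sort(perm[:k])
        test_idx = np.sort(perm[k:])
    return table.take(train_idx), table.take(test_idx)


def split_by_replicate(
    table: SpectrumTable, n_replicates: int = 3, holdout: int = -1
) -> tuple[SpectrumTable, SpectrumTable]:
    """Hold out one acquisition replicate (capture) per variety.

    Stricter alternative to the random stratified split: rows within each
    variety are assumed ordered by capture, in equal consecutive blocks (as
    the acquisition front end emits them); the ``holdout`` block (default:
    the last) of every variety forms the test set.  Deterministic.
    """
    if n_replicates < 2:
        raise SplitError("need at least 2 replicates to hold one out")
    holdout = holdout % n_replicates
    train_idx, test_idx = [], []
    for lab in np.unique(table.labels):
        rows = np.flatnonzero(table.labels == lab)
        if len(rows) % n_replicates:
            raise SplitError(
                f"class {lab} has {len(rows)} rows, not a multiple of {n_replicates}"
            )
        block = len(rows) // n_replicates
        test = rows[holdout * block : (holdout + 1) * block]
        train = np.setdiff1d(rows, test)
        train_idx.append(train)
        test_idx.append(test)
    return (
        table.take(np.sort(np.concatenate(train_idx))),
        table.take(np.sort(np.concatenate(test_idx))),
    )


def fit_apply_normalization(
    train: SpectrumTable,
    test: SpectrumTable,
    spec: NormalizationSpec,
) -> tuple[SpectrumTable, SpectrumTable, dict]:
    """Fit per-feature statistics on ``train`` and apply them to both tables.

    Returns the transformed tables plus the fitted statistics.  Test values
    outside the training range are transformed with the same affine/log map
    and are deliberately not clipped.
    """
    if train.n_samples == 0:
        raise ValidationError("training table is empty")
    x = train.spectra
    if spec.method == "NONE":
        stats: dict = {"method": "NONE"}
        return train.with_spectra(x.copy()), test.with_spectra(test.spectra.copy()), stats
    if spec.method == "STANDARD":
        mean = x.mean(axis=0)
        var = x.var(axis=0)
        n_zero = int((var < _EPS_VAR).sum())
        if n_zero:
            warnings.warn(f"{n_zero} zero-variance feature(s) under STANDARD; guarded by epsilon")
        sd = np.sqrt(np.maximum(var, _EPS_VAR))
        stats = {"method": "STANDARD", "mean": mean, "sd": sd}
        f = lambda a: (a - mean) / sd
    elif spec.method == "MINMAX":
        lo = x.min(axis=0)
        hi = x.max(axis=0)
        span = np.maximum(hi - lo, _EPS_VAR)
        stats = {"method": "MINMAX", "min": lo, "max": hi}
        f = lambda a: (a - lo) / span
    else:  # LOG
        lo = x.min(axis=0)
        stats = {"method": "LOG", "min": lo}
        f = lambda a: np.log(np.maximum(a - lo + 1.0, _EPS_VAR))
    return train.with_spectra(f(x)), test.with_spectra(f(test.spectra)), stats
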