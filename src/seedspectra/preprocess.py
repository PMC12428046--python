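"""Spectral preprocessing operators.

Seven row-wise operators on spectra, all band-count preserving and free of
randomness:

``RAW``   identity
``D1``    first derivative: central differences with one-sided edges, unit
          band spacing (``numpy.gradient`` convention)
``D2``    second derivative, implemented as ``D1`` applied twice
``SG``    Savitzky–Golay polynomial smoothing (polynomial edge fit, so
          polynomials up to the fit order are reproduced exactly everywhere)
``GF``    Gaussian filter of a given sigma in band units
``MF``    median filter
``MA``    moving average

Smoothing windows default to common chemometrics choices (window 5,
polynomial order 2, Gaussian sigma 2 bands); all are overridable.  MF/MA/GF
use reflect padding so the output length equals the input length.

Derivatives remove exactly the additive baseline offsets (D1) and linear
baseline drift (D2) that scatter between seed surfaces introduces, which is
why they help classification downstream.  A Savitzky–Golay derivative is
available as a configurable alternative to plain differences
(``PreprocessSpec(method="SG", sg_deriv=1)``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d, median_filter, uniform_filter1d
from scipy.signal import savgol_filter

from .dataset import SpectrumTable
from .errors import ValidationError

__all__ = ["PreprocessSpec", "apply_preprocess", "METHODS"]

METHODS = ("RAW", "D1", "D2", "SG", "GF", "MF", "MA")


@dataclass(frozen=True)
class PreprocessSpec:
    """Declarative choice of one preprocessing operator with its parameters."""

    method: str = "RAW"
    window: int = 5
    polyorder: int = 2
    sigma_bands: float = 2.0
    sg_deriv: int = 0

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValidationError(f"unknown method {self.method!r}; choose from {METHODS}")
        if self.method in ("SG", "MF", "MA"):
            if self.window < 3 or self.window % 2 == 0:
                raise ValidationError("window must be an odd integer >= 3")
        if self.method == "SG":
            if not (0 <= self.polyorder < self.window):
                raise ValidationError("polyorder must satisfy 0 <= polyorder < window")
            if not (0 <= self.sg_deriv <= self.polyorder):
                raise ValidationError("sg_deriv must satisfy 0 <= sg_deriv <= polyorder")
        if self.method == "GF" and self.sigma_bands <= 0:
            raise ValidationError("sigma_bands must be positive")


def _transform(x: np.ndarray, spec: PreprocessSpec) -> np.ndarray:
    if spec.method == "RAW":
        return x.copy()
    if spec.method == "D1":
        return np.gradient(x, axis=1)
    if spec.method == "D2":
        return np.gradient(np.gradient(x, axis=1), axis=1)
    if spec.method == "SG":
        return savgol_filter(x, spec.window, spec.polyorder, deriv=spec.sg_deriv, axis=1, mode="interp")
    if spec.method == "GF":
        return gaussian_filter1d(x, spec.sigma_bands, axis=1, mode="reflect")
    if spec.method == "MF":
        return median_filter(x, size=(1, spec.window), mode="reflect")
    # MA
    return uniform_filter1d(x, spec.window, axis=1, mode="reflect")


def apply_preprocess(table: SpectrumTable, spec: PreprocessSpec) -> SpectrumTable:
    """Row-wise transform; labels and wavelengths carried through unchanged."""
    if spec.method in ("SG", "MF", "MA") and spec.window >= table.n_bands:
        raise ValidationError(
            f"window {spec.window} must be smaller than the band count {table.n_bands}"
        )
    if spec.method in ("D1", "D2") and table.n_bands < 2:
        raise ValidationError("derivatives need at least 2 bands")
    return table.with_spectra(_transform(table.spectra, spec))
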