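"""Synthetic hyperspectral seed data with a controllable separability dial.

Real NIR reflectance curves of seeds are smooth, with broad absorption
features, and differ between varieties by small shape changes superimposed on
a large shared envelope.  The generator models a variety template as

    T_v(lambda) = baseline + sum_j a_j * exp(-0.5 ((lambda - c_j) / w_j)^2)

where a fixed set of *shared* bumps forms the species-level envelope and a
per-variety set of bumps, scaled by the separability dial ``delta``, encodes
the varietal signature.  ``delta = 0`` makes all templates identical (a pure
no-signal control); inter-template L2 distance grows exactly linearly in
``delta``.

Individual seed spectra are ``gain * T_v + offset + noise`` with a
multiplicative scatter gain, an additive baseline offset, and i.i.d. per-band
noise — precisely the artifact families derivative preprocessing is meant to
remove.  Full camera scenes encode a reflectance field back into digital
numbers via ``dn = dark + R * (white - dark)`` so the whole
calibrate/segment/extract front end can be exercised end to end.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .cube_io import ReferencePair, SpectralCube
from .dataset import SpectrumTable
from .errors import LayoutError, ValidationError

__all__ = [
    "VarietyTemplate",
    "SynthSpec",
    "CubeScene",
    "make_templates",
    "make_spectrum_table",
    "make_cube_scene",
    "DEFAULT_VARIETY_NAMES",
]

# Variety codes used for default labelling (index i names variety i+1).
DEFAULT_VARIETY_NAMES = [
    "ZASY688", "ZSASQ66", "ZSALXQ518", "ZQBSY438", "ZSPY128", "ZAQF216",
    "ZBHT526", "ZBJL6", "GBJH25", "ZJNY516", "GMBSB1259", "ZBQF218",
    "QAGNY599", "JBL3712", "JAM1910", "ZSDTY71110", "ZAQKY918", "GADF1908",
    "JAGNY168", "ZBNF7019", "ZHAXY99", "ZHBP220", "ZSBJYY1207", "ZSAZT2208",
    "QBFLQC2", "JAC1219", "QBFY166", "ZAZD1568", "ZSBZT2209", "QBFLQC5",
]

# Shared species-level envelope: a handful of broad features on a mid-range
# baseline, chosen so every template stays well inside (0, 1).
_SHARED_BASELINE = 0.45
_SHARED_CENTERS = (950.0, 1200.0, 1450.0, 1650.0)
_SHARED_WIDTHS = (80.0, 180.0, 60.0, 90.0)
_SHARED_AMPS = (0.05, 0.15, -0.12, 0.06)


def variety_names_for(n: int) -> list[str]:
    names = list(DEFAULT_VARIETY_NAMES[:n])
    names += [f"SYNV{i + 1:03d}" for i in range(len(names), n)]
    return names


@dataclass(frozen=True)
class VarietyTemplate:
    """Sum-of-Gaussian-bumps reflectance template for one variety."""

    variety_id: int
    centers: tuple[float, ...]
    widths: tuple[float, ...]
    amplitudes: tuple[float, ...]
    baseline: float

    def __post_init__(self) -> None:
        if self.variety_id < 1:
            raise ValidationError("variety_id must be >= 1")
        if not (len(self.centers) == len(self.widths) == len(self.amplitudes)):
            raise ValidationError("centers, widths and amplitudes must have equal length")
        if any(w <= 0 for w in self.widths):
            raise ValidationError("all bump widths must be positive")

    def evaluate(self, wavelengths_nm: np.ndarray) -> np.ndarray:
        """Template reflectance on the wavelength grid."""
        wl = np.asarray(wavelengths_nm, dtype=float)
        curve = np.full_like(wl, self.baseline)
        for c, w, a in zip(self.centers, self.widths, self.amplitudes):
            curve += a * np.exp(-0.5 * ((wl - c) / w) ** 2)
        return curve


@dataclass(frozen=True)
class SynthSpec:
    """Study conditions for the generator.

    Defaults mirror the acquisition design this package emulates: 30
    varieties x 90 seeds x 512 bands over 870–1709 nm.  ``separability``
    scales the varietal signature (0 = no signal); the three noise scales are
    the sd of the multiplicative scatter gain, of the additive baseline
    offset, and of the per-band white noise, all in reflectance units.
    """

    n_varieties: int = 30
    seeds_per_variety: int = 90
    n_bands: int = 512
    wavelength_range: tuple[float, float] = (870.0, 1709.0)
    separability: float = 1.0
    scatter_sd: float = 0.05
    offset_sd: float = 0.02
    noise_sd: float = 0.005
    rng_seed: int = 0
    bumps_per_variety: int = 8
    bump_amp_sd: float = 0.03

    def __post_init__(self) -> None:
        if min(self.n_varieties, self.seeds_per_variety, self.n_bands) < 1:
            raise ValidationError("all counts must be >= 1")
        if self.wavelength_range[0] >= self.wavelength_range[1]:
            raise ValidationError("wavelength_range must be ascending")
        if self.separability < 0:
            raise ValidationError("separability must be >= 0")
        if min(self.scatter_sd, self.offset_sd, self.noise_sd) < 0:
            raise ValidationError("all noise sds must be >= 0")
        if self.bumps_per_variety < 1 or self.bump_amp_sd < 0:
            raise ValidationError("bump parameters out of range")

    @property
    def wavelengths_nm(self) -> np.ndarray:
        lo, hi = self.wavelength_range
        return np.linspace(lo, hi, self.n_bands)


def make_templates(spec: SynthSpec) -> list[VarietyTemplate]:
    """Draw one template per variety, reproducibly from ``spec.rng_seed``.

    Every template shares the species envelope; variety-specific bumps have
    amplitudes scaled by ``spec.separability``, so ``separability = 0``
    yields element-wise identical templates and inter-template distances are
    exactly linear in the dial.
    """
    rng = np.random.default_rng([spec.rng_seed, 0])
    lo, hi = spec.wavelength_range
    wl = spec.wavelengths_nm
    templates = []
    for v in range(1, spec.n_varieties + 1):
        centers = rng.uniform(lo, hi, spec.bumps_per_variety)
        widths = rng.uniform(30.0, 120.0, spec.bumps_per_variety)
        amps = rng.normal(0.0, spec.bump_amp_sd, spec.bumps_per_variety) * spec.separability
        t = VarietyTemplate(
            variety_id=v,
            centers=_SHARED_CENTERS + tuple(centers),
            widths=_SHARED_WIDTHS + tuple(widths),
            amplitudes=_SHARED_AMPS + tuple(amps),
            baseline=_SHARED_BASELINE,
        )
        curve = t.evaluate(wl)
        if curve.min() <= 0.0 or curve.max() >= 1.0:
            raise ValidationError(
                "template leaves (0, 1); lower separability or bump_amp_sd"
            )
        templates.append(t)
    return templates


def make_spectrum_table(spec: SynthSpec) -> SpectrumTable:
    """(n_varieties * seeds_per_variety) x n_bands table with balanced labels.

    Row i of variety v is ``gain * T_v + offset + noise`` with
    ``gain ~ N(1, scatter_sd)``, ``offset ~ N(0, offset_sd)`` and per-band
    i.i.d. ``N(0, noise_sd)`` noise.
    """
    templates = make_templates(spec)
    wl = spec.wavelengths_nm
    curves = np.stack([t.evaluate(wl) for t in templates])
    rng = np.random.default_rng([spec.rng_seed, 1])
    n = spec.n_varieties * spec.seeds_per_variety
    spectra = np.empty((n, spec.n_bands))
    labels = np.empty(n, dtype=int)
    row = 0
    for v in range(spec.n_varieties):
        gains = rng.normal(1.0, spec.scatter_sd, spec.seeds_per_variety)
        offsets = rng.normal(0.0, spec.offset_sd, spec.seeds_per_variety)
        noise = rng.normal(0.0, spec.noise_sd, (spec.seeds_per_variety, spec.n_bands))
        block = gains[:, None] * curves[v] + offsets[:, None] + noise
        spectra[row : row + spec.seeds_per_variety] = block
        labels[row : row + spec.seeds_per_variety] = v + 1
        row += spec.seeds_per_variety
    return SpectrumTable(spectra, labels, variety_names_for(spec.n_varieties), wl)


@dataclass
class CubeScene:
    """One synthetic camera capture plus its generation ground truth."""

    raw: SpectralCube
    white: SpectralCube
    dark: SpectralCube
    masks: np.ndarray  # (rows, cols) int; 0 background, 1..n seeds in grid order
    seed_spectra: np.ndarray  # (n_seeds, bands): noise-free per-seed reflectance
    reflectance_field: np.ndarray  # (rows, cols, bands): encoded reflectance

    @property
    def references(self) -> ReferencePair:
        return ReferencePair(white=self.white, dark=self.dark)


def make_cube_scene(
    spec: SynthSpec,
    grid_rows: int = 5,
    grid_cols: int = 6,
    variety: int = 1,
    capture: int = 0,
    cell_px: int = 16,
    margin_px: int = 8,
    seed_radii: tuple[float, float] = (6.0, 5.0),
    background_reflectance: float = 0.05,
    white_dn: float = 12000.0,
    dark_dn: float = 800.0,
    frame_shape: Optional[tuple[int, int]] = None,
) -> CubeScene:
    """Synthesize one push-broom capture of a grid of same-variety seeds.

    Seeds of ``variety`` are laid out as ``grid_rows x grid_cols`` ellipses on
    a dark background; each seed carries its own scatter gain and baseline
    offset, with per-pixel band noise on top.  The raw cube holds digital
    numbers ``dn = dark + R * (white - dark)``; white and dark references are
    single line frames to be broadcast by :func:`seedspectra.cube_io.calibrate`.
    """
    n_seeds = grid_rows * grid_cols
    if n_seeds > spec.seeds_per_variety:
        raise ValidationError(
            f"grid requests {n_seeds} seeds; only {spec.seeds_per_variety} per variety"
        )
    if not (1 <= variety <= spec.n_varieties):
        raise ValidationError(f"variety {variety} outside 1..{spec.n_varieties}")
    if 2 * max(seed_radii) >= cell_px:
        raise LayoutError("seed ellipse does not fit in its grid cell")
    rows = grid_rows * cell_px + 2 * margin_px
    cols = grid_cols * cell_px + 2 * margin_px
    if frame_shape is not None:
        if frame_shape[0] < rows or frame_shape[1] < cols:
            raise LayoutError(f"grid needs a {rows}x{cols} frame; got {frame_shape}")
        rows, cols = frame_shape

    wl = spec.wavelengths_nm
    template = make_templates(spec)[variety - 1].evaluate(wl)
    rng = np.random.default_rng([spec.rng_seed, 2, variety, capture])

    masks = np.zeros((rows, cols), dtype=int)
    field = np.full((rows, cols, spec.n_bands), background_reflectance, dtype=np.float64)
    seed_spectra = np.empty((n_seeds, spec.n_bands))
    rr, cc = np.mgrid[0:rows, 0:cols]
    sid = 0
    for gr in range(grid_rows):
        for gc in range(grid_cols):
            cy = margin_px + gr * cell_px + cell_px / 2 - 0.5
            cx = margin_px + gc * cell_px + cell_px / 2 - 0.5
            gain = rng.normal(1.0, spec.scatter_sd)
            offset = rng.normal(0.0, spec.offset_sd)
            spectrum = gain * template + offset
            seed_spectra[sid] = spectrum
            inside = ((rr - cy) / seed_radii[0]) ** 2 + ((cc - cx) / seed_radii[1]) ** 2 <= 1.0
            masks[inside] = sid + 1
            field[inside] = spectrum
            sid += 1
    if spec.noise_sd > 0:
        field += rng.normal(0.0, spec.noise_sd, field.shape)

    dn = dark_dn + field * (white_dn - dark_dn)
    raw = SpectralCube(dn.astype(np.float32), wl, interleave="bil", dtype_code=4, kind="raw")
    white = SpectralCube(
        np.full((1, cols, spec.n_bands), white_dn, dtype=np.float32), wl,
        interleave="bil", dtype_code=4, kind="white",
    )
    dark = SpectralCube(
        np.full((1, cols, spec.n_bands), dark_dn, dtype=np.float32), wl,
        interleave="bil", dtype_code=4, kind="dark",
    )
    return CubeScene(raw, white, dark, masks, seed_spectra, field)
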