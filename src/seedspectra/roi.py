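"""Seed segmentation and per-seed mean-spectrum extraction.

Seeds are bright against the dark scene background in the band-mean
reflectance image, so segmentation is a global threshold (Otsu by default, or
a fixed reflectance value) followed by 4-connected component labelling and an
area filter.  Components are then ordered into grid positions: centroid rows
are clustered with a 1-D gap heuristic into grid rows, and sorted by column
within each row.

The region of interest is the whole seed footprint; one spectrum per seed is
the unweighted per-band mean over the region's pixels.  Discriminating the
embryo face from the endosperm automatically is out of reach of a threshold
segmenter and is documented as a limitation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .cube_io import SpectralCube
from .dataset import SpectrumTable
from .errors import ValidationError
from .synth import variety_names_for

__all__ = ["SeedRegion", "segment_seeds", "extract_spectra"]

_FOUR_CONNECTED = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])


@dataclass
class SeedRegion:
    """One segmented seed: pixel set, centroid and assigned grid position."""

    pixel_set: list[tuple[int, int]]
    centroid: tuple[float, float]
    grid_pos: tuple[int, int]
    area_px: int

    def __post_init__(self) -> None:
        if not self.pixel_set:
            raise ValidationError("pixel_set must be non-empty")
        if self.area_px != len(self.pixel_set):
            raise ValidationError("area_px must equal |pixel_set|")


def _cluster_rows(centroids: np.ndarray, areas: np.ndarray) -> np.ndarray:
    """Assign a grid-row index to each centroid via a 1-D gap heuristic.

    Sorted centroid row coordinates are split wherever the gap to the next
    centroid exceeds 1.5x the median seed diameter proxy sqrt(area): gaps
    within a physical grid row are a few pixels, gaps between rows are of the
    order of the cell pitch.
    """
    order = np.argsort(centroids[:, 0])
    gap_threshold = 1.5 * float(np.median(np.sqrt(areas)))
    row_idx = np.empty(len(centroids), dtype=int)
    current = 0
    prev = None
    for i in order:
        r = centroids[i, 0]
        if prev is not None and r - prev > gap_threshold:
            current += 1
        row_idx[i] = current
        prev = r
    return row_idx


def segment_seeds(
    cube: SpectralCube,
    threshold: Union[float, str] = "otsu",
    min_area: int = 20,
    max_area: int = 100_000,
) -> list[SeedRegion]:
    """Threshold the band-mean image and return seeds in row-major grid order."""
    if cube.kind != "reflectance":
        raise ValidationError("segment_seeds expects a reflectance cube")
    mean_img = cube.data.mean(axis=2)
    if threshold == "otsu":
        if np.ptp(mean_img) == 0:
            return []
        # Otsu's histogram threshold can land inside a very narrow background
        # peak (band-averaging makes background noise tiny); refine it to the
        # midpoint of the two class means (isodata iteration) so the cut sits
        # between the clusters rather than inside one.
        thr = float(threshold_otsu(mean_img))
        for _ in range(10):
            lo = mean_img[mean_img <= thr]
            hi = mean_img[mean_img > thr]
            if lo.size == 0 or hi.size == 0:
                break
            new = 0.5 * (float(lo.mean()) + float(hi.mean()))
            if abs(new - thr) < 1e-9:
                break
            thr = new
    else:
        thr = float(threshold)
        if not (0.0 < thr < 1.0):
            raise ValidationError("fixed threshold must lie in (0, 1)")
    binary = mean_img > thr
    labelled, n = ndimage.label(binary, structure=_FOUR_CONNECTED)
    if n == 0:
        warnings.warn("no regions found above threshold; returning empty list")
        return []
    areas = ndimage.sum_labels(np.ones_like(labelled), labelled, index=np.arange(1, n + 1))
    keep = [i + 1 for i in range(n) if min_area <= areas[i] <= max_area]
    if not keep:
        warnings.warn("all regions fell outside the area window; returning empty list")
        return []
    centroids = np.array(ndimage.center_of_mass(binary, labelled, keep))
    kept_areas = areas[np.array(keep) - 1]

    row_idx = _cluster_rows(centroids, kept_areas)
    regions: list[SeedRegion] = []
    # Row-major ordering: by grid row, then centroid column (ties by column index).
    order = np.lexsort((centroids[:, 1], row_idx))
    row_lengths = np.bincount(row_idx)
    if len(set(row_lengths.tolist())) > 1:
        warnings.warn(f"ragged grid layout: row lengths {row_lengths.tolist()}")
    col_counter: dict[int, int] = {}
    for i in order:
        lab = keep[i]
        r = int(row_idx[i])
        pos = (r, col_counter.get(r, 0))
        col_counter[r] = pos[1] + 1
        pixels = np.argwhere(labelled == lab)
        regions.append(
            SeedRegion(
                pixel_set=[(int(r), int(c)) for r, c in pixels],
                centroid=(float(centroids[i, 0]), float(centroids[i, 1])),
                grid_pos=pos,
                area_px=int(kept_areas[i]),
            )
        )
    return regions


def extract_spectra(
    cube: SpectralCube,
    regions: list[SeedRegion],
    label: int = 1,
    variety_names: Optional[list[str]] = None,
) -> SpectrumTable:
    """One row per region: the unweighted mean spectrum over its pixel set.

    Rows follow the regions' grid order.  All rows carry ``label`` (a scene
    images a single variety); pass the scene's variety id when assembling a
    multi-variety table.
    """
    rows, cols, _ = cube.shape
    spectra = np.empty((len(regions), cube.shape[2]))
    for i, region in enumerate(regions):
        coords = np.asarray(region.pixel_set)
        if coords.min() < 0 or coords[:, 0].max() >= rows or coords[:, 1].max() >= cols:
            raise IndexError(f"region {i} has pixels outside the cube frame")
        spectra[i] = cube.data[coords[:, 0], coords[:, 1], :].mean(axis=0)
    names = variety_names or variety_names_for(label)
    labels = np.full(len(regions), label, dtype=int)
    return SpectrumTable(spectra, labels, names, cube.wavelengths_nm.copy())


def export_regions_csv(regions: list[SeedRegion], path: Union[str, Path]) -> None:
    """Write labelled pixel coordinates (seed_index, grid_row, grid_col, row, col)."""
    import pandas as pd

    records = [
        (i + 1, *region.grid_pos, r, c)
        for i, region in enumerate(regions)
        for r, c in region.pixel_set
    ]
    pd.DataFrame(
        records, columns=["seed_index", "grid_row", "grid_col", "row", "col"]
    ).to_csv(path, index=False)


def label_mask(regions: list[SeedRegion], shape: tuple[int, int]) -> np.ndarray:
    """Integer label image (0 background, i+1 per region) for PNG export."""
    mask = np.zeros(shape, dtype=np.uint16)
    for i, region in enumerate(regions):
        for r, c in region.pixel_set:
            mask[r, c] = i + 1
    return mask
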