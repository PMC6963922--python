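"""Per-fruit ROI extraction: single-band binarization + connected components."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import measure
from skimage.filters import threshold_otsu

from .cube import Hypercube
from .errors import (
    DegenerateImageError,
    EmptySceneError,
    ShapeMismatchError,
)

SEGMENTATION_WAVELENGTH_NM = 1119.0
DEFAULT_MIN_AREA = 30


@dataclass
class ROISet:
    """Labelled fruit regions from one scene."""

    label_image: np.ndarray
    fruit_ids: list[int]
    band_used_nm: float

    def mask(self, fruit_id: int) -> np.ndarray:
        return self.label_image == fruit_id

    def area(self, fruit_id: int) -> int:
        return int(np.count_nonzero(self.label_image == fruit_id))


@dataclass
class PixelSpectra:
    """All pixel spectra belonging to one fruit, rows in raster order."""

    fruit_id: int
    matrix: np.ndarray  # pixels x bands


def band_image(cube: Hypercube, wavelength_nm: float) -> tuple[np.ndarray, int]:
    """Gray-scale image of the band nearest ``wavelength_nm`` plus its index."""
    idx = cube.axis.nearest(wavelength_nm)
    return cube.data[:, :, idx], idx


def binarize(
    gray: np.ndarray,
    method: str = "otsu",
    threshold: float | None = None,
) -> np.ndarray:
    """Foreground mask: 1 where ``gray >= threshold``.

    ``method='otsu'`` picks the threshold automatically and refuses constant
    images; ``method='fixed'`` uses the given ``threshold``.
    """
    gray = np.asarray(gray, dtype=float)
    if not np.all(np.isfinite(gray)):
        raise ValueError("image contains non-finite values")
    if method == "fixed":
        if threshold is None:
            raise ValueError("fixed method requires a threshold")
        t = float(threshold)
    elif method == "otsu":
        if np.ptp(gray) == 0.0:
            raise DegenerateImageError("cannot auto-threshold a constant image")
        t = float(threshold_otsu(gray))
    else:
        raise ValueError(f"unknown binarization method {method!r}")
    return gray >= t


def label_fruits(mask: np.ndarray, min_area: int = DEFAULT_MIN_AREA) -> ROISet:
    """8-connected components of ``mask``, small specks dropped.

    Surviving components are relabelled 1..K in raster order of their first
    pixel.  Raises :class:`EmptySceneError` when nothing survives.
    """
    mask = np.asarray(mask).astype(bool)
    raw_labels = measure.label(mask, connectivity=2)
    flat = raw_labels.ravel()
    ids, first_idx, counts = np.unique(flat, return_index=True, return_counts=True)
    keep = [(fi, i) for i, fi, c in zip(ids, first_idx, counts) if i != 0 and c >= min_area]
    if not keep:
        raise EmptySceneError(
            f"no connected component with >= {min_area} px found"
        )
    keep.sort()  # raster order of first pixel
    relabel = np.zeros(int(ids.max()) + 1, dtype=np.int32)
    for new_id, (_, old_id) in enumerate(keep, start=1):
        relabel[old_id] = new_id
    label_image = relabel[raw_labels]
    return ROISet(
        label_image=label_image,
        fruit_ids=list(range(1, len(keep) + 1)),
        band_used_nm=float("nan"),
    )


def segment_scene(
    cube: Hypercube,
    wavelength_nm: float = SEGMENTATION_WAVELENGTH_NM,
    min_area: int = DEFAULT_MIN_AREA,
    method: str = "otsu",
    threshold: float | None = None,
) -> ROISet:
    """Full segmentation: band image -> binarize -> label."""
    gray, _ = band_image(cube, wavelength_nm)
    mask = binarize(gray, method=method, threshold=threshold)
    roiset = label_fruits(mask, min_area=min_area)
    roiset.band_used_nm = float(wavelength_nm)
    return roiset


def extract_pixel_spectra(cube: Hypercube, roiset: ROISet) -> list[PixelSpectra]:
    """Reflectance rows for every fruit, background excluded."""
    if cube.kind != "reflectance":
        raise ValueError("extract_pixel_spectra expects a reflectance cube")
    if cube.data.shape[:2] != roiset.label_image.shape:
        raise ShapeMismatchError(
            f"cube spatial shape {cube.data.shape[:2]} != label image shape "
            f"{roiset.label_image.shape}"
        )
    out = []
    for fid in roiset.fruit_ids:
        rows = cube.data[roiset.label_image == fid]
        out.append(PixelSpectra(fruit_id=fid, matrix=rows))
    return out


def match_origins(roiset: ROISet, truth_label_image: np.ndarray, fruit_origins: dict[int, int]) -> dict[int, int]:
    """Assign each detected ROI the majority ground-truth origin under it."""
    if roiset.label_image.shape != truth_label_image.shape:
        raise ShapeMismatchError(
            f"label image shapes differ: {roiset.label_image.shape} vs {truth_label_image.shape}"
        )
    origin_of: dict[int, int] = {}
    for fid in roiset.fruit_ids:
        true_ids = truth_label_image[roiset.label_image == fid]
        true_ids = true_ids[true_ids > 0]
        if true_ids.size == 0:
            raise EmptySceneError(f"detected ROI {fid} overlaps no ground-truth fruit")
        vals, counts = np.unique(true_ids, return_counts=True)
        origin_of[fid] = int(fruit_origins[int(vals[np.argmax(counts)])])
    return origin_of
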