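"""Band cropping, wavelet denoising, area normalization, per-fruit averaging.

The fixed preprocessing order is: crop to the retained band window, wavelet
denoise each pixel spectrum, area-normalize each pixel spectrum, then average
the pixels of a fruit into its one representative spectrum.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import wavelet
from .cube import WavelengthAxis
from .errors import EmptyInputError, NormalizationError, WavelengthRangeError
from .segmentation import PixelSpectra

#: 1-based inclusive band numbers of the retained window (200 variables)
DEFAULT_FIRST_BAND = 31
DEFAULT_LAST_BAND = 230


@dataclass
class SpectrumTable:
    """One preprocessed spectrum per fruit plus labels and split flags."""

    matrix: np.ndarray  # samples x retained bands
    axis: WavelengthAxis
    labels: np.ndarray  # origin codes 0/1/2
    sample_ids: list[str]
    split: np.ndarray | None = None  # per-sample split names, optional

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.matrix.ndim != 2:
            raise ValueError("matrix must be samples x bands")
        if self.matrix.shape[1] != len(self.axis):
            raise ValueError("band count does not match axis length")
        if self.matrix.shape[0] != self.labels.size or self.matrix.shape[0] != len(self.sample_ids):
            raise ValueError("labels/sample_ids must have one entry per row")
        if not np.isin(self.labels, (0, 1, 2)).all():
            raise ValueError("labels must be origin codes 0, 1 or 2")
        if self.split is not None:
            self.split = np.asarray(self.split, dtype=object)
            if self.split.size != self.matrix.shape[0]:
                raise ValueError("split must have one entry per row")

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    def rows(self, selector: np.ndarray) -> "SpectrumTable":
        selector = np.asarray(selector)
        if selector.dtype == bool:
            selector = np.flatnonzero(selector)
        return SpectrumTable(
            matrix=self.matrix[selector],
            axis=self.axis,
            labels=self.labels[selector],
            sample_ids=[self.sample_ids[int(i)] for i in selector],
            split=None if self.split is None else self.split[selector],
        )

    def subset_split(self, name: str) -> "SpectrumTable":
        if self.split is None:
            raise ValueError("table has no split assignment")
        return self.rows(self.split == name)

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.matrix, columns=[f"{v:.4f}" for v in self.axis.values])
        df.insert(0, "split", self.split if self.split is not None else "")
        df.insert(0, "origin", self.labels)
        df.insert(0, "sample_id", self.sample_ids)
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "SpectrumTable":
        df = pd.read_csv(path)
        meta = ["sample_id", "origin", "split"]
        wavecols = [c for c in df.columns if c not in meta]
        split = df["split"].astype(str).to_numpy() if df["split"].notna().any() else None
        return cls(
            matrix=df[wavecols].to_numpy(dtype=float),
            axis=WavelengthAxis(np.asarray([float(c) for c in wavecols])),
            labels=df["origin"].to_numpy(dtype=int),
            sample_ids=[str(s) for s in df["sample_id"]],
            split=split,
        )


def crop_bands(
    spectra: np.ndarray,
    axis: WavelengthAxis,
    first_band: int = DEFAULT_FIRST_BAND,
    last_band: int = DEFAULT_LAST_BAND,
) -> tuple[np.ndarray, WavelengthAxis]:
    """Keep 1-based inclusive band numbers ``first_band..last_band``."""
    n = len(axis)
    if not (1 <= first_band <= last_band <= n):
        raise WavelengthRangeError(
            f"band window [{first_band}, {last_band}] invalid for {n} bands "
            "(1-based, inclusive, first <= last)"
        )
    spectra = np.asarray(spectra)
    sl = slice(first_band - 1, last_band)
    return spectra[..., sl], axis.subset(np.arange(first_band - 1, last_band))


def wavelet_denoise(
    spectra: np.ndarray,
    level: int = 3,
    n_vanishing: int = 6,
    threshold: float | str = "bayes",
) -> np.ndarray:
    """Daubechies-6 level-3 shrinkage of each spectrum (last axis)."""
    return wavelet.denoise(spectra, level=level, n_vanishing=n_vanishing, threshold=threshold)


def area_normalize(spectra: np.ndarray) -> np.ndarray:
    """Scale each spectrum so its values sum to one."""
    spectra = np.asarray(spectra, dtype=float)
    total = spectra.sum(axis=-1, keepdims=True)
    if np.any(np.abs(total) < 1e-300):
        raise NormalizationError("cannot area-normalize a zero-sum spectrum")
    return spectra / total


def average_roi(pixel_matrix: np.ndarray) -> np.ndarray:
    """Arithmetic mean over pixels (rows)."""
    pixel_matrix = np.asarray(pixel_matrix, dtype=float)
    if pixel_matrix.ndim != 2 or pixel_matrix.shape[0] == 0:
        raise EmptyInputError("average_roi needs a non-empty pixels x bands matrix")
    return pixel_matrix.mean(axis=0)


def preprocess_fruit(
    pixels: PixelSpectra,
    axis: WavelengthAxis,
    first_band: int = DEFAULT_FIRST_BAND,
    last_band: int = DEFAULT_LAST_BAND,
    denoise_level: int = 3,
) -> tuple[np.ndarray, WavelengthAxis]:
    """Crop -> denoise per pixel -> area-normalize per pixel -> average."""
    cropped, cropped_axis = crop_bands(pixels.matrix, axis, first_band, last_band)
    den = wavelet_denoise(cropped, level=denoise_level)
    norm = area_normalize(den)
    return average_roi(norm), cropped_axis


def build_table(
    fruit_pixels: list[tuple[str, int, PixelSpectra]],
    axis: WavelengthAxis,
    first_band: int = DEFAULT_FIRST_BAND,
    last_band: int = DEFAULT_LAST_BAND,
) -> SpectrumTable:
    """Assemble the per-fruit spectrum table.

    ``fruit_pixels`` holds ``(sample_id, origin, PixelSpectra)`` triples.
    """
    if not fruit_pixels:
        raise EmptyInputError("no fruits to assemble")
    rows, labels, ids = [], [], []
    cropped_axis = None
    for sample_id, origin, pixels in fruit_pixels:
        spectrum, cropped_axis = preprocess_fruit(pixels, axis, first_band, last_band)
        rows.append(spectrum)
        labels.append(origin)
        ids.append(sample_id)
    return SpectrumTable(
        matrix=np.vstack(rows), axis=cropped_axis, labels=np.asarray(labels), sample_ids=ids
    )
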