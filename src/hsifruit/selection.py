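"""Effective-wavelength selection from second-derivative class-mean spectra.

The manual step of picking the derivative peaks/valleys that differ most
between classes is automated as: collect local extrema of any class curve,
rank them by between-class spread (max minus min across class curves at that
band), and keep the top-ranked bands greedily subject to a minimum
wavelength separation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.signal import savgol_filter

from .cube import WavelengthAxis
from .errors import ParameterError, WavelengthRangeError
from .preprocess import SpectrumTable

DEFAULT_WINDOW = 9
DEFAULT_POLYORDER = 2
DEFAULT_N_MAX = 22
DEFAULT_MIN_SEPARATION_NM = 8.0
DEFAULT_SPREAD_QUANTILE = 0.5


@dataclass
class SecondDerivativeSet:
    """Savitzky-Golay second-derivative curves, one per class."""

    curves: np.ndarray  # classes x bands
    axis: WavelengthAxis
    window: int
    polyorder: int


@dataclass
class EffectiveWavelengths:
    """Selected bands, ascending, with their between-class spread scores."""

    wavelengths_nm: np.ndarray
    band_indices: np.ndarray
    scores: np.ndarray
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        idx = np.asarray(self.band_indices, dtype=int)
        if idx.size != np.unique(idx).size:
            raise ValueError("duplicate band indices")
        order = np.argsort(np.asarray(self.wavelengths_nm))
        object.__setattr__(self, "wavelengths_nm", np.asarray(self.wavelengths_nm, float)[order])
        object.__setattr__(self, "band_indices", idx[order])
        object.__setattr__(self, "scores", np.asarray(self.scores, float)[order])

    def __len__(self) -> int:
        return int(self.band_indices.size)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "wavelengths_nm": self.wavelengths_nm.tolist(),
                    "band_indices": self.band_indices.tolist(),
                    "scores": self.scores.tolist(),
                    "params": self.params,
                },
                indent=2,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "EffectiveWavelengths":
        d = json.loads(Path(path).read_text())
        return cls(
            wavelengths_nm=np.asarray(d["wavelengths_nm"]),
            band_indices=np.asarray(d["band_indices"]),
            scores=np.asarray(d["scores"]),
            params=d.get("params", {}),
        )


def class_mean_spectra(table: SpectrumTable) -> np.ndarray:
    """Per-class mean spectra (classes 0..2), rows ordered by class code."""
    return np.vstack([table.matrix[table.labels == c].mean(axis=0) for c in (0, 1, 2)])


def second_derivative(
    class_means: np.ndarray,
    axis: WavelengthAxis,
    window: int = DEFAULT_WINDOW,
    polyorder: int = DEFAULT_POLYORDER,
) -> SecondDerivativeSet:
    """Savitzky-Golay second derivative of each class-mean spectrum.

    The derivative is taken in band-index units (``delta=1``); only the
    locations of extrema matter downstream, not the physical scale.
    """
    class_means = np.atleast_2d(np.asarray(class_means, dtype=float))
    n = class_means.shape[1]
    if window % 2 != 1 or not (2 <= polyorder < window) or window > n:
        raise ParameterError(
            f"need odd window, 2 <= polyorder < window <= n_bands; "
            f"got window={window}, polyorder={polyorder}, n_bands={n}"
        )
    curves = savgol_filter(
        class_means, window_length=window, polyorder=max(polyorder, 2), deriv=2, delta=1.0, axis=-1
    )
    return SecondDerivativeSet(curves=curves, axis=axis, window=window, polyorder=polyorder)


def _local_extrema(curve: np.ndarray) -> np.ndarray:
    """Interior indices that are strict local maxima or minima."""
    left = curve[1:-1] - curve[:-2]
    right = curve[1:-1] - curve[2:]
    is_max = (left > 0) & (right > 0)
    is_min = (left < 0) & (right < 0)
    return np.flatnonzero(is_max | is_min) + 1


def select_effective(
    deriv: SecondDerivativeSet,
    n_max: int = DEFAULT_N_MAX,
    min_separation_nm: float = DEFAULT_MIN_SEPARATION_NM,
    spread_quantile: float = DEFAULT_SPREAD_QUANTILE,
) -> EffectiveWavelengths:
    """Greedy spread-ranked selection of derivative extrema.

    Identical class curves have zero spread everywhere and yield an empty
    (but valid) selection.
    """
    curves = deriv.curves
    if curves.shape[0] < 2:
        raise ParameterError("need at least two class curves")
    candidates = np.unique(np.concatenate([_local_extrema(c) for c in curves]))
    spread = curves.max(axis=0) - curves.min(axis=0)
    params = {
        "n_max": int(n_max),
        "min_separation_nm": float(min_separation_nm),
        "spread_quantile": float(spread_quantile),
        "window": deriv.window,
        "polyorder": deriv.polyorder,
    }
    empty = EffectiveWavelengths(
        wavelengths_nm=np.empty(0), band_indices=np.empty(0, int), scores=np.empty(0), params=params
    )
    if candidates.size == 0:
        return empty
    cand_spread = spread[candidates]
    positive = cand_spread > 0
    if not positive.any():
        return empty
    floor = np.quantile(cand_spread[positive], spread_quantile)
    candidates = candidates[positive & (cand_spread >= floor)]
    # rank by spread descending, ties toward the lower band index
    order = np.lexsort((candidates, -spread[candidates]))
    lam = deriv.axis.values
    chosen: list[int] = []
    for idx in candidates[order]:
        if len(chosen) >= n_max:
            break
        if all(abs(lam[idx] - lam[j]) >= min_separation_nm for j in chosen):
            chosen.append(int(idx))
    chosen_arr = np.asarray(sorted(chosen), dtype=int)
    return EffectiveWavelengths(
        wavelengths_nm=lam[chosen_arr],
        band_indices=chosen_arr,
        scores=spread[chosen_arr],
        params=params,
    )


def select_from_table(
    table: SpectrumTable,
    window: int = DEFAULT_WINDOW,
    polyorder: int = DEFAULT_POLYORDER,
    n_max: int = DEFAULT_N_MAX,
    min_separation_nm: float = DEFAULT_MIN_SEPARATION_NM,
    spread_quantile: float = DEFAULT_SPREAD_QUANTILE,
) -> EffectiveWavelengths:
    """Convenience wrapper: class means -> second derivative -> selection."""
    deriv = second_derivative(class_mean_spectra(table), table.axis, window, polyorder)
    return select_effective(deriv, n_max, min_separation_nm, spread_quantile)


def fixed_wavelengths(axis: WavelengthAxis, wavelengths_nm: list[float]) -> EffectiveWavelengths:
    """Build a selection from an explicit wavelength list (nearest bands)."""
    indices = sorted({axis.nearest(w) for w in wavelengths_nm})
    idx = np.asarray(indices, dtype=int)
    return EffectiveWavelengths(
        wavelengths_nm=axis.values[idx],
        band_indices=idx,
        scores=np.full(idx.size, np.nan),
        params={"mode": "fixed"},
    )


def subset_table(table: SpectrumTable, ew: EffectiveWavelengths) -> SpectrumTable:
    """Column-subset the table to the selected bands."""
    idx = np.asarray(ew.band_indices, dtype=int)
    if idx.size and (idx.min() < 0 or idx.max() >= len(table.axis)):
        raise WavelengthRangeError(
            f"band index {idx.max()} outside retained axis of {len(table.axis)} bands"
        )
    return SpectrumTable(
        matrix=table.matrix[:, idx],
        axis=table.axis.subset(idx),
        labels=table.labels,
        sample_ids=list(table.sample_ids),
        split=table.split,
    )
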