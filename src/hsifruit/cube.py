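"""Hypercube containers, reflectance correction and cube I/O.

A hypercube is stored as a 3-D array shaped ``(width, length, bands)``:
``width`` is the across-track pixel count of the line-scan camera
(320 by default), ``length`` the number of scan lines, and ``bands`` the
spectral axis.  Reference frames are per-line calibrations shaped
``(width, bands)`` and broadcast along the scan direction; full-frame
references shaped like the cube are accepted as well.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np

from .errors import DegenerateReferenceError, FormatError, WavelengthRangeError

DEFAULT_WIDTH = 320
DEFAULT_N_BANDS = 256
DEFAULT_RANGE_NM = (874.0, 1734.0)

#: guard on (white - dark) before division
DIVISION_TOLERANCE = 1e-9


@dataclass(frozen=True)
class WavelengthAxis:
    """Strictly ascending wavelength values, one per band, in nm."""

    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1 or values.size < 2:
            raise ValueError("wavelength axis must be a 1-D array of >= 2 values")
        if not np.all(np.diff(values) > 0):
            raise ValueError("wavelength axis must be strictly ascending")
        object.__setattr__(self, "values", values)

    @classmethod
    def default(cls) -> "WavelengthAxis":
        """The instrument axis: 256 bands evenly spanning 874-1734 nm."""
        lo, hi = DEFAULT_RANGE_NM
        return cls(np.linspace(lo, hi, DEFAULT_N_BANDS))

    def __len__(self) -> int:
        return int(self.values.size)

    @property
    def spacing(self) -> float:
        """Mean band-to-band spacing in nm."""
        return float((self.values[-1] - self.values[0]) / (len(self) - 1))

    def nearest(self, wavelength_nm: float) -> int:
        """Index of the band closest to ``wavelength_nm``.

        Raises :class:`WavelengthRangeError` when the request falls outside
        the covered range.
        """
        if not (self.values[0] <= wavelength_nm <= self.values[-1]):
            raise WavelengthRangeError(
                f"wavelength {wavelength_nm} nm outside axis range "
                f"[{self.values[0]}, {self.values[-1]}] nm"
            )
        return int(np.argmin(np.abs(self.values - wavelength_nm)))

    def subset(self, indices: np.ndarray) -> "WavelengthAxis":
        return WavelengthAxis(self.values[np.asarray(indices)])


@dataclass
class Hypercube:
    """A raw or reflectance cube plus its wavelength axis."""

    data: np.ndarray
    axis: WavelengthAxis
    kind: str = "raw"  # "raw" | "reflectance"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("cube data must be 3-D (width, length, bands)")
        if self.data.shape[2] != len(self.axis):
            raise FormatError(
                f"cube has {self.data.shape[2]} bands but axis has "
                f"{len(self.axis)} wavelengths"
            )
        if self.kind not in ("raw", "reflectance"):
            raise ValueError(f"unknown cube kind {self.kind!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class ReferenceFrames:
    """Dark-current and white-panel reference frames.

    Shapes may be ``(width, bands)`` (per-line, the default produced by the
    simulator) or ``(width, length, bands)`` (full frame).
    """

    dark: np.ndarray
    white: np.ndarray

    def __post_init__(self) -> None:
        self.dark = np.asarray(self.dark, dtype=float)
        self.white = np.asarray(self.white, dtype=float)
        if self.dark.shape != self.white.shape:
            raise FormatError(
                f"dark/white reference shapes differ: {self.dark.shape} vs {self.white.shape}"
            )

    def broadcast_to(self, cube_shape: tuple[int, int, int]) -> tuple[np.ndarray, np.ndarray]:
        w, length, b = cube_shape
        if self.dark.shape == (w, b):
            return self.dark[:, None, :], self.white[:, None, :]
        if self.dark.shape == (w, length, b):
            return self.dark, self.white
        raise FormatError(
            f"reference shape {self.dark.shape} incompatible with cube shape "
            f"{cube_shape}; expected {(w, b)} or {(w, length, b)}"
        )


def correct_reflectance(raw: Hypercube, refs: ReferenceFrames) -> Hypercube:
    """White/dark reflectance correction: ``(raw - dark) / (white - dark)``.

    Values outside [0, 1] are deliberately not clipped.  A near-zero
    ``white - dark`` denominator raises :class:`DegenerateReferenceError`
    naming the first offending element.
    """
    if raw.kind != "raw":
        raise ValueError("correct_reflectance expects a raw cube")
    dark, white = refs.broadcast_to(raw.shape)
    denom = white - dark
    bad = np.abs(denom) <= DIVISION_TOLERANCE
    if np.any(bad):
        idx = tuple(int(i) for i in np.argwhere(bad)[0])
        raise DegenerateReferenceError(
            f"white - dark <= {DIVISION_TOLERANCE} at element {idx}"
        )
    data = (raw.data - dark) / denom
    return Hypercube(data=data, axis=raw.axis, kind="reflectance")


# ---------------------------------------------------------------------------
# HDF5-style scene container
# ---------------------------------------------------------------------------

def write_cube(
    cube: Hypercube,
    path: str | Path,
    refs: ReferenceFrames | None = None,
    label_image: np.ndarray | None = None,
    fruit_origins: dict[int, int] | None = None,
) -> None:
    """Write a cube (plus optional references and ground truth) to HDF5."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=cube.data)
        f.create_dataset("wavelengths", data=cube.axis.values)
        f.attrs["kind"] = cube.kind
        if refs is not None:
            g = f.create_group("references")
            g.create_dataset("dark", data=refs.dark)
            g.create_dataset("white", data=refs.white)
        if label_image is not None:
            f.create_dataset("label_image", data=np.asarray(label_image, dtype=np.int32))
        if fruit_origins is not None:
            f.attrs["fruit_origins"] = json.dumps(
                {str(k): int(v) for k, v in fruit_origins.items()}
            )


def read_cube(path: str | Path) -> tuple[Hypercube, ReferenceFrames | None]:
    with h5py.File(path, "r") as f:
        data = f["data"][()]
        wavelengths = f["wavelengths"][()]
        if data.shape[2] != wavelengths.shape[0]:
            raise FormatError(
                f"container has {data.shape[2]} bands but "
                f"{wavelengths.shape[0]} wavelengths"
            )
        cube = Hypercube(data=data, axis=WavelengthAxis(wavelengths), kind=str(f.attrs["kind"]))
        refs = None
        if "references" in f:
            refs = ReferenceFrames(dark=f["references/dark"][()], white=f["references/white"][()])
    return cube, refs


def read_scene(path: str | Path) -> dict:
    """Read the full scene container including ground truth when present."""
    out: dict = {}
    cube, refs = read_cube(path)
    out["cube"], out["refs"] = cube, refs
    with h5py.File(path, "r") as f:
        if "label_image" in f:
            out["label_image"] = f["label_image"][()]
        if "fruit_origins" in f.attrs:
            out["fruit_origins"] = {
                int(k): int(v) for k, v in json.loads(f.attrs["fruit_origins"]).items()
            }
    return out


# ---------------------------------------------------------------------------
# ENVI-style header + band-interleaved-by-line binary
# ---------------------------------------------------------------------------

_ENVI_DTYPES = {4: np.dtype("<f4"), 5: np.dtype("<f8")}
_ENVI_CODES = {v: k for k, v in _ENVI_DTYPES.items()}


def write_envi(cube: Hypercube, path_base: str | Path) -> tuple[Path, Path]:
    """Write ``<base>.hdr`` (text header) and ``<base>.img`` (BIL binary)."""
    base = Path(path_base)
    base.parent.mkdir(parents=True, exist_ok=True)
    hdr, img = base.with_suffix(".hdr"), base.with_suffix(".img")
    data = np.ascontiguousarray(cube.data)
    dtype = np.dtype("<f8") if data.dtype == np.float64 else np.dtype("<f4")
    code = _ENVI_CODES[dtype]
    width, length, bands = data.shape
    wl = ",\n".join(f"  {v:.6f}" for v in cube.axis.values)
    hdr.write_text(
        "ENVI\n"
        f"samples = {width}\n"
        f"lines = {length}\n"
        f"bands = {bands}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        f"data type = {code}\n"
        "interleave = bil\n"
        "byte order = 0\n"
        f"kind = {cube.kind}\n"
        "wavelength units = nm\n"
        "wavelength = {\n" + wl + "\n}\n"
    )
    # BIL layout: for each line, bands x samples
    bil = data.transpose(1, 2, 0).astype(dtype)
    bil.tofile(img)
    return hdr, img


def _parse_envi_header(text: str) -> dict:
    fields: dict = {}
    body = text
    # pull out the brace-delimited wavelength block first
    if "wavelength" in body:
        start = body.index("wavelength =")
        brace0 = body.index("{", start)
        brace1 = body.index("}", brace0)
        wl = [float(x) for x in body[brace0 + 1 : brace1].replace("\n", " ").split(",") if x.strip()]
        fields["wavelength"] = wl
        body = body[:start] + body[brace1 + 1 :]
    for line in body.splitlines():
        if "=" in line:
            key, _, val = line.partition("=")
            fields[key.strip()] = val.strip()
    return fields


def read_envi(path_base: str | Path) -> Hypercube:
    base = Path(path_base)
    hdr, img = base.with_suffix(".hdr"), base.with_suffix(".img")
    fields = _parse_envi_header(hdr.read_text())
    width = int(fields["samples"])
    length = int(fields["lines"])
    bands = int(fields["bands"])
    code = int(fields["data type"])
    if code not in _ENVI_DTYPES:
        raise FormatError(f"unsupported ENVI data type {code}")
    wavelengths = fields.get("wavelength")
    if wavelengths is None:
        raise FormatError("ENVI header lacks a wavelength block")
    if len(wavelengths) != bands:
        raise FormatError(
            f"header lists {len(wavelengths)} wavelengths but declares {bands} bands"
        )
    raw = np.fromfile(img, dtype=_ENVI_DTYPES[code])
    expected = width * length * bands
    if raw.size != expected:
        raise FormatError(f"binary holds {raw.size} values, header implies {expected}")
    data = raw.reshape(length, bands, width).transpose(2, 0, 1)
    kind = fields.get("kind", "raw")
    return Hypercube(data=data, axis=WavelengthAxis(np.asarray(wavelengths)), kind=kind)
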