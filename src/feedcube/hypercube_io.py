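"""Hypercube data model and ENVI file I/O.

A hypercube is a 3-D array with two spatial axes and one spectral axis.
Internally the axis order is fixed as ``(line y, sample x, band)``; the ENVI
interleave (BIL/BIP/BSQ) is handled purely at the file boundary.

The ENVI format is a plain ASCII header (``.hdr``) describing shape,
interleave, data type and wavelengths, next to a raw binary payload.  The
reader/writer here covers the subset needed for reflectance work: integer and
float sample types, all three interleaves, little/big endian, and wavelength
metadata (required — a cube without a wavelength grid is useless for
chemometrics).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import DimensionError, DomainError, FormatError

__all__ = [
    "WavelengthGrid",
    "Hypercube",
    "ReferencePanel",
    "make_grid",
    "subrange_indices",
    "nearest_band",
    "read_envi",
    "write_envi",
]

#: cube calibration states
STATES = ("raw_counts", "reflectance", "masked_reflectance")

# ENVI numeric "data type" codes <-> numpy dtypes
_ENVI_DTYPES = {
    1: np.uint8,
    2: np.int16,
    3: np.int32,
    4: np.float32,
    5: np.float64,
    12: np.uint16,
    13: np.uint32,
    14: np.int64,
}
_DTYPE_CODES = {np.dtype(v): k for k, v in _ENVI_DTYPES.items()}


@dataclass(frozen=True, eq=False)
class WavelengthGrid:
    """Strictly increasing band centres in nanometres."""

    band_centers: np.ndarray

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, WavelengthGrid):
            return NotImplemented
        return np.array_equal(self.band_centers, other.band_centers)

    def __hash__(self) -> int:
        return hash(self.band_centers.tobytes())

    def __post_init__(self) -> None:
        centers = np.asarray(self.band_centers, dtype=float)
        if centers.ndim != 1 or centers.size == 0:
            raise DomainError("band_centers must be a non-empty 1-D array")
        if not np.all(np.diff(centers) > 0):
            raise DomainError("band_centers must be strictly increasing")
        object.__setattr__(self, "band_centers", centers)

    @property
    def count(self) -> int:
        return int(self.band_centers.size)

    @property
    def spacing(self) -> float:
        """Mean inter-band spacing in nm (exact for uniform grids)."""
        return float(np.mean(np.diff(self.band_centers)))

    def __len__(self) -> int:  # pragma: no cover - convenience
        return self.count


@dataclass
class Hypercube:
    """3-D spectral image with calibration state.

    ``data`` is indexed ``(y, x, band)``; the band axis length must equal
    ``grid.count``.  ``state`` tracks where the cube sits in the calibration
    chain; a ``masked_reflectance`` cube must carry a mask of matching
    spatial shape.
    """

    data: np.ndarray
    grid: WavelengthGrid
    state: str = "raw_counts"
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise DimensionError(f"cube must be 3-D, got {self.data.ndim}-D")
        if self.data.shape[2] != self.grid.count:
            raise DimensionError(
                f"band axis length {self.data.shape[2]} != grid count {self.grid.count}"
            )
        if self.state not in STATES:
            raise DomainError(f"unknown state {self.state!r}")
        if self.state != "raw_counts" and not np.all(np.isfinite(self.data)):
            raise DomainError("reflectance cube contains non-finite values")
        if self.mask is not None:
            self.mask = np.asarray(self.mask).astype(bool)
            if self.mask.shape != self.data.shape[:2]:
                raise DimensionError("mask spatial shape does not match cube")
        if self.state == "masked_reflectance" and self.mask is None:
            raise DomainError("masked_reflectance state requires a mask")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class ReferencePanel:
    """White and dark reference frames for reflectance calibration.

    Both frames may be full-frame ``(y, x, band)`` or per-line ``(x, band)``
    (a line-scan instrument records one reference line that applies to every
    scan line).  White must exceed dark on the usable band range.
    """

    white: np.ndarray
    dark: np.ndarray

    def __post_init__(self) -> None:
        self.white = np.asarray(self.white, dtype=float)
        self.dark = np.asarray(self.dark, dtype=float)
        if self.white.shape != self.dark.shape:
            raise DimensionError("white and dark frames must have identical shapes")
        if self.white.ndim not in (2, 3):
            raise DimensionError("reference frames must be 2-D (x, band) or 3-D (y, x, band)")


def make_grid(start: float, stop: float, n_bands: int) -> WavelengthGrid:
    """Uniform wavelength grid with ``n_bands`` centres from start to stop.

    The 894-2504 nm sensor range divided into 275 bands yields the nominal
    ~5.85 nm interval of SWIR line-scan instruments
    (exactly 1610/274 ≈ 5.876 nm as the uniform partition).
    """
    if not (stop > start):
        raise DomainError(f"stop ({stop}) must exceed start ({start})")
    if n_bands < 2:
        raise DomainError("a grid needs at least 2 bands")
    return WavelengthGrid(np.linspace(start, stop, n_bands))


def subrange_indices(grid: WavelengthGrid, low: float, high: float) -> np.ndarray:
    """Indices of all band centres c with low <= c <= high, in order.

    Used to restrict models to the 894-1917 nm window where the detector
    signal-to-noise ratio is adequate.  An empty selection is allowed.
    """
    if low > high:
        raise DomainError("low must not exceed high")
    c = grid.band_centers
    return np.flatnonzero((c >= low) & (c <= high))


def nearest_band(grid: WavelengthGrid, target: float) -> int:
    """Index of the band centre nearest ``target`` (ties toward lower index)."""
    # np.argmin returns the first minimum, which is the lower index on a tie
    return int(np.argmin(np.abs(grid.band_centers - target)))


# ---------------------------------------------------------------------------
# ENVI header parsing / writing
# ---------------------------------------------------------------------------

def _parse_header(text: str) -> dict[str, str]:
    """Parse an ENVI header into a flat {key: value-string} dict.

    Values in braces may span lines; keys are case-insensitive and stored
    lower-case.
    """
    if not text.lstrip().lower().startswith("envi"):
        raise FormatError("not an ENVI header: missing leading 'ENVI' token")
    body = text.lstrip()[4:]
    fields: dict[str, str] = {}
    # key = value  |  key = { multi, line, value }
    pattern = re.compile(r"^\s*([^={}\n]+?)\s*=\s*(\{[^}]*\}|[^\n]*)", re.M | re.S)
    for m in pattern.finditer(body):
        key = m.group(1).strip().lower()
        val = m.group(2).strip()
        if val.startswith("{"):
            val = val[1:-1].strip()
        fields[key] = val
    return fields


def _require(fields: dict[str, str], key: str) -> str:
    if key not in fields:
        raise FormatError(f"ENVI header missing required field '{key}'")
    return fields[key]


def read_envi(header_path: str | Path, data_path: str | Path | None = None) -> Hypercube:
    """Read an ENVI header/binary pair into a Hypercube.

    ``data_path`` defaults to the header path with the ``.hdr`` suffix
    stripped (or swapped for ``.dat``).  Raises :class:`FormatError` naming
    the offending field on any inconsistency: missing wavelengths, a
    wavelength list whose length disagrees with ``bands``, an unknown
    interleave or data type, or a truncated binary payload.
    """
    header_path = Path(header_path)
    if data_path is None:
        stem = header_path.with_suffix("")
        data_path = stem if stem.exists() else stem.with_suffix(".dat")
    data_path = Path(data_path)

    fields = _parse_header(header_path.read_text())
    samples = int(_require(fields, "samples"))
    lines = int(_require(fields, "lines"))
    bands = int(_require(fields, "bands"))
    interleave = _require(fields, "interleave").lower()
    if interleave not in ("bil", "bip", "bsq"):
        raise FormatError(f"unknown interleave '{interleave}'")
    code = int(_require(fields, "data type"))
    if code not in _ENVI_DTYPES:
        raise FormatError(f"unsupported data type code {code}")
    dtype = np.dtype(_ENVI_DTYPES[code])
    byte_order = int(fields.get("byte order", "0"))
    dtype = dtype.newbyteorder("<" if byte_order == 0 else ">")
    offset = int(fields.get("header offset", "0"))

    wl_text = _require(fields, "wavelength")
    wavelengths = np.array([float(v) for v in wl_text.replace("\n", " ").split(",") if v.strip()])
    if wavelengths.size != bands:
        raise FormatError(
            f"wavelength list length {wavelengths.size} != bands {bands}"
        )

    expected = samples * lines * bands * dtype.itemsize
    payload = data_path.read_bytes()[offset:]
    if len(payload) < expected:
        raise FormatError(
            f"truncated binary: expected {expected} bytes, found {len(payload)}"
        )
    flat = np.frombuffer(payload[:expected], dtype=dtype)

    if interleave == "bip":       # (lines, samples, bands)
        data = flat.reshape(lines, samples, bands)
    elif interleave == "bil":     # (lines, bands, samples)
        data = flat.reshape(lines, bands, samples).transpose(0, 2, 1)
    else:                         # bsq: (bands, lines, samples)
        data = flat.reshape(bands, lines, samples).transpose(1, 2, 0)

    state = fields.get("feedcube state", "raw_counts")
    if state not in STATES:
        state = "raw_counts"
    return Hypercube(np.ascontiguousarray(data), WavelengthGrid(wavelengths), state=state)


def write_envi(
    cube: Hypercube,
    header_path: str | Path,
    data_path: str | Path | None = None,
    interleave: str = "bil",
) -> tuple[Path, Path]:
    """Write a Hypercube as an ENVI header/binary pair.

    The write→read round trip is bit-exact for the data and reproduces the
    wavelength grid to full float precision.
    """
    header_path = Path(header_path)
    if data_path is None:
        data_path = header_path.with_suffix(".dat")
    data_path = Path(data_path)
    interleave = interleave.lower()
    if interleave not in ("bil", "bip", "bsq"):
        raise FormatError(f"unknown interleave '{interleave}'")

    dtype = np.dtype(cube.data.dtype)
    if dtype not in _DTYPE_CODES:
        raise FormatError(f"dtype {dtype} has no ENVI data type code")
    lines, samples, bands = cube.data.shape

    if interleave == "bip":
        payload = cube.data
    elif interleave == "bil":
        payload = cube.data.transpose(0, 2, 1)
    else:
        payload = cube.data.transpose(2, 0, 1)

    wl = ", ".join(f"{w:.6f}" for w in cube.grid.band_centers)
    header = (
        "ENVI\n"
        "description = {feedcube hypercube}\n"
        f"samples = {samples}\n"
        f"lines = {lines}\n"
        f"bands = {bands}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        f"data type = {_DTYPE_CODES[dtype]}\n"
        f"interleave = {interleave}\n"
        "byte order = 0\n"
        f"feedcube state = {cube.state}\n"
        "wavelength units = Nanometers\n"
        f"wavelength = {{ {wl} }}\n"
    )
    header_path.write_text(header)
    data_path.write_bytes(np.ascontiguousarray(payload).astype(dtype.newbyteorder("<")).tobytes())
    return header_path, data_path
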