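"""Reflectance calibration and background masking.

Calibration normalises raw counts between the dark-current frame (0 %
reflectance) and the white-reference frame (~99 % reflectance):
``X = (raw − dark) / (white − dark)``.  Masking thresholds a single band
image — by default the 1140 nm band, where the sample is brightest relative
to the background — then cleans the binary image morphologically and fills
holes.  Sample pixels are 1, background 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import (
    DegenerateImageError,
    DimensionError,
    DomainError,
    EmptySampleError,
)
from .hypercube_io import Hypercube, ReferencePanel, nearest_band

__all__ = [
    "MaskParams",
    "calibrate",
    "auto_threshold",
    "build_mask",
    "apply_mask",
    "mean_spectrum",
]

#: guard for the white-dark denominator
_EPS = 1e-6


@dataclass(frozen=True)
class MaskParams:
    """Background-mask parameters.

    ``threshold`` may be a reflectance value in (0, 1) or the string
    ``"auto"`` for the midpoint rule (mean of the image max and min).  The
    fixed default 0.46 reproduces the documented instrument configuration.
    """

    band_nm: float = 1140.0
    threshold: float | str = 0.46
    erosion_radius: int = 1
    fill_holes: bool = True

    def __post_init__(self) -> None:
        if self.threshold != "auto" and not (0.0 < float(self.threshold) < 1.0):
            raise DomainError("numeric threshold must lie in (0, 1)")
        if self.erosion_radius < 0:
            raise DomainError("erosion_radius must be >= 0")


def calibrate(raw: Hypercube, panel: ReferencePanel) -> Hypercube:
    """Convert raw counts to reflectance via white/dark references.

    Pixels/bands where ``white − dark <= 1e-6`` are flagged invalid and set
    to 0.  Reference frames may be full-frame ``(y, x, band)`` or per-line
    ``(x, band)``, broadcast across scan lines.
    """
    if raw.state != "raw_counts":
        raise DomainError(f"calibrate expects raw_counts, got state {raw.state!r}")
    white, dark = panel.white, panel.dark
    if white.ndim == 2:
        white = white[None, :, :]
        dark = dark[None, :, :]
    try:
        denom = np.broadcast_to(white - dark, raw.data.shape)
        dark_b = np.broadcast_to(dark, raw.data.shape)
    except ValueError as exc:
        raise DimensionError(f"reference frames do not conform to cube: {exc}") from exc
    valid = denom > _EPS
    refl = np.zeros_like(raw.data, dtype=float)
    np.divide(raw.data - dark_b, denom, out=refl, where=valid)
    refl[~valid] = 0.0
    return Hypercube(refl, raw.grid, state="reflectance")


def auto_threshold(band_image: np.ndarray) -> float:
    """Midpoint threshold: mean of the band image's maximum and minimum."""
    band_image = np.asarray(band_image, dtype=float)
    lo, hi = float(band_image.min()), float(band_image.max())
    if hi <= lo:
        raise DegenerateImageError("constant band image: no threshold exists")
    return 0.5 * (hi + lo)


def build_mask(cube: Hypercube, params: MaskParams = MaskParams()) -> np.ndarray:
    """Binary sample mask from a single-band threshold plus morphology.

    The band nearest ``params.band_nm`` is thresholded (sample pixels are the
    bright side).  Erosion with a disk of the configured radius removes
    speckle; the surviving objects are then restored exactly by binary
    propagation inside the thresholded image (so a clean object is not
    shrunk), and holes are filled.
    """
    if cube.state not in ("reflectance", "masked_reflectance"):
        raise DomainError("build_mask expects a reflectance cube")
    wl = cube.grid.band_centers
    if not (wl[0] <= params.band_nm <= wl[-1]):
        raise DomainError(f"band {params.band_nm} nm outside grid range")
    img = cube.data[:, :, nearest_band(cube.grid, params.band_nm)]
    thr = auto_threshold(img) if params.threshold == "auto" else float(params.threshold)
    binary = img > thr
    if params.erosion_radius > 0 and binary.any():
        r = params.erosion_radius
        yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
        structure = yy**2 + xx**2 <= r**2
        seed = ndimage.binary_erosion(binary, structure=structure)
        binary = ndimage.binary_propagation(seed, mask=binary)
    if params.fill_holes:
        binary = ndimage.binary_fill_holes(binary)
    return binary.astype(bool)


def apply_mask(cube: Hypercube, mask: np.ndarray) -> Hypercube:
    """Zero background pixels in every band and attach the mask."""
    mask = np.asarray(mask).astype(bool)
    if mask.shape != cube.data.shape[:2]:
        raise DimensionError("mask spatial shape does not match cube")
    data = cube.data * mask[:, :, None]
    return Hypercube(data, cube.grid, state="masked_reflectance", mask=mask)


def mean_spectrum(cube: Hypercube, mask: np.ndarray | None = None) -> np.ndarray:
    """Per-band arithmetic mean over foreground pixels only."""
    if mask is None:
        mask = cube.mask
    if mask is None:
        raise EmptySampleError("no mask given and cube carries none")
    mask = np.asarray(mask).astype(bool)
    if mask.shape != cube.data.shape[:2]:
        raise DimensionError("mask spatial shape does not match cube")
    if not mask.any():
        raise EmptySampleError("mask selects no foreground pixels")
    return cube.data[mask].mean(axis=0)
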