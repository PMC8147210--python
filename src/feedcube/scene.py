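"""Synthetic SWIR reflectance spectra and hypercube scenes.

The spectral model is a two-component absorption mixture on a gentle
baseline.  Water contributes Gaussian absorption lobes at the O-H stretching
second overtone (~1000 nm) and first overtone (~1450 nm); dry matter
(carbohydrate/protein C-H, N-H and aromatic C-H overtones) contributes lobes
near 1225, 1530 and 1660 nm.  A pixel at wet-basis moisture ``m`` reflects

    R(λ) = offset + slope * (baseline(λ) − m·A_water(λ) − (1−m)·A_dry(λ)) + ε(λ)

where (offset, slope) is an additive/multiplicative scatter pair and ε is
zero-mean Gaussian noise whose standard deviation is inflated above 1917 nm,
where SWIR detectors lose signal-to-noise.  Values are clipped to (0, 1.2].

A scene places a circular sample disk on a darker background, gives every
disk pixel its own moisture (the sample moisture plus a smooth zero-mean
random field) and its own scatter pair, and converts reflectance to raw
sensor counts via dark and white reference frames with a non-uniform
illumination profile — the exact inverse of reflectance calibration, so a
noise-free scene round-trips through calibration exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .design import SampleRecord
from .errors import DomainError
from .hypercube_io import Hypercube, WavelengthGrid, make_grid

__all__ = [
    "SceneConfig",
    "default_grid",
    "water_absorbance",
    "dry_absorbance",
    "baseline_reflectance",
    "synth_spectrum",
    "synth_scene",
    "synth_spectra_matrix",
]

#: noisy detector region starts here (nm)
HIGH_NOISE_CUTOFF_NM = 1917.0

# absorption lobes: (centre nm, width nm, depth)
_WATER_LOBES = ((1000.0, 40.0, 0.18), (1450.0, 55.0, 0.35))
_DRY_LOBES = ((1225.0, 45.0, 0.12), (1530.0, 50.0, 0.10), (1660.0, 50.0, 0.12))


def default_grid() -> WavelengthGrid:
    """The 275-band uniform 894-2504 nm sensor grid."""
    return make_grid(894.0, 2504.0, 275)


def _lobes(wl: np.ndarray, lobes) -> np.ndarray:
    a = np.zeros_like(wl, dtype=float)
    for centre, width, depth in lobes:
        a += depth * np.exp(-0.5 * ((wl - centre) / width) ** 2)
    return a


def water_absorbance(wl: np.ndarray) -> np.ndarray:
    """Water absorption profile: O-H overtone lobes near 1000 and 1450 nm."""
    return _lobes(np.asarray(wl, dtype=float), _WATER_LOBES)


def dry_absorbance(wl: np.ndarray) -> np.ndarray:
    """Dry-matter absorption profile: lobes near 1225, 1530 and 1660 nm."""
    return _lobes(np.asarray(wl, dtype=float), _DRY_LOBES)


def baseline_reflectance(wl: np.ndarray) -> np.ndarray:
    """Absorption-free reflectance: bright with a gentle downward tilt."""
    wl = np.asarray(wl, dtype=float)
    return 0.90 - 0.08 * (wl - 894.0) / (2504.0 - 894.0)


def _noise_sigma(wl: np.ndarray, floor: float, high_mult: float) -> np.ndarray:
    sigma = np.full(wl.shape, float(floor))
    sigma[wl > HIGH_NOISE_CUTOFF_NM] *= float(high_mult)
    return sigma


def synth_spectrum(
    M_wb: float,
    grid: WavelengthGrid,
    scatter: tuple[float, float] = (0.0, 1.0),
    seed: int | None = None,
    noise_floor: float = 0.0,
    high_band_noise_mult: float = 5.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """One reflectance spectrum at moisture ``M_wb`` on ``grid``.

    ``scatter`` is the additive/multiplicative pair (offset, slope).  The
    function is pure: identical arguments and seed give identical vectors.
    """
    if not (0.0 <= M_wb < 1.0):
        raise DomainError(f"moisture fraction must be in [0, 1), got {M_wb}")
    wl = grid.band_centers
    offset, slope = scatter
    clean = baseline_reflectance(wl) - M_wb * water_absorbance(wl) - (1.0 - M_wb) * dry_absorbance(wl)
    refl = offset + slope * clean
    if noise_floor > 0.0:
        if rng is None:
            rng = np.random.default_rng(seed)
        refl = refl + rng.normal(0.0, _noise_sigma(wl, noise_floor, high_band_noise_mult))
    return np.clip(refl, 1e-9, 1.2)


@dataclass(frozen=True)
class SceneConfig:
    """Geometry, optics and noise of one synthetic scene.

    ``field_amplitude`` is the standard deviation (moisture fraction) of the
    smooth per-pixel moisture field inside the disk; 0.03 emulates the uneven
    moisture spread visible in real feed samples.  ``noise_floor`` is the
    reflectance noise s.d. below 1917 nm.
    """

    height: int = 64
    width: int = 64
    disk_radius: int = 22
    grid: WavelengthGrid = field(default_factory=default_grid)
    background_level: float = 0.12
    scatter_offset_range: tuple[float, float] = (-0.02, 0.02)
    scatter_slope_range: tuple[float, float] = (0.95, 1.05)
    noise_floor: float = 0.002
    high_band_noise_mult: float = 5.0
    field_smoothness: float = 8.0  # Gaussian sigma, pixels
    field_amplitude: float = 0.03  # moisture-fraction s.d. inside the disk
    white_level: float = 4000.0  # counts at unit illumination
    dark_level: float = 100.0  # dark-current counts
    seed: int = 0

    def __post_init__(self) -> None:
        if self.disk_radius <= 0 or 2 * self.disk_radius >= min(self.height, self.width):
            raise DomainError("disk must fit inside the image")
        if self.noise_floor < 0 or self.high_band_noise_mult <= 0:
            raise DomainError("noise parameters must be positive")


def _disk_mask(cfg: SceneConfig) -> np.ndarray:
    cy, cx = (cfg.height - 1) / 2.0, (cfg.width - 1) / 2.0
    yy, xx = np.mgrid[0 : cfg.height, 0 : cfg.width]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= cfg.disk_radius**2


def _moisture_field(M_wb: float, mask: np.ndarray, cfg: SceneConfig, rng) -> np.ndarray:
    """Smooth per-pixel moisture with disk mean exactly ``M_wb``."""
    field2d = rng.standard_normal(mask.shape)
    if cfg.field_smoothness > 0:
        field2d = ndimage.gaussian_filter(field2d, cfg.field_smoothness)
    if cfg.field_amplitude > 0:
        sd = field2d[mask].std()
        field2d = field2d * (cfg.field_amplitude / sd) if sd > 0 else 0.0 * field2d
    else:
        field2d = np.zeros_like(field2d)
    m = M_wb + field2d
    m = np.clip(m, 0.0, 0.99)
    m = m - (m[mask].mean() - M_wb)  # re-centre after clipping
    return np.clip(m, 0.0, 0.999)


def synth_scene(
    sample: SampleRecord | float,
    cfg: SceneConfig,
) -> tuple[Hypercube, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Build one raw-count scene for a sample.

    Returns ``(raw cube, white frame, dark frame, truth moisture image,
    true mask)``.  The truth image holds moisture fractions on the disk and
    NaN on the background; the disk mean equals the sample moisture to 1e-6.
    Raw counts are ``reflectance * (white - dark) + dark`` per pixel/band, so
    calibration inverts the construction exactly when noise is zero.
    """
    M_wb = sample.M_wb if isinstance(sample, SampleRecord) else float(sample)
    if not (0.0 <= M_wb < 1.0):
        raise DomainError(f"moisture fraction must be in [0, 1), got {M_wb}")
    rng = np.random.default_rng(cfg.seed)
    wl = cfg.grid.band_centers
    h, w, k = cfg.height, cfg.width, cfg.grid.count

    mask = _disk_mask(cfg)
    m_img = _moisture_field(M_wb, mask, cfg, rng)

    # reflectance is affine in per-pixel moisture
    base = baseline_reflectance(wl) - dry_absorbance(wl)  # at m = 0
    coef = water_absorbance(wl) - dry_absorbance(wl)  # depression per unit m
    offset = rng.uniform(*cfg.scatter_offset_range, size=(h, w))
    slope = rng.uniform(*cfg.scatter_slope_range, size=(h, w))
    refl = offset[:, :, None] + slope[:, :, None] * (
        base[None, None, :] - m_img[:, :, None] * coef[None, None, :]
    )
    bg = np.full(k, cfg.background_level)
    refl[~mask] = bg
    if cfg.noise_floor > 0:
        sigma = _noise_sigma(wl, cfg.noise_floor, cfg.high_band_noise_mult)
        refl = refl + rng.normal(0.0, 1.0, size=refl.shape) * sigma[None, None, :]
    refl = np.clip(refl, 1e-9, 1.2)

    # reference frames: smooth non-uniform illumination, small positive dark
    yy, xx = np.mgrid[0:h, 0:w]
    illum = 0.9 + 0.2 * np.exp(
        -(((yy - h / 2) / (0.8 * h)) ** 2 + ((xx - w / 2) / (0.8 * w)) ** 2)
    )
    lamp = 1.0 - 0.25 * (wl - wl[0]) / (wl[-1] - wl[0])  # lamp rolls off with λ
    white = cfg.white_level * illum[:, :, None] * lamp[None, None, :]
    dark = np.full((h, w, k), cfg.dark_level)
    if cfg.noise_floor > 0:
        dark = dark + rng.normal(0.0, 40.0 * cfg.noise_floor, size=dark.shape)
    white = white + dark

    raw = refl * (white - dark) + dark
    truth = np.where(mask, m_img, np.nan)
    cube = Hypercube(raw, cfg.grid, state="raw_counts")
    return cube, white, dark, truth, mask


def synth_spectra_matrix(
    moistures: np.ndarray,
    grid: WavelengthGrid,
    seed: int = 0,
    noise_floor: float = 0.002,
    high_band_noise_mult: float = 5.0,
    scatter_offset_range: tuple[float, float] = (-0.02, 0.02),
    scatter_slope_range: tuple[float, float] = (0.95, 1.05),
) -> np.ndarray:
    """N spectra with independent per-sample scatter and noise.

    Fast path for model experiments that do not need full images: each row is
    one :func:`synth_spectrum` draw at the corresponding moisture fraction.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for m in np.asarray(moistures, dtype=float):
        scatter = (
            rng.uniform(*scatter_offset_range),
            rng.uniform(*scatter_slope_range),
        )
        rows.append(
            synth_spectrum(
                m,
                grid,
                scatter=scatter,
                noise_floor=noise_floor,
                high_band_noise_mult=high_band_noise_mult,
                rng=rng,
            )
        )
    return np.vstack(rows)
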