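"""Pixel-wise moisture maps and feed-management decision rules.

A masked reflectance cube is unfolded into pixel spectra, each pixel is
preprocessed with the model's frozen transform and multiplied by the
regression (beta) coefficients, and the predictions are folded back into a
2-D image.  Background pixels carry NaN — never 0 — so a genuinely bone-dry
pixel stays representable.  A mask-aware 3×3 median filter cleans the map
for display.

Decision rules follow feed-management practice: moisture above the high cut
(default 40 %) or below the low cut (default 20 %) sends the batch back for
water-content retreatment; anything between is acceptable for feeding.  Cuts
are exclusive — exactly 20 % or 40 % is accepted.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .errors import DecisionError, DomainError, ModelCompatibilityError
from .hypercube_io import Hypercube
from .pls import PLSModel, predict

__all__ = [
    "MoistureMap",
    "DecisionRule",
    "predict_map",
    "median_filter_3x3",
    "render_map",
    "classify_batch",
]


@dataclass
class MoistureMap:
    """Per-pixel predicted moisture in percent; NaN marks background."""

    values: np.ndarray
    mask: np.ndarray
    display_range: tuple[float, float] = (0.0, 80.0)
    provenance: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask).astype(bool)
        if self.values.shape != self.mask.shape:
            raise DomainError("map and mask shapes differ")
        if not np.all(np.isfinite(self.values[self.mask])):
            raise DomainError("foreground moisture values must be finite")

    @property
    def masked_mean(self) -> float:
        if not self.mask.any():
            raise DecisionError("map has no foreground pixels")
        return float(self.values[self.mask].mean())


@dataclass(frozen=True)
class DecisionRule:
    """Acceptable moisture window for feeding/storage decisions."""

    low_cut: float = 20.0
    high_cut: float = 40.0
    context: str = "farm"

    def __post_init__(self) -> None:
        if not self.low_cut < self.high_cut:
            raise DomainError("low_cut must be below high_cut")
        if self.context not in ("factory", "farm"):
            raise DomainError(f"unknown context {self.context!r}")


def predict_map(cube: Hypercube, model: PLSModel) -> MoistureMap:
    """Apply a fitted model to every foreground pixel of a masked cube."""
    if cube.mask is None:
        raise ModelCompatibilityError("cube carries no mask; apply_mask first")
    if model.grid is not None and (
        model.grid.count != cube.grid.count
        or not np.allclose(model.grid.band_centers, cube.grid.band_centers, atol=1e-6)
    ):
        # model trained on a band subset of the cube grid is also accepted
        if model.band_indices is None or np.max(model.band_indices, initial=-1) >= cube.grid.count or not np.allclose(
            cube.grid.band_centers[model.band_indices], model.grid.band_centers, atol=1e-6
        ):
            raise ModelCompatibilityError("cube wavelength grid does not match the model")
    values = np.full(cube.data.shape[:2], np.nan)
    mask = cube.mask
    if mask.any():
        pixels = cube.data[mask]
        if model.band_indices is not None:
            pixels = pixels[:, model.band_indices]
        if pixels.shape[1] != model.beta.shape[0]:
            raise ModelCompatibilityError(
                f"pixel spectra have {pixels.shape[1]} bands, model expects {model.beta.shape[0]}"
            )
        if model.method is not None:
            pixels = model.method.apply(pixels)
        values[mask] = predict(model, pixels)
    return MoistureMap(values, mask)


def median_filter_3x3(mmap: MoistureMap) -> MoistureMap:
    """3×3 median over foreground neighbourhoods; background excluded.

    Each foreground pixel becomes the median of the in-mask pixels in its
    3×3 neighbourhood (itself included); background pixels stay NaN.
    """
    v = mmap.values
    padded = np.pad(v, 1, constant_values=np.nan)
    stack = np.stack(
        [padded[dy : dy + v.shape[0], dx : dx + v.shape[1]] for dy in range(3) for dx in range(3)]
    )
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN windows off-mask
        med = np.nanmedian(stack, axis=0)
    out = np.where(mmap.mask, med, np.nan)
    return MoistureMap(out, mmap.mask, mmap.display_range, mmap.provenance)


def render_map(
    mmap: MoistureMap,
    path: str | Path,
    colormap: str = "viridis",
    display_range: tuple[float, float] | None = None,
) -> Path:
    """Render the map to PNG with a colour bar; background in neutral grey.

    Values are clipped to the display range before colour lookup; output
    bytes are deterministic for identical inputs.
    """
    lo, hi = display_range if display_range is not None else mmap.display_range
    if not lo < hi:
        raise DomainError("display range must satisfy lo < hi")
    shown = np.clip(mmap.values, lo, hi)
    shown = np.ma.masked_array(shown, ~mmap.mask)
    cmap = plt.get_cmap(colormap).copy()
    cmap.set_bad("0.85")
    fig, ax = plt.subplots(figsize=(4.5, 4))
    im = ax.imshow(shown, cmap=cmap, vmin=lo, vmax=hi, interpolation="nearest")
    ax.set_xticks([])
    ax.set_yticks([])
    fig.colorbar(im, ax=ax, label="moisture (% wet basis)")
    path = Path(path)
    fig.savefig(path, dpi=100, metadata={"Software": "feedcube"})
    plt.close(fig)
    return path


def classify_batch(sample: MoistureMap | float, rule: DecisionRule = DecisionRule()) -> str:
    """Feed-management decision for a sample or a whole map.

    For a map the decision statistic is the masked mean.  Returns
    ``retreat_high`` above the high cut, ``retreat_low`` below the low cut,
    and ``accept`` inside the window (cut values inclusive of accept).
    """
    value = sample.masked_mean if isinstance(sample, MoistureMap) else float(sample)
    if value > rule.high_cut:
        return "retreat_high"
    if value < rule.low_cut:
        return "retreat_low"
    return "accept"
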