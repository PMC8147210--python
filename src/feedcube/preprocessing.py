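"""Spectral preprocessing transforms.

Eight row-wise treatments of an N × K spectra matrix: raw passthrough,
mean/max/range normalisation, multiplicative scatter correction (MSC),
standard normal variate (SNV), and Savitzky-Golay first and second
derivatives.  All transforms are local to a row once fitted — MSC estimates
its reference spectrum from the calibration set and freezes it — which is
what makes pixel-wise application possible at mapping time.

Definitions follow standard chemometrics practice:

- mean:   x / mean(x)
- max:    x / max(x)
- range:  (x − min(x)) / (max(x) − min(x))
- SNV:    (x − mean(x)) / sd(x), sample (n−1) standard deviation
- MSC:    ordinary least squares of x on the reference, x = b0 + b1·ref + e,
          corrected row = (x − b0) / b1
- SG d-th derivative: local polynomial least squares in a symmetric window,
  derivative of the fit at the centre, per nanometre; edges by polynomial
  extrapolation of the edge windows.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import savgol_filter

from .errors import (
    DegenerateSpectrumError,
    DimensionError,
    ParameterError,
    ScatterCorrectionError,
)
from .hypercube_io import WavelengthGrid

__all__ = [
    "METHOD_KINDS",
    "SpectraTable",
    "PreprocessMethod",
    "FittedPreprocess",
    "normalize_mean",
    "normalize_max",
    "normalize_range",
    "msc",
    "snv",
    "savgol",
    "preprocess",
]

METHOD_KINDS = ("raw", "mean", "max", "range", "msc", "snv", "sg1", "sg2")


@dataclass
class SpectraTable:
    """N spectra paired with a wet-basis moisture response in percent."""

    X: np.ndarray
    grid: WavelengthGrid
    y: np.ndarray
    sample_ids: list[str] = field(default_factory=list)
    transform: "FittedPreprocess | None" = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.X.ndim != 2:
            raise DimensionError("X must be 2-D (samples x bands)")
        if self.X.shape[1] != self.grid.count:
            raise DimensionError(
                f"X has {self.X.shape[1]} bands but grid has {self.grid.count}"
            )
        if self.y.shape != (self.X.shape[0],):
            raise DimensionError("y length must equal the number of spectra")
        if not self.sample_ids:
            self.sample_ids = [str(i) for i in range(self.X.shape[0])]
        if len(self.sample_ids) != self.X.shape[0]:
            raise DimensionError("sample_ids length must equal the number of spectra")
        if not (np.all(np.isfinite(self.X)) and np.all(np.isfinite(self.y))):
            raise DimensionError("spectra table contains non-finite entries")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    def subset_bands(self, indices: np.ndarray) -> "SpectraTable":
        """Restrict to a band subset (e.g. the 894-1917 nm window)."""
        indices = np.asarray(indices, dtype=int)
        return SpectraTable(
            self.X[:, indices],
            WavelengthGrid(self.grid.band_centers[indices]),
            self.y,
            list(self.sample_ids),
        )

    def take(self, rows: np.ndarray) -> "SpectraTable":
        rows = np.asarray(rows, dtype=int)
        return SpectraTable(
            self.X[rows],
            self.grid,
            self.y[rows],
            [self.sample_ids[i] for i in rows],
        )


@dataclass(frozen=True)
class PreprocessMethod:
    """A preprocessing choice plus its parameters.

    Savitzky-Golay defaults: window 11 with polynomial order 2 for the first
    derivative and order 3 for the second (set ``sg_polyorder`` explicitly to
    override).  ``msc_reference`` of ``"mean-of-calibration"`` freezes the
    calibration-set mean spectrum at fit time.
    """

    kind: str = "raw"
    sg_window: int = 11
    sg_polyorder: int | None = None
    msc_reference: str = "mean-of-calibration"

    def __post_init__(self) -> None:
        if self.kind not in METHOD_KINDS:
            raise ParameterError(f"unknown preprocessing kind {self.kind!r}")
        if self.kind in ("sg1", "sg2"):
            order = self.polyorder
            deriv = 1 if self.kind == "sg1" else 2
            if self.sg_window % 2 == 0 or self.sg_window <= order:
                raise ParameterError("sg_window must be odd and exceed the polyorder")
            if order < deriv:
                raise ParameterError("sg_polyorder must be >= the derivative order")

    @property
    def polyorder(self) -> int:
        if self.sg_polyorder is not None:
            return self.sg_polyorder
        return 2 if self.kind == "sg1" else 3


def _rows(x: np.ndarray) -> tuple[np.ndarray, bool]:
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        return x[None, :], True
    if x.ndim != 2:
        raise DimensionError("expected a spectrum or a matrix of spectra")
    return x, False


def normalize_mean(x: np.ndarray) -> np.ndarray:
    """Divide each spectrum by its mean."""
    X, squeeze = _rows(x)
    denom = X.mean(axis=1, keepdims=True)
    if np.any(np.abs(denom) < 1e-300):
        raise DegenerateSpectrumError("zero-mean spectrum cannot be mean-normalised")
    out = X / denom
    return out[0] if squeeze else out


def normalize_max(x: np.ndarray) -> np.ndarray:
    """Divide each spectrum by its maximum."""
    X, squeeze = _rows(x)
    denom = X.max(axis=1, keepdims=True)
    if np.any(np.abs(denom) < 1e-300):
        raise DegenerateSpectrumError("zero-max spectrum cannot be max-normalised")
    out = X / denom
    return out[0] if squeeze else out


def normalize_range(x: np.ndarray) -> np.ndarray:
    """Min-max scale each spectrum to [0, 1]."""
    X, squeeze = _rows(x)
    lo = X.min(axis=1, keepdims=True)
    hi = X.max(axis=1, keepdims=True)
    if np.any(hi - lo <= 0):
        raise DegenerateSpectrumError("constant spectrum has no range")
    out = (X - lo) / (hi - lo)
    return out[0] if squeeze else out


def msc(X: np.ndarray, reference: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Multiplicative scatter correction against a reference spectrum.

    Each row is regressed on the reference by ordinary least squares,
    ``x = b0 + b1 * ref + e``, and corrected as ``(x − b0) / b1``.  Returns
    the corrected matrix and the per-row ``(b0, b1)`` coefficients.
    """
    X, squeeze = _rows(X)
    ref = np.asarray(reference, dtype=float)
    if ref.shape != (X.shape[1],):
        raise DimensionError("reference length must equal the band count")
    ref_c = ref - ref.mean()
    var = float(ref_c @ ref_c)
    if var <= 0:
        raise ScatterCorrectionError("constant MSC reference")
    b1 = (X - X.mean(axis=1, keepdims=True)) @ ref_c / var
    if np.any(np.abs(b1) < 1e-12):
        bad = int(np.argmin(np.abs(b1)))
        raise ScatterCorrectionError(f"near-zero MSC slope for row {bad}")
    b0 = X.mean(axis=1) - b1 * ref.mean()
    corrected = (X - b0[:, None]) / b1[:, None]
    coeffs = np.column_stack([b0, b1])
    if squeeze:
        return corrected[0], coeffs[0]
    return corrected, coeffs


def snv(x: np.ndarray) -> np.ndarray:
    """Standard normal variate: centre and scale each spectrum to unit sd."""
    X, squeeze = _rows(x)
    sd = X.std(axis=1, ddof=1, keepdims=True)
    if np.any(sd <= 0):
        raise DegenerateSpectrumError("constant spectrum has zero standard deviation")
    out = (X - X.mean(axis=1, keepdims=True)) / sd
    return out[0] if squeeze else out


def savgol(
    X: np.ndarray,
    window: int,
    polyorder: int,
    deriv: int,
    delta: float = 1.0,
) -> np.ndarray:
    """Savitzky-Golay derivative of each spectrum, per ``delta`` nm."""
    Xr, squeeze = _rows(X)
    if window % 2 == 0 or window <= polyorder:
        raise ParameterError("window must be odd and exceed polyorder")
    if polyorder < deriv:
        raise ParameterError("polyorder must be >= deriv")
    if Xr.shape[1] < window:
        raise ParameterError("spectrum shorter than the filter window")
    out = savgol_filter(
        Xr, window_length=window, polyorder=polyorder, deriv=deriv,
        delta=delta, axis=1, mode="interp",
    )
    return out[0] if squeeze else out


@dataclass
class FittedPreprocess:
    """A preprocessing transform frozen for row-local reuse.

    For MSC the calibration reference spectrum is stored; for the SG
    derivatives the grid spacing.  ``apply`` is strictly row-local, so the
    same object serves tabular spectra and unfolded pixel spectra alike.
    """

    method: PreprocessMethod
    reference: np.ndarray | None = None
    delta: float = 1.0

    def apply(self, X: np.ndarray) -> np.ndarray:
        kind = self.method.kind
        if kind == "raw":
            return np.asarray(X, dtype=float).copy()
        if kind == "mean":
            return normalize_mean(X)
        if kind == "max":
            return normalize_max(X)
        if kind == "range":
            return normalize_range(X)
        if kind == "snv":
            return snv(X)
        if kind == "msc":
            if self.reference is None:
                raise ScatterCorrectionError("MSC transform has no frozen reference")
            corrected, _ = msc(X, self.reference)
            return corrected
        deriv = 1 if kind == "sg1" else 2
        return savgol(X, self.method.sg_window, self.method.polyorder, deriv, self.delta)


def fit_preprocess(
    method: PreprocessMethod,
    calibration: SpectraTable | None = None,
) -> FittedPreprocess:
    """Freeze a transform's fit-time artifacts from a calibration table."""
    reference = None
    delta = 1.0
    if method.kind == "msc":
        if isinstance(method.msc_reference, str):
            if calibration is None:
                raise ScatterCorrectionError(
                    "MSC with 'mean-of-calibration' needs a calibration table"
                )
            reference = calibration.X.mean(axis=0)
        else:  # pragma: no cover - explicit reference path
            reference = np.asarray(method.msc_reference, dtype=float)
    if method.kind in ("sg1", "sg2") and calibration is not None:
        delta = calibration.grid.spacing
    return FittedPreprocess(method, reference=reference, delta=delta)


def preprocess(
    table: SpectraTable,
    method: PreprocessMethod,
    fitted: FittedPreprocess | None = None,
) -> SpectraTable:
    """Transform a spectra table row-wise; grid and response are unchanged.

    When ``fitted`` is None the transform is fitted on ``table`` itself
    (calibration usage); pass the calibration-set transform to apply the same
    frozen artifacts to validation rows or pixels.  The fitted transform is
    stored on the returned table's ``transform`` attribute.
    """
    if fitted is None:
        fitted = fit_preprocess(method, table)
    out = SpectraTable(
        fitted.apply(table.X), table.grid, table.y, list(table.sample_ids)
    )
    out.transform = fitted
    return out
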