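"""Preprocessing: transverse averaging, offset baseline, Savitzky-Golay second
derivatives, spectral-region masking, and OD-profile resampling.

All spectrum-matrix operations take spectra as rows of a 2-D array alongside
the shared wavenumber grid.  Savitzky-Golay derivatives leave the
``(window - 1) / 2`` edge points as NaN: the derivative filter is undefined
there and downstream peak reads skip them.  The transformer classes follow the
scikit-learn ``fit``/``transform`` protocol so they compose into pipelines;
the module-level functions are thin wrappers over them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import savgol_coeffs
from sklearn.base import BaseEstimator, TransformerMixin

from .spectral import ODProfile, SpectralImage

__all__ = [
    "RegionMask",
    "DerivativeConfig",
    "default_region_mask",
    "transverse_average",
    "offset_baseline_correct",
    "second_derivative",
    "apply_mask",
    "match_and_resample",
    "OffsetBaselineCorrector",
    "SavitzkyGolayDerivative",
    "RegionMasker",
    "SpectralPipeline",
]

BASELINE_RANGE = (1000.0, 1700.0)


@dataclass(frozen=True)
class RegionMask:
    """Included wavenumber intervals (cm^-1), inclusive at both ends.

    The default keeps 1000-1440 and 1480-1700 and drops 1440-1480, the band
    where residual embedding paraffin absorbs.
    """

    intervals: tuple[tuple[float, float], ...] = ((1000.0, 1440.0), (1480.0, 1700.0))

    def __post_init__(self) -> None:
        prev_hi = -np.inf
        for lo, hi in self.intervals:
            if lo >= hi:
                raise ValueError("mask intervals must have lo < hi")
            if lo <= prev_hi:
                raise ValueError("mask intervals must be ascending and non-overlapping")
            prev_hi = hi

    def selector(self, wavenumbers: np.ndarray) -> np.ndarray:
        """Boolean column selector over a wavenumber grid."""
        wavenumbers = np.asarray(wavenumbers, dtype=float)
        keep = np.zeros(wavenumbers.shape, dtype=bool)
        for lo, hi in self.intervals:
            keep |= (wavenumbers >= lo) & (wavenumbers <= hi)
        return keep


def default_region_mask() -> RegionMask:
    return RegionMask()


@dataclass(frozen=True)
class DerivativeConfig:
    """Savitzky-Golay derivative settings (7-point window by default)."""

    window_points: int = 7
    polynomial_order: int = 2
    derivative_order: int = 2

    def __post_init__(self) -> None:
        if self.window_points % 2 == 0 or self.window_points < 3:
            raise ValueError("window_points must be odd and >= 3")
        if not self.derivative_order <= self.polynomial_order < self.window_points:
            raise ValueError("need derivative_order <= polynomial_order < window_points")


def transverse_average(image: SpectralImage) -> np.ndarray:
    """Average an image parallel to the articular surface.

    Returns the (n_depth, n_wavenumbers) matrix of row-mean spectra; row i is
    the arithmetic mean over all columns of image row i.
    """
    return image.absorbance.mean(axis=1)


def _as_2d(spectra: np.ndarray) -> tuple[np.ndarray, bool]:
    spectra = np.asarray(spectra, dtype=float)
    if spectra.ndim == 1:
        return spectra[None, :], True
    if spectra.ndim != 2:
        raise ValueError("spectra must be 1-D or 2-D")
    return spectra, False


class OffsetBaselineCorrector(TransformerMixin, BaseEstimator):
    """Offset baseline correction: subtract each spectrum's minimum over the
    analysis range (default 1000-1700 cm^-1, the union of the model regions)."""

    def __init__(self, wavenumbers=None, anchor_lo: float = BASELINE_RANGE[0],
                 anchor_hi: float = BASELINE_RANGE[1]):
        self.wavenumbers = wavenumbers
        self.anchor_lo = anchor_lo
        self.anchor_hi = anchor_hi

    def fit(self, X, y=None):
        return self

    def transform(self, X):
        X, squeeze = _as_2d(X)
        if np.all(np.isnan(X)):
            raise ValueError("all-NaN spectrum")
        wn = np.asarray(self.wavenumbers, dtype=float) if self.wavenumbers is not None else None
        if wn is not None:
            sel = (wn >= self.anchor_lo) & (wn <= self.anchor_hi)
            if not sel.any():
                sel = np.ones_like(wn, dtype=bool)
        else:
            sel = np.ones(X.shape[1], dtype=bool)
        out = X - np.nanmin(X[:, sel], axis=1, keepdims=True)
        return out[0] if squeeze else out


def offset_baseline_correct(spectra: np.ndarray,
                            wavenumbers: np.ndarray | None = None) -> np.ndarray:
    return OffsetBaselineCorrector(wavenumbers=wavenumbers).transform(spectra)


class SavitzkyGolayDerivative(TransformerMixin, BaseEstimator):
    """Savitzky-Golay derivative filter on a uniform wavenumber grid.

    Interior points carry the least-squares polynomial derivative scaled by
    1 / h**deriv (units per (cm^-1)**deriv); the (window-1)/2 points at each
    edge are NaN.
    """

    def __init__(self, wavenumbers=None, config: DerivativeConfig | None = None):
        self.wavenumbers = wavenumbers
        self.config = config

    def _grid_step(self) -> float:
        wn = np.asarray(self.wavenumbers, dtype=float)
        steps = np.diff(wn)
        h = steps.mean()
        if np.any(np.abs(steps - h) > 1e-6 * abs(h)):
            raise ValueError("Savitzky-Golay derivative requires a uniform wavenumber grid")
        return float(h)

    def fit(self, X, y=None):
        return self

    def transform(self, X):
        cfg = self.config or DerivativeConfig()
        X, squeeze = _as_2d(X)
        if X.shape[1] < cfg.window_points:
            raise ValueError("spectrum shorter than the derivative window")
        h = self._grid_step()
        coeffs = savgol_coeffs(cfg.window_points, cfg.polynomial_order,
                               deriv=cfg.derivative_order, delta=h, use="dot")
        half = cfg.window_points // 2
        out = np.full_like(X, np.nan)
        # valid (interior) convolution; edges stay NaN by design
        for k in range(cfg.window_points):
            seg = X[:, k:X.shape[1] - cfg.window_points + 1 + k]
            if k == 0:
                acc = coeffs[k] * seg
            else:
                acc = acc + coeffs[k] * seg
        out[:, half:X.shape[1] - half] = acc
        return out[0] if squeeze else out


def second_derivative(spectra: np.ndarray, wavenumbers: np.ndarray,
                      config: DerivativeConfig | None = None) -> np.ndarray:
    return SavitzkyGolayDerivative(wavenumbers=wavenumbers, config=config).transform(spectra)


class RegionMasker(TransformerMixin, BaseEstimator):
    """Restrict spectra to the wavenumber columns inside a :class:`RegionMask`."""

    def __init__(self, wavenumbers=None, mask: RegionMask | None = None):
        self.wavenumbers = wavenumbers
        self.mask = mask

    def fit(self, X=None, y=None):
        mask = self.mask or default_region_mask()
        wn = np.asarray(self.wavenumbers, dtype=float)
        self.selector_ = mask.selector(wn)
        if not self.selector_.any():
            raise ValueError("region mask excludes every wavenumber")
        self.kept_wavenumbers_ = wn[self.selector_]
        return self

    def transform(self, X):
        if not hasattr(self, "selector_"):
            self.fit()
        X, squeeze = _as_2d(X)
        out = X[:, self.selector_]
        return out[0] if squeeze else out


def apply_mask(spectra: np.ndarray, wavenumbers: np.ndarray,
               mask: RegionMask | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Apply a region mask; returns (masked spectra, kept wavenumbers)."""
    masker = RegionMasker(wavenumbers=wavenumbers, mask=mask).fit()
    return masker.transform(spectra), masker.kept_wavenumbers_


def match_and_resample(od: ODProfile | np.ndarray, n_target: int) -> np.ndarray:
    """Resample an OD depth profile onto ``n_target`` points.

    Surface and bone junction are aligned: the first and last OD samples map
    exactly to the first and last target points, interior values by linear
    interpolation on the normalised depth [0, 1].  This resolves the ~5 um
    densitometry vs 25 um FT-IR pitch mismatch so that each depth-wise
    spectrum receives exactly one reference value.
    """
    values = od.od if isinstance(od, ODProfile) else np.asarray(od, dtype=float)
    if n_target < 2:
        raise ValueError("n_target must be at least 2")
    if values.size < 2:
        raise ValueError("profile must contain at least 2 samples")
    source = np.linspace(0.0, 1.0, values.size)
    target = np.linspace(0.0, 1.0, n_target)
    return np.interp(target, source, values)


@dataclass
class SpectralPipeline:
    """The preprocessing chain shared by calibration and image prediction.

    ``domain`` selects the multivariate input representation: offset-corrected
    absorbance (default) or Savitzky-Golay second derivative.  The same object
    must be used to build the training matrix and to preprocess images at
    prediction time so that the variable grid matches the fitted model.
    """

    wavenumbers: np.ndarray
    domain: str = "absorbance"
    mask: RegionMask = field(default_factory=default_region_mask)
    derivative: DerivativeConfig = field(default_factory=DerivativeConfig)

    def __post_init__(self) -> None:
        if self.domain not in ("absorbance", "second_derivative"):
            raise ValueError("domain must be 'absorbance' or 'second_derivative'")
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)

    @property
    def variable_wavenumbers(self) -> np.ndarray:
        return RegionMasker(self.wavenumbers, self.mask).fit().kept_wavenumbers_

    def transform(self, spectra: np.ndarray) -> np.ndarray:
        """Map raw spectra (rows) to the masked model-variable matrix."""
        corrected = offset_baseline_correct(spectra, self.wavenumbers)
        if self.domain == "second_derivative":
            corrected = second_derivative(corrected, self.wavenumbers, self.derivative)
        masked, _ = apply_mask(corrected, self.wavenumbers, self.mask)
        if np.any(np.isnan(masked)):
            raise ValueError("masked variables contain undefined (edge) derivative points; "
                             "widen the grid or narrow the mask")
        return masked
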