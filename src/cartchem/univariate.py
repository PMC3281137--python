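"""Univariate FT-IR proteoglycan parameters and their linear OD calibration.

Four classical PG surrogates are computed per depth point:

* ``carb_area`` — integrated absorbance of the carbohydrate region
  (984-1140 cm^-1), trapezoid rule on the native grid;
* ``carb_amide_ratio`` — the same area normalised by the amide I area
  (1584-1720 cm^-1);
* ``d2_1062`` / ``d2_1374`` — depths of the second-derivative peaks at
  1062 cm^-1 (sulphate) and 1374 cm^-1 (CH3), reported as the negated
  derivative value at the located minimum so that larger = more PG.

Each parameter is converted to predicted OD by ordinary least squares against
the densitometry reference.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin

from .preprocess import second_derivative  # noqa: F401  (re-exported convenience)

__all__ = [
    "integrate_band",
    "carb_amide_ratio",
    "deriv_peak_intensity",
    "UnivariateODCalibration",
    "univariate_calibrate",
    "parameter_table",
    "CARB_BAND",
    "AMIDE_I_BAND",
]

CARB_BAND = (984.0, 1140.0)
AMIDE_I_BAND = (1584.0, 1720.0)
RATIO_TOL = 1e-12


def integrate_band(spectrum: np.ndarray, wavenumbers: np.ndarray,
                   lo_cm: float = CARB_BAND[0], hi_cm: float = CARB_BAND[1]) -> np.ndarray:
    """Trapezoidal band area over grid points in [lo_cm, hi_cm] inclusive.

    Accepts a single spectrum or a matrix of row spectra; returns a scalar or
    a vector of areas in absorbance * cm^-1.
    """
    wavenumbers = np.asarray(wavenumbers, dtype=float)
    spectrum = np.asarray(spectrum, dtype=float)
    sel = (wavenumbers >= lo_cm) & (wavenumbers <= hi_cm)
    if sel.sum() < 2:
        raise ValueError("integration band must cover at least 2 grid points")
    area = np.trapezoid(spectrum[..., sel], wavenumbers[sel], axis=-1)
    return area


def carb_amide_ratio(spectrum: np.ndarray, wavenumbers: np.ndarray) -> np.ndarray:
    """Carbohydrate area divided by amide I area."""
    carb = integrate_band(spectrum, wavenumbers, *CARB_BAND)
    amide = integrate_band(spectrum, wavenumbers, *AMIDE_I_BAND)
    if np.any(np.abs(amide) <= RATIO_TOL):
        raise ValueError("amide I area is (near-)zero: carbohydrate/amide ratio undefined")
    return carb / amide


def deriv_peak_intensity(deriv_spectrum: np.ndarray, wavenumbers: np.ndarray,
                         center_cm: float, half_window_cm: float = 8.0) -> np.ndarray:
    """Depth of the second-derivative absorption peak nearest ``center_cm``.

    Searches the valid (non-NaN) derivative points within +/- half_window_cm
    of the centre for the deepest minimum of the raw derivative (ties broken
    toward the centre) and returns the negated value there, so absorption
    peaks come out positive.  A flat spectrum returns 0.
    """
    wavenumbers = np.asarray(wavenumbers, dtype=float)
    deriv = np.asarray(deriv_spectrum, dtype=float)
    sel = (wavenumbers >= center_cm - half_window_cm) & (wavenumbers <= center_cm + half_window_cm)
    if not sel.any():
        raise ValueError("peak search window lies outside the wavenumber grid")
    window = deriv[..., sel]
    wn = wavenumbers[sel]
    if np.all(np.isnan(window)):
        raise ValueError("no valid derivative points in the peak search window "
                         "(all edge points)")

    def _one(row: np.ndarray) -> float:
        valid = ~np.isnan(row)
        vals = row[valid]
        locs = wn[valid]
        depth = -vals  # negated: absorption minima become positive depths
        best = depth.max()
        candidates = np.flatnonzero(depth >= best - 0.0)
        nearest = candidates[np.argmin(np.abs(locs[candidates] - center_cm))]
        return float(depth[nearest])

    if window.ndim == 1:
        return _one(window)
    return np.array([_one(row) for row in window])


class UnivariateODCalibration(RegressorMixin, BaseEstimator):
    """Ordinary least squares conversion of one spectral parameter to OD.

    Fitted attributes: ``slope_``, ``intercept_``, ``rmse_`` (training RMSE in
    OD units).
    """

    def fit(self, X, y):
        param = np.asarray(X, dtype=float).reshape(-1)
        od = np.asarray(y, dtype=float).reshape(-1)
        if param.size != od.size:
            raise ValueError("parameter and OD vectors must have equal length")
        if param.size < 3:
            raise ValueError("need at least 3 points for a linear calibration")
        if np.ptp(param) <= 0:
            raise ValueError("constant parameter: degenerate linear fit")
        slope, intercept = np.polyfit(param, od, 1)
        self.slope_ = float(slope)
        self.intercept_ = float(intercept)
        residual = od - self.predict(param)
        self.rmse_ = float(np.sqrt(np.mean(residual ** 2)))
        return self

    def predict(self, X):
        param = np.asarray(X, dtype=float).reshape(-1)
        return self.slope_ * param + self.intercept_


def univariate_calibrate(param_values, od_values):
    """OLS of OD on a univariate parameter.

    Returns ``(slope, intercept, predicted_od, rmse)``.
    """
    model = UnivariateODCalibration().fit(param_values, od_values)
    predicted = model.predict(param_values)
    return model.slope_, model.intercept_, predicted, model.rmse_


def parameter_table(corrected_spectra: np.ndarray,
                    deriv_spectra: np.ndarray,
                    wavenumbers: np.ndarray,
                    sample_ids=None,
                    od_ref=None) -> pd.DataFrame:
    """Per-depth-point table of the four univariate PG parameters.

    ``corrected_spectra`` are offset-baseline-corrected absorbance rows;
    ``deriv_spectra`` their Savitzky-Golay second derivatives on the same grid.
    """
    corrected_spectra = np.atleast_2d(np.asarray(corrected_spectra, dtype=float))
    deriv_spectra = np.atleast_2d(np.asarray(deriv_spectra, dtype=float))
    n = corrected_spectra.shape[0]
    table = pd.DataFrame({
        "sample_id": np.asarray(sample_ids) if sample_ids is not None else np.repeat("", n),
        "depth_index": np.arange(n),
        "carb_area": integrate_band(corrected_spectra, wavenumbers, *CARB_BAND),
        "carb_amide_ratio": carb_amide_ratio(corrected_spectra, wavenumbers),
        "d2_1062": deriv_peak_intensity(deriv_spectra, wavenumbers, 1062.0),
        "d2_1374": deriv_peak_intensity(deriv_spectra, wavenumbers, 1374.0),
    })
    if od_ref is not None:
        table["od_ref"] = np.asarray(od_ref, dtype=float)
    return table
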