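"""Core data containers and text I/O for FT-IR spectral images and OD profiles.

Conventions
-----------
* Depth coordinate: 0 um at the articular surface, increasing toward the
  cartilage-bone interface.  Row index 0 of a :class:`SpectralImage` is the
  surface row.
* Optical density (OD) is the Safranin-O digital-densitometry readout; the
  densitometer is calibrated over 0-3 OD, so profiles outside that range are
  rejected on read.
* CSV dialect is fixed (comma separated, ``.`` decimal, UTF-8) so that
  write -> read round-trips are bit-stable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SpectralImage",
    "ODProfile",
    "CalibrationDataset",
    "read_spectral_image",
    "write_spectral_image",
    "read_od_profile",
    "write_od_profile",
]

OD_MIN = 0.0
OD_MAX = 3.0


def _require_ascending(values: np.ndarray, name: str) -> None:
    if values.ndim != 1 or values.size < 1:
        raise ValueError(f"{name} must be a non-empty 1-D array")
    if np.any(np.diff(values) <= 0):
        raise ValueError(f"{name} must be strictly ascending")


@dataclass
class SpectralImage:
    """Absorbance hyperspectral image on a (row, column, wavenumber) grid.

    Parameters
    ----------
    wavenumbers : ndarray, shape (n_wavenumbers,)
        Strictly ascending grid in cm^-1.
    absorbance : ndarray, shape (n_rows, n_cols, n_wavenumbers)
        Absorbance units; must be finite.
    pixel_pitch_um : float
        Physical pixel pitch in micrometres.
    sample_id, group : str
        Provenance labels ("control" / "depleted" for phantom studies).
    """

    wavenumbers: np.ndarray
    absorbance: np.ndarray
    pixel_pitch_um: float = 25.0
    sample_id: str = ""
    group: str = ""

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        _require_ascending(self.wavenumbers, "wavenumbers")
        if self.absorbance.ndim != 3:
            raise ValueError("absorbance must have shape (n_rows, n_cols, n_wavenumbers)")
        if self.absorbance.shape[2] != self.wavenumbers.size:
            raise ValueError("absorbance last axis must match wavenumber grid length")
        if self.absorbance.shape[0] < 1 or self.absorbance.shape[1] < 1:
            raise ValueError("image must contain at least one pixel")
        if not np.all(np.isfinite(self.absorbance)):
            raise ValueError("absorbance contains non-finite values")
        if self.pixel_pitch_um <= 0:
            raise ValueError("pixel_pitch_um must be positive")

    @property
    def n_rows(self) -> int:
        return self.absorbance.shape[0]

    @property
    def n_cols(self) -> int:
        return self.absorbance.shape[1]

    @property
    def depth_um(self) -> np.ndarray:
        """Depth of each row centre below the articular surface."""
        return np.arange(self.n_rows) * self.pixel_pitch_um


@dataclass
class ODProfile:
    """Depth-wise Safranin-O optical density reference profile."""

    depth_um: np.ndarray
    od: np.ndarray
    sample_id: str = ""

    def __post_init__(self) -> None:
        self.depth_um = np.asarray(self.depth_um, dtype=float)
        self.od = np.asarray(self.od, dtype=float)
        _require_ascending(self.depth_um, "depth_um")
        if self.od.shape != self.depth_um.shape:
            raise ValueError("depth_um and od must have equal lengths")
        if not np.all(np.isfinite(self.od)):
            raise ValueError("od contains non-finite values")
        if np.any(self.od < OD_MIN) or np.any(self.od > OD_MAX):
            raise ValueError(f"od values must lie within the calibrated range [{OD_MIN}, {OD_MAX}]")


@dataclass
class CalibrationDataset:
    """Matched (preprocessed spectrum, OD) pairs used to train calibrations.

    ``X`` rows are depth points pooled over samples; ``y`` is the resampled
    Safranin-O OD at the same depth.  ``stratum`` carries the OD-stratum label
    assigned by the stratified-selection rule (empty string before selection).
    """

    X: np.ndarray
    y: np.ndarray
    sample_ids: np.ndarray
    wavenumbers: np.ndarray
    stratum: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.sample_ids = np.asarray(self.sample_ids)
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        if self.stratum is None:
            self.stratum = np.full(self.y.shape, "", dtype=object)
        self.stratum = np.asarray(self.stratum)
        n = self.X.shape[0]
        if self.y.shape != (n,) or self.sample_ids.shape != (n,) or self.stratum.shape != (n,):
            raise ValueError("X, y, sample_ids and stratum row counts must agree")
        if self.X.shape[1] != self.wavenumbers.size:
            raise ValueError("X column count must match wavenumber grid")
        if not (np.all(np.isfinite(self.X)) and np.all(np.isfinite(self.y))):
            raise ValueError("calibration data contains missing values")
        if np.any(self.y < OD_MIN) or np.any(self.y > OD_MAX):
            raise ValueError("reference OD outside [0, 3]")

    def __len__(self) -> int:
        return self.X.shape[0]

    def subset(self, indices: np.ndarray) -> "CalibrationDataset":
        indices = np.asarray(indices)
        return CalibrationDataset(
            X=self.X[indices],
            y=self.y[indices],
            sample_ids=self.sample_ids[indices],
            wavenumbers=self.wavenumbers,
            stratum=self.stratum[indices],
        )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_spectral_image(image: SpectralImage, path: str | Path) -> None:
    """Write an image as CSV: columns ``row,col,<wavenumber>...``, one pixel per line."""
    n_rows, n_cols, n_wn = image.absorbance.shape
    rows, cols = np.meshgrid(np.arange(n_rows), np.arange(n_cols), indexing="ij")
    flat = image.absorbance.reshape(n_rows * n_cols, n_wn)
    df = pd.DataFrame(flat, columns=[repr(float(w)) for w in image.wavenumbers])
    df.insert(0, "col", cols.ravel())
    df.insert(0, "row", rows.ravel())
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(f"# pixel_pitch_um={image.pixel_pitch_um!r} sample_id={image.sample_id} group={image.group}\n")
        df.to_csv(fh, index=False, lineterminator="\n", float_format="%.17g")


def read_spectral_image(path: str | Path) -> SpectralImage:
    """Read a CSV spectral image written by :func:`write_spectral_image`."""
    with open(path, "r", encoding="utf-8") as fh:
        first = fh.readline()
    meta: dict[str, str] = {}
    skip = 0
    if first.startswith("#"):
        skip = 1
        for token in first[1:].split():
            if "=" in token:
                key, _, value = token.partition("=")
                meta[key] = value
    df = pd.read_csv(path, skiprows=skip, float_precision="round_trip")
    if df.isna().any().any():
        raise ValueError("spectral image file contains missing (NaN) cells")
    wn_cols = [c for c in df.columns if c not in ("row", "col")]
    try:
        wavenumbers = np.array([float(c) for c in wn_cols])
    except ValueError as exc:
        raise ValueError("wavenumber header must be numeric") from exc
    _require_ascending(wavenumbers, "wavenumber header")
    rows = df["row"].to_numpy(dtype=int)
    cols = df["col"].to_numpy(dtype=int)
    n_rows, n_cols = rows.max() + 1, cols.max() + 1
    if len(df) != n_rows * n_cols:
        raise ValueError("ragged image: pixel rows do not fill the (row, col) grid")
    cube = np.empty((n_rows, n_cols, wavenumbers.size))
    cube[rows, cols] = df[wn_cols].to_numpy(dtype=float)
    return SpectralImage(
        wavenumbers=wavenumbers,
        absorbance=cube,
        pixel_pitch_um=float(meta.get("pixel_pitch_um", 25.0)),
        sample_id=meta.get("sample_id", ""),
        group=meta.get("group", ""),
    )


def write_od_profile(profile: ODProfile, path: str | Path) -> None:
    df = pd.DataFrame({"depth_um": profile.depth_um, "od": profile.od})
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(f"# sample_id={profile.sample_id}\n")
        df.to_csv(fh, index=False, lineterminator="\n", float_format="%.17g")


def write_spectral_image_tiff(image: SpectralImage, path: str | Path) -> None:
    """Write an image as a multi-page float32 TIFF, one page per wavenumber.

    Wavenumbers and pixel pitch go into the page description; this export is
    for viewing in image software and is lossy (float32), unlike the CSV form.
    """
    import tifffile

    pages = np.moveaxis(image.absorbance, 2, 0).astype(np.float32)
    description = (f"sample_id={image.sample_id} group={image.group} "
                   f"pixel_pitch_um={image.pixel_pitch_um} "
                   f"wavenumbers={','.join(repr(float(w)) for w in image.wavenumbers)}")
    tifffile.imwrite(path, pages, description=description)


def write_od_map_tiff(od_map: np.ndarray, path: str | Path) -> None:
    """Write a predicted OD map as a single-page float32 greyscale TIFF."""
    import tifffile

    tifffile.imwrite(path, np.asarray(od_map, dtype=np.float32))


def read_od_profile(path: str | Path) -> ODProfile:
    with open(path, "r", encoding="utf-8") as fh:
        first = fh.readline()
    sample_id = ""
    skip = 0
    if first.startswith("#"):
        skip = 1
        for token in first[1:].split():
            if token.startswith("sample_id="):
                sample_id = token.partition("=")[2]
    df = pd.read_csv(path, skiprows=skip, float_precision="round_trip")
    if list(df.columns) != ["depth_um", "od"]:
        raise ValueError("OD profile file must have exactly the columns depth_um, od")
    return ODProfile(
        depth_um=df["depth_um"].to_numpy(dtype=float),
        od=df["od"].to_numpy(dtype=float),
        sample_id=sample_id,
    )
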