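"""Synthetic cartilage-section FT-IR phantoms with known ground truth.

The generator emulates the measurement that motivates the calibration problem:
a 400-um-wide strip of articular cartilage imaged in transmission at 25 um
pixel pitch and 4 cm^-1 spectral resolution, with a Safranin-O optical-density
(OD) depth profile as the proteoglycan (PG) reference.  Absorbance follows a
Beer-Lambert mixture of three Gaussian-sum basis spectra:

* PG: sulphate band at 1062 cm^-1, CH3 band at 1374 cm^-1, and a broad
  carbohydrate mass over ~1030-1120 cm^-1;
* collagen: amide I at 1655 cm^-1, amide II at 1550 cm^-1, plus 1240 and
  1080 cm^-1 contributions that overlap the carbohydrate region — the overlap
  that defeats univariate PG estimation;
* residual paraffin: a band confined to 1440-1480 cm^-1 (the region excluded
  from multivariate models).

Sections carry a multiplicative thickness factor drawn once per virtual
section (microtome section-to-section thickness variation); pixels carry
additive zero-mean noise with SD = single-scan SD / sqrt(averaged scans).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .spectral import ODProfile, SpectralImage

__all__ = [
    "BasisSpectra",
    "CompositionPhantom",
    "AcquisitionConfig",
    "PhantomConfig",
    "DEFAULT_PEAKS",
    "make_basis_spectra",
    "make_composition_phantom",
    "render_spectral_image",
    "render_od_reference",
    "make_study_samples",
]

logger = logging.getLogger(__name__)

CONTROL = "control"
DEPLETED = "depleted"

PARAFFIN_BAND = (1440.0, 1480.0)

#: Default Gaussian peak table: component -> list of (centre cm^-1, sigma cm^-1, height).
DEFAULT_PEAKS: dict[str, list[tuple[float, float, float]]] = {
    "pg": [(1062.0, 14.0, 1.0), (1374.0, 10.0, 0.5), (1080.0, 45.0, 0.5)],
    "collagen": [(1655.0, 25.0, 1.0), (1550.0, 25.0, 0.75),
                 (1240.0, 20.0, 0.35), (1080.0, 30.0, 0.95)],
    "paraffin": [(1462.0, 8.0, 1.0)],
}


@dataclass
class BasisSpectra:
    """Absorptivity-per-unit-concentration curves on a common wavenumber grid."""

    wavenumbers: np.ndarray
    pg_epsilon: np.ndarray
    collagen_epsilon: np.ndarray
    paraffin_epsilon: np.ndarray

    def __post_init__(self) -> None:
        for name in ("pg_epsilon", "collagen_epsilon", "paraffin_epsilon"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != np.shape(self.wavenumbers):
                raise ValueError(f"{name} must match the wavenumber grid")
            if np.any(arr < 0):
                raise ValueError(f"{name} must be non-negative")
            setattr(self, name, arr)


@dataclass
class CompositionPhantom:
    """Known depth-wise PG and collagen concentration profiles (arbitrary units)."""

    depth_um: np.ndarray
    pg_profile: np.ndarray
    collagen_profile: np.ndarray
    group: str = CONTROL
    sample_id: str = ""

    def __post_init__(self) -> None:
        if np.any(self.pg_profile < 0) or np.any(self.collagen_profile < 0):
            raise ValueError("concentration profiles must be non-negative")
        if self.group not in (CONTROL, DEPLETED):
            raise ValueError(f"unknown group {self.group!r}")


@dataclass
class AcquisitionConfig:
    """FT-IR imaging acquisition statistics.

    ``noise_sd_single_scan`` is the additive absorbance noise SD of one scan;
    averaging ``scans_per_pixel`` scans divides it by sqrt(scans).
    ``thickness_cv`` is the coefficient of variation of the per-section
    multiplicative (lognormal) thickness factor.
    """

    pixel_pitch_um: float = 25.0
    strip_width_um: float = 400.0
    scans_per_pixel: int = 8
    noise_sd_single_scan: float = 0.15
    thickness_cv: float = 0.10
    paraffin_level_max: float = 0.04
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.pixel_pitch_um, self.strip_width_um) <= 0 or self.scans_per_pixel < 1:
            raise ValueError("acquisition geometry parameters must be positive")
        if self.noise_sd_single_scan < 0 or self.thickness_cv < 0:
            raise ValueError("noise and thickness CV must be non-negative")
        if abs(self.strip_width_um / self.pixel_pitch_um
               - round(self.strip_width_um / self.pixel_pitch_um)) > 1e-9:
            raise ValueError("strip_width_um must be an integer multiple of pixel_pitch_um")

    @property
    def n_cols(self) -> int:
        return int(round(self.strip_width_um / self.pixel_pitch_um))

    @property
    def pixel_noise_sd(self) -> float:
        return self.noise_sd_single_scan / np.sqrt(self.scans_per_pixel)


@dataclass
class PhantomConfig:
    """Parametric depth-composition curves for one virtual cartilage section.

    The control PG profile is a logistic rise from a depleted superficial zone
    (``pg_surface``) to a plateau (``pg_plateau``) with midpoint
    ``pg_midpoint_um`` and width ``pg_width_um``; collagen rises monotonically
    from ``collagen_surface`` to ``collagen_deep`` as (z/Z)^gamma.
    """

    pg_surface: float = 0.12
    pg_plateau: float = 1.0
    pg_midpoint_um: float = 150.0
    pg_width_um: float = 55.0
    collagen_surface: float = 0.45
    collagen_deep: float = 1.40
    collagen_gamma: float = 1.3
    collagen_depth_varying: bool = True
    # between-sample biological variability: multiplicative lognormal SDs on
    # the PG plateau, the overall collagen level, and the deep-zone collagen
    # rise; the collagen depth-gradient (deep level and curvature) varies
    # between animals, which is what defeats depth-blind univariate bands
    pg_level_sd: float = 0.12
    collagen_level_sd: float = 0.05
    collagen_deep_sd: float = 0.35
    collagen_gamma_jitter: float = 0.5
    midpoint_jitter_um: float = 40.0


def _gaussian_sum(wavenumbers: np.ndarray,
                  peaks: list[tuple[float, float, float]]) -> np.ndarray:
    out = np.zeros_like(wavenumbers, dtype=float)
    for center, width, height in peaks:
        if width <= 0 or height <= 0:
            raise ValueError("peak widths and heights must be positive")
        if not (wavenumbers[0] <= center <= wavenumbers[-1]):
            raise ValueError(f"peak centre {center} outside wavenumber grid")
        out += height * np.exp(-0.5 * ((wavenumbers - center) / width) ** 2)
    return out


def make_basis_spectra(peak_config: dict[str, list[tuple[float, float, float]]] | None = None,
                       wavenumbers: np.ndarray | None = None) -> BasisSpectra:
    """Build Gaussian-sum basis spectra.

    ``peak_config`` maps ``"pg"``, ``"collagen"``, ``"paraffin"`` to lists of
    (centre, sigma, height).  An empty list yields an all-zero absorptivity for
    that component.  A non-empty PG list must place peaks near both 1062 and
    1374 cm^-1; paraffin peaks must lie inside 1440-1480 cm^-1 and their tails
    are truncated to that band so the excluded-region structure is exact.
    """
    if wavenumbers is None:
        wavenumbers = np.arange(900.0, 1800.0 + 1e-9, 4.0)
    wavenumbers = np.asarray(wavenumbers, dtype=float)
    peaks = dict(DEFAULT_PEAKS if peak_config is None else peak_config)
    for key in ("pg", "collagen", "paraffin"):
        peaks.setdefault(key, [])

    pg_peaks = peaks["pg"]
    if pg_peaks:
        for target in (1062.0, 1374.0):
            if not any(abs(c - target) <= 8.0 for c, _, _ in pg_peaks):
                raise ValueError(f"PG basis must contain a peak within 8 cm^-1 of {target:g}")
    for center, _, _ in peaks["paraffin"]:
        if not (PARAFFIN_BAND[0] <= center <= PARAFFIN_BAND[1]):
            raise ValueError("paraffin peaks must lie inside 1440-1480 cm^-1")

    paraffin = _gaussian_sum(wavenumbers, peaks["paraffin"])
    inside = (wavenumbers >= PARAFFIN_BAND[0]) & (wavenumbers <= PARAFFIN_BAND[1])
    paraffin = np.where(inside, paraffin, 0.0)

    return BasisSpectra(
        wavenumbers=wavenumbers,
        pg_epsilon=_gaussian_sum(wavenumbers, pg_peaks),
        collagen_epsilon=_gaussian_sum(wavenumbers, peaks["collagen"]),
        paraffin_epsilon=paraffin,
    )


def make_composition_phantom(n_depth: int = 60,
                             group: str = CONTROL,
                             depletion_fraction: float = 0.35,
                             seed: int | np.random.Generator = 0,
                             pixel_pitch_um: float = 25.0,
                             config: PhantomConfig | None = None,
                             sample_id: str = "") -> CompositionPhantom:
    """Generate a depth-composition phantom for one virtual section.

    A ``"depleted"`` phantom has its PG profile zeroed over the superficial
    ``depletion_fraction`` of the total depth (emulating enzymatic digestion of
    superficial glycosaminoglycans) and is otherwise identical to the control
    drawn with the same seed.
    """
    if n_depth < 10:
        raise ValueError("n_depth must be at least 10")
    if not 0.0 <= depletion_fraction <= 1.0:
        raise ValueError("depletion_fraction must lie in [0, 1]")
    cfg = config or PhantomConfig()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    depth = np.arange(n_depth) * pixel_pitch_um
    total = depth[-1] if depth[-1] > 0 else 1.0

    pg_level = cfg.pg_plateau * rng.lognormal(0.0, cfg.pg_level_sd)
    col_level = rng.lognormal(0.0, cfg.collagen_level_sd)
    deep_level = cfg.collagen_deep * rng.lognormal(0.0, cfg.collagen_deep_sd)
    gamma = cfg.collagen_gamma * np.exp(rng.uniform(-cfg.collagen_gamma_jitter,
                                                    cfg.collagen_gamma_jitter))
    midpoint = cfg.pg_midpoint_um + rng.uniform(-cfg.midpoint_jitter_um, cfg.midpoint_jitter_um)

    pg = cfg.pg_surface + (pg_level - cfg.pg_surface) / (
        1.0 + np.exp(-(depth - midpoint) / cfg.pg_width_um))
    if cfg.collagen_depth_varying:
        collagen = cfg.collagen_surface + (max(deep_level, cfg.collagen_surface)
                                           - cfg.collagen_surface) * (depth / total) ** gamma
    else:
        collagen = np.full_like(depth, 0.5 * (cfg.collagen_surface + cfg.collagen_deep))
    collagen = collagen * col_level

    if group == DEPLETED:
        pg = np.where(depth < depletion_fraction * (total + pixel_pitch_um), 0.0, pg)
    return CompositionPhantom(depth_um=depth, pg_profile=np.maximum(pg, 0.0),
                              collagen_profile=collagen, group=group, sample_id=sample_id)


def render_spectral_image(phantom: CompositionPhantom,
                          basis: BasisSpectra,
                          acq: AcquisitionConfig,
                          rng: np.random.Generator | None = None) -> SpectralImage:
    """Beer-Lambert forward model: concentrations x basis + thickness + noise.

    Noiseless absorbance at pixel (i, j), wavenumber v is
    ``t * (pg(i) eps_pg(v) + col(i) eps_col(v) + paraffin eps_par(v))`` where
    ``t`` is a single lognormal thickness factor for the whole section and the
    paraffin level is a uniform draw in [0, paraffin_level_max].  Additive
    pixel noise has SD ``noise_sd_single_scan / sqrt(scans_per_pixel)``.
    """
    if not np.allclose(np.diff(phantom.depth_um), acq.pixel_pitch_um):
        raise ValueError("phantom depth axis pitch does not match acquisition pixel pitch")
    rng = rng if rng is not None else np.random.default_rng(acq.seed)

    if acq.thickness_cv > 0:
        sigma = np.sqrt(np.log1p(acq.thickness_cv ** 2))
        thickness = rng.lognormal(-0.5 * sigma ** 2, sigma)  # mean-1 lognormal
    else:
        thickness = 1.0
    paraffin_level = rng.uniform(0.0, acq.paraffin_level_max) if acq.paraffin_level_max > 0 else 0.0

    clean = (phantom.pg_profile[:, None] * basis.pg_epsilon[None, :]
             + phantom.collagen_profile[:, None] * basis.collagen_epsilon[None, :]
             + paraffin_level * basis.paraffin_epsilon[None, :])
    cube = np.repeat((thickness * clean)[:, None, :], acq.n_cols, axis=1)
    if acq.pixel_noise_sd > 0:
        cube = cube + rng.normal(0.0, acq.pixel_noise_sd, size=cube.shape)
    return SpectralImage(wavenumbers=basis.wavenumbers, absorbance=cube,
                         pixel_pitch_um=acq.pixel_pitch_um,
                         sample_id=phantom.sample_id, group=phantom.group)


def render_od_reference(phantom: CompositionPhantom,
                        od_pixel_um: float = 5.0,
                        n_sections: int = 3,
                        thickness_cv: float = 0.10,
                        od_scale: float = 2.3,
                        seed: int | np.random.Generator = 0) -> ODProfile:
    """Safranin-O densitometry reference: OD proportional to PG content.

    Each of ``n_sections`` virtual stained sections gets an independent
    lognormal thickness factor; the per-section OD curves are averaged
    (mirroring the three-section averaging of the reference measurement),
    resampled to ``od_pixel_um`` pitch, and clipped to the calibrated 0-3
    range.  A pre-clip OD above 3 is logged as a warning.
    """
    if od_scale <= 0:
        raise ValueError("od_scale must be positive")
    if n_sections < 1:
        raise ValueError("n_sections must be at least 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    fine_depth = np.arange(0.0, phantom.depth_um[-1] + 1e-9, od_pixel_um)
    fine_pg = np.interp(fine_depth, phantom.depth_um, phantom.pg_profile)

    if thickness_cv > 0:
        sigma = np.sqrt(np.log1p(thickness_cv ** 2))
        factors = rng.lognormal(-0.5 * sigma ** 2, sigma, size=n_sections)
    else:
        factors = np.ones(n_sections)
    od = od_scale * fine_pg * np.mean(factors)
    if np.any(od > 3.0):
        logger.warning("sample %s: OD exceeds the 0-3 calibrated range before clipping "
                       "(max %.3f); clipping", phantom.sample_id, float(od.max()))
    od = np.clip(od, 0.0, 3.0)
    return ODProfile(depth_um=fine_depth, od=od, sample_id=phantom.sample_id)


@dataclass
class StudySample:
    """One virtual specimen: phantom ground truth, FT-IR image, OD reference."""

    phantom: CompositionPhantom
    image: SpectralImage
    od: ODProfile


def make_study_samples(n_per_group: int = 8,
                       seed: int = 0,
                       n_depth: int = 60,
                       depletion_fraction: float = 0.35,
                       acq: AcquisitionConfig | None = None,
                       phantom_config: PhantomConfig | None = None,
                       basis: BasisSpectra | None = None,
                       od_scale: float = 2.3,
                       od_sections: int = 3) -> list[StudySample]:
    """Generate the default study material: ``n_per_group`` controls and
    ``n_per_group`` enzymatically depleted virtual samples with paired
    references, all randomness derived from one root seed."""
    acq = acq or AcquisitionConfig()
    basis = basis or make_basis_spectra()
    root = np.random.SeedSequence(seed)
    samples: list[StudySample] = []
    for group, prefix in ((CONTROL, "C"), (DEPLETED, "E")):
        for i in range(n_per_group):
            child = np.random.default_rng(root.spawn(1)[0])
            sample_id = f"{prefix}{i + 1:02d}"
            phantom = make_composition_phantom(
                n_depth=n_depth, group=group,
                depletion_fraction=depletion_fraction if group == DEPLETED else 0.0,
                seed=child, pixel_pitch_um=acq.pixel_pitch_um,
                config=phantom_config, sample_id=sample_id)
            image = render_spectral_image(phantom, basis, acq, rng=child)
            od = render_od_reference(phantom, thickness_cv=acq.thickness_cv,
                                     od_scale=od_scale, n_sections=od_sections,
                                     seed=child)
            samples.append(StudySample(phantom=phantom, image=image, od=od))
    return samples
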