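"""End-to-end synthetic calibration study.

Mirrors the measurement campaign the package models: generate control and
enzymatically PG-depleted virtual cartilage sections with paired Safranin-O
references, hold one sample of each group out of all model fitting,
preprocess and pool the rest into a calibration set (optionally stratified
over the OD range), fit the four univariate calibrations and the PLSR / PCR
models with LOO-CV component selection, compare all six predictors, and
demonstrate the final PLSR model on the held-out images.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import chemometrics as chem
from . import compare as cmp
from .preprocess import (DerivativeConfig, SpectralPipeline, match_and_resample,
                         offset_baseline_correct, second_derivative,
                         transverse_average)
from .spectral import (CalibrationDataset, write_od_map_tiff, write_od_profile,
                       write_spectral_image)
from .synth import (AcquisitionConfig, PhantomConfig, StudySample,
                    make_basis_spectra, make_study_samples)
from .univariate import parameter_table, univariate_calibrate

logger = logging.getLogger(__name__)

__all__ = ["StudyConfig", "StudyResult", "run_study", "build_calibration_dataset"]

UNIVARIATE_PARAMS = ("carb_area", "carb_amide_ratio", "d2_1062", "d2_1374")


@dataclass
class StudyConfig:
    """Full configuration of the synthetic study; YAML round-trippable."""

    seed: int = 0
    samples_per_group: int = 8
    heldout_per_group: int = 1
    n_depth: int = 60
    depletion_fraction: float = 0.35
    od_scale: float = 2.3
    od_sections: int = 3
    acquisition: AcquisitionConfig = field(default_factory=AcquisitionConfig)
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    domain: str = "absorbance"
    derivative: DerivativeConfig = field(default_factory=DerivativeConfig)
    stratify: str = "auto"              # auto | on | off
    stratification: chem.StratificationRule = field(default_factory=chem.StratificationRule)
    k_max: int = 15
    selection_rel_tol: float = 0.02
    cv_unit: str = "point"              # point | sample
    comparison_preset: str = "all"      # all | adjacent7

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["stratification"]["full_range"] = list(self.stratification.full_range)
        data["stratification"]["boundaries"] = list(self.stratification.boundaries)
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "StudyConfig":
        data = dict(data)
        if "acquisition" in data and isinstance(data["acquisition"], dict):
            data["acquisition"] = AcquisitionConfig(**data["acquisition"])
        if "phantom" in data and isinstance(data["phantom"], dict):
            data["phantom"] = PhantomConfig(**data["phantom"])
        if "derivative" in data and isinstance(data["derivative"], dict):
            data["derivative"] = DerivativeConfig(**data["derivative"])
        if "stratification" in data and isinstance(data["stratification"], dict):
            s = dict(data["stratification"])
            if "full_range" in s:
                s["full_range"] = tuple(s["full_range"])
            if "boundaries" in s:
                s["boundaries"] = tuple(s["boundaries"])
            data["stratification"] = chem.StratificationRule(**s)
        return cls(**data)


@dataclass
class StudyResult:
    """Everything the study computes, in memory."""

    config: StudyConfig
    samples: list[StudySample]
    heldout: list[StudySample]
    dataset: CalibrationDataset
    selected: CalibrationDataset
    stratified: bool
    univariate_predictions: dict[str, np.ndarray]
    univariate_fits: pd.DataFrame
    cv_results: dict[str, chem.CVResult]
    report: cmp.MethodComparisonReport
    final_plsr: chem.NIPALSPLSRegression
    pipeline: SpectralPipeline
    heldout_metrics: pd.DataFrame
    heldout_profiles: dict[str, pd.DataFrame]
    heldout_maps: dict[str, np.ndarray]


def build_calibration_dataset(samples: list[StudySample],
                              pipeline: SpectralPipeline) -> tuple[CalibrationDataset, pd.DataFrame]:
    """Pool depth-wise (spectrum, OD) pairs over samples.

    Returns the calibration dataset of preprocessed masked variables and the
    univariate parameter table for the same depth points (kept on the raw
    grid, where the band integrals and derivative peaks live).
    """
    X_parts, y_parts, id_parts, tables = [], [], [], []
    for sample in samples:
        depth_spectra = transverse_average(sample.image)
        y = match_and_resample(sample.od, depth_spectra.shape[0])
        y = np.clip(y, 0.0, 3.0)
        X_parts.append(pipeline.transform(depth_spectra))
        y_parts.append(y)
        id_parts.append(np.repeat(sample.image.sample_id, depth_spectra.shape[0]))
        corrected = offset_baseline_correct(depth_spectra, sample.image.wavenumbers)
        deriv = second_derivative(corrected, sample.image.wavenumbers)
        tables.append(parameter_table(corrected, deriv, sample.image.wavenumbers,
                                      sample_ids=np.repeat(sample.image.sample_id,
                                                           depth_spectra.shape[0]),
                                      od_ref=y))
    dataset = CalibrationDataset(
        X=np.vstack(X_parts), y=np.concatenate(y_parts),
        sample_ids=np.concatenate(id_parts),
        wavenumbers=pipeline.variable_wavenumbers)
    table = pd.concat(tables, ignore_index=True)
    return dataset, table


def run_study(config: StudyConfig | None = None,
              outdir: str | Path | None = None) -> StudyResult:
    """Execute the full synthetic study; optionally write the output bundle."""
    config = config or StudyConfig()
    basis = make_basis_spectra()
    samples = make_study_samples(
        n_per_group=config.samples_per_group, seed=config.seed,
        n_depth=config.n_depth, depletion_fraction=config.depletion_fraction,
        acq=config.acquisition, phantom_config=config.phantom, basis=basis,
        od_scale=config.od_scale, od_sections=config.od_sections)

    h = config.heldout_per_group
    controls = [s for s in samples if s.image.group == "control"]
    depleted = [s for s in samples if s.image.group == "depleted"]
    if h >= len(controls) or h >= len(depleted):
        raise ValueError("held-out samples leave an empty training set")
    heldout = controls[-h:] + depleted[-h:] if h > 0 else []
    training = controls[:-h] + depleted[:-h] if h > 0 else samples

    pipeline = SpectralPipeline(wavenumbers=basis.wavenumbers, domain=config.domain,
                                derivative=config.derivative)
    dataset, uni_table = build_calibration_dataset(training, pipeline)

    # --- stratified calibration-set construction -------------------------
    stratified = False
    if config.stratify in ("on", "auto"):
        try:
            rule = chem.StratificationRule(
                full_range=config.stratification.full_range,
                boundaries=config.stratification.boundaries,
                draw_count=config.stratification.draw_count,
                seed=config.seed)
            idx = chem.stratified_select(dataset.y, rule)
            stratified = True
        except ValueError as exc:
            if config.stratify == "on":
                raise
            logger.info("stratification skipped (%s); using all %d points", exc, len(dataset))
            idx = np.arange(len(dataset))
    else:
        idx = np.arange(len(dataset))
    selected = dataset.subset(idx)
    selected.stratum = chem.stratum_labels(selected.y, config.stratification)
    uni_selected = uni_table.iloc[idx].reset_index(drop=True)

    # --- univariate calibrations ----------------------------------------
    uni_preds: dict[str, np.ndarray] = {}
    fit_rows = {}
    for name in UNIVARIATE_PARAMS:
        slope, intercept, predicted, rmse_val = univariate_calibrate(
            uni_selected[name].to_numpy(), selected.y)
        uni_preds[name] = predicted
        fit_rows[name] = {"slope": slope, "intercept": intercept, "rmse": rmse_val}
    uni_fits = pd.DataFrame(fit_rows).T

    # --- multivariate models with LOO-CV --------------------------------
    groups = selected.sample_ids if config.cv_unit == "sample" else None
    cv_results = {
        m: chem.loo_cv(selected.X, selected.y, method=m, k_max=config.k_max,
                       groups=groups, rel_tol=config.selection_rel_tol)
        for m in ("plsr", "pcr")}

    predictions = dict(uni_preds)
    predictions["plsr"] = cv_results["plsr"].selected_predictions
    predictions["pcr"] = cv_results["pcr"].selected_predictions
    comparisons = (list(cmp.ADJACENT_COMPARISONS)
                   if config.comparison_preset == "adjacent7" else None)
    report = cmp.build_comparison_report(predictions, selected.y, comparisons=comparisons)

    # --- held-out imaging demonstration ---------------------------------
    final_plsr = chem.NIPALSPLSRegression(
        n_components=cv_results["plsr"].selected_k).fit(selected.X, selected.y)
    heldout_rows = []
    heldout_profiles: dict[str, pd.DataFrame] = {}
    heldout_maps: dict[str, np.ndarray] = {}
    for sample in heldout:
        od_map, profile = chem.predict_image(final_plsr, sample.image, pipeline)
        heldout_maps[sample.image.sample_id] = od_map
        reference = match_and_resample(sample.od, profile.size)
        r, _ = cmp.pearson_r(profile, reference)
        depth = sample.image.depth_um
        third = max(1, profile.size // 3)
        heldout_rows.append({
            "sample_id": sample.image.sample_id,
            "group": sample.image.group,
            "r": r,
            "rmse": cmp.rmse(profile, reference),
            "superficial_pred": float(profile[:third].mean()),
            "deep_pred": float(profile[-third:].mean()),
        })
        heldout_profiles[sample.image.sample_id] = pd.DataFrame(
            {"depth_um": depth, "predicted_od": profile, "reference_od": reference})
    heldout_metrics = pd.DataFrame(heldout_rows)

    result = StudyResult(
        config=config, samples=samples, heldout=heldout, dataset=dataset,
        selected=selected, stratified=stratified,
        univariate_predictions=uni_preds, univariate_fits=uni_fits,
        cv_results=cv_results, report=report, final_plsr=final_plsr,
        pipeline=pipeline, heldout_metrics=heldout_metrics,
        heldout_profiles=heldout_profiles, heldout_maps=heldout_maps)
    if outdir is not None:
        write_study_bundle(result, Path(outdir))
    return result


def _calibration_frame(result: StudyResult) -> pd.DataFrame:
    sel = result.selected
    df = pd.DataFrame({"sample_id": sel.sample_ids, "od_ref": sel.y,
                       "stratum": sel.stratum})
    for name, pred in result.univariate_predictions.items():
        df[f"pred_{name}"] = pred
    df["pred_plsr"] = result.cv_results["plsr"].selected_predictions
    df["pred_pcr"] = result.cv_results["pcr"].selected_predictions
    return df


def write_study_bundle(result: StudyResult, outdir: Path) -> None:
    """Write datasets, model summaries, the comparison report, and figures."""
    outdir = Path(outdir)
    (outdir / "samples").mkdir(parents=True, exist_ok=True)
    result.config.to_yaml(outdir / "config.yaml")

    for sample in result.samples:
        sid = sample.image.sample_id
        write_spectral_image(sample.image, outdir / "samples" / f"{sid}_image.csv")
        write_od_profile(sample.od, outdir / "samples" / f"{sid}_od.csv")

    _calibration_frame(result).to_csv(outdir / "calibration.csv", index=False)
    result.univariate_fits.to_csv(outdir / "univariate_fits.csv")
    result.report.per_method.to_csv(outdir / "per_method.csv")
    result.report.comparisons.to_csv(outdir / "steiger_comparisons.csv", index=False)
    result.heldout_metrics.to_csv(outdir / "heldout_metrics.csv", index=False)
    for sid, profile in result.heldout_profiles.items():
        profile.to_csv(outdir / f"heldout_profile_{sid}.csv", index=False)
    for sid, od_map in result.heldout_maps.items():
        write_od_map_tiff(od_map, outdir / f"heldout_odmap_{sid}.tiff")
    pd.DataFrame({m: cv.rmsecv for m, cv in result.cv_results.items()},
                 index=np.arange(1, result.config.k_max + 1)).to_csv(
        outdir / "rmsecv.csv", index_label="k")

    summary = {
        "seed": result.config.seed,
        "n_calibration_points": int(len(result.selected)),
        "stratified": bool(result.stratified),
        "selected_k": {m: int(cv.selected_k) for m, cv in result.cv_results.items()},
        "rmsecv_at_selected_k": {m: float(cv.rmsecv[cv.selected_k - 1])
                                 for m, cv in result.cv_results.items()},
        "pearson_r": {m: float(v) for m, v in result.report.per_method["r"].items()},
        "bonferroni_threshold": float(result.report.bonferroni_threshold),
        "mean_relative_error": {m: float(v)
                                for m, v in result.report.mean_relative_error.items()},
    }
    with open(outdir / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2)
    _write_figures(result, outdir)


def _write_figures(result: StudyResult, outdir: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots()
    ks = np.arange(1, result.config.k_max + 1)
    for m, cv in result.cv_results.items():
        ax.plot(ks, cv.rmsecv, marker="o", label=f"{m.upper()} (k={cv.selected_k})")
    ax.set_xlabel("number of components")
    ax.set_ylabel("RMSECV (OD)")
    ax.legend()
    fig.savefig(outdir / "rmsecv.png", dpi=120)
    plt.close(fig)

    methods = list(result.report.per_method.index)
    preds = dict(result.univariate_predictions)
    preds["plsr"] = result.cv_results["plsr"].selected_predictions
    preds["pcr"] = result.cv_results["pcr"].selected_predictions
    fig, axes = plt.subplots(2, 3, figsize=(12, 7), sharex=True, sharey=True)
    for ax, m in zip(axes.ravel(), methods):
        ax.plot(result.selected.y, preds[m], ".", ms=2)
        lim = [0, 3]
        ax.plot(lim, lim, "k--", lw=0.7)
        ax.set_title(f"{m} (r={result.report.per_method.loc[m, 'r']:.3f})")
    fig.supxlabel("reference OD")
    fig.supylabel("predicted OD")
    fig.savefig(outdir / "scatter.png", dpi=120)
    plt.close(fig)

    if result.heldout_profiles:
        fig, axes = plt.subplots(1, len(result.heldout_profiles),
                                 figsize=(5 * len(result.heldout_profiles), 4),
                                 squeeze=False)
        for ax, (sid, prof) in zip(axes.ravel(), result.heldout_profiles.items()):
            ax.plot(prof["depth_um"], prof["reference_od"], "r-", label="densitometry")
            ax.plot(prof["depth_um"], prof["predicted_od"], "k-", label="PLSR")
            ax.set_title(sid)
            ax.set_xlabel("depth (um)")
            ax.set_ylabel("OD")
            ax.legend()
        fig.savefig(outdir / "heldout_profiles.png", dpi=120)
        plt.close(fig)
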