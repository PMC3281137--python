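"""Statistical comparison of PG predictors: Pearson correlations, Steiger's
test for dependent overlapping correlations, Bonferroni correction, RMSE and
relative-error-vs-OD summaries.

All predictors are compared against the same densitometry reference, so their
correlations with it are dependent (they share the reference variable).
Steiger's Z (overlapping case, pooled-r Fisher transform) is the appropriate
two-correlation test; with several pairwise tests the family-wise error is
controlled by Bonferroni.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "pearson_r",
    "steiger_test",
    "bonferroni",
    "rmse",
    "relative_error_profile",
    "MethodComparisonReport",
    "build_comparison_report",
    "ADJACENT_COMPARISONS",
    "DEFAULT_OD_BINS",
]

DEFAULT_OD_BINS = (0.0, 1.5, 2.0, 2.15, np.inf)
RELATIVE_ERROR_EPSILON = 0.05

#: The seven performance-adjacent comparisons the headline analysis reports:
#: within-family contrasts plus each family's best against the next family.
ADJACENT_COMPARISONS: tuple[tuple[str, str], ...] = (
    ("carb_area", "carb_amide_ratio"),
    ("d2_1374", "d2_1062"),
    ("d2_1062", "carb_area"),
    ("d2_1374", "carb_area"),
    ("plsr", "d2_1374"),
    ("pcr", "d2_1374"),
    ("plsr", "pcr"),
)


def pearson_r(x, y) -> tuple[float, float]:
    """Sample Pearson correlation with a two-sided t-test p-value (n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3 or x.size != y.size:
        raise ValueError("need two equal-length vectors with n >= 3")
    if np.ptp(x) <= 0 or np.ptp(y) <= 0:
        raise ValueError("Pearson correlation undefined for constant input")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def steiger_test(r_jk: float, r_jh: float, r_kh: float, n: int) -> tuple[float, float]:
    """Steiger's Z for two dependent correlations sharing variable j.

    ``r_jk`` and ``r_jh`` are the correlations being compared (reference j
    with predictors k and h); ``r_kh`` is the correlation between the two
    predictors.  Uses the pooled-r variant: Fisher-z difference scaled by the
    asymptotic standard error with covariance driven by ``r_kh``.  Two-sided
    p from the standard normal.
    """
    for r in (r_jk, r_jh, r_kh):
        if abs(r) >= 1.0:
            raise ValueError("|r| = 1 gives an infinite Fisher z; test undefined")
    if n < 10:
        raise ValueError("Steiger's test requires n >= 10")
    z_jk = np.arctanh(r_jk)
    z_jh = np.arctanh(r_jh)
    r_bar = 0.5 * (r_jk + r_jh)
    psi = r_kh * (1.0 - 2.0 * r_bar ** 2) - 0.5 * r_bar ** 2 * (
        1.0 - 2.0 * r_bar ** 2 - r_kh ** 2)
    c_bar = psi / (1.0 - r_bar ** 2) ** 2
    z = (z_jk - z_jh) * np.sqrt((n - 3.0) / (2.0 - 2.0 * c_bar))
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)


def bonferroni(p_values, alpha: float = 0.05, n_comparisons: int = 7):
    """Bonferroni decisions: significant iff p < alpha / n_comparisons.

    Returns ``(decisions, threshold)``.
    """
    if n_comparisons < 1:
        raise ValueError("n_comparisons must be >= 1")
    threshold = alpha / n_comparisons
    p = np.asarray(p_values, dtype=float)
    return p < threshold, threshold


def rmse(predicted, reference) -> float:
    predicted = np.asarray(predicted, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if predicted.size == 0 or predicted.shape != reference.shape:
        raise ValueError("need two equal-length non-empty vectors")
    return float(np.sqrt(np.mean((predicted - reference) ** 2)))


def relative_error_profile(predicted, reference,
                           od_bins=DEFAULT_OD_BINS,
                           epsilon: float = RELATIVE_ERROR_EPSILON) -> pd.DataFrame:
    """Mean relative prediction error (|error| / predicted) per reference-OD bin.

    Points with predicted OD below ``epsilon`` are excluded from the means
    (division instability near zero) and counted in ``n_excluded``; a bin with
    no usable point reports NaN.
    """
    predicted = np.asarray(predicted, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if predicted.shape != reference.shape:
        raise ValueError("predicted and reference must have equal lengths")
    edges = np.asarray(od_bins, dtype=float)
    if np.any(np.diff(edges) <= 0):
        raise ValueError("bin edges must be ascending")
    usable = predicted >= epsilon
    rel = np.full(predicted.shape, np.nan)
    rel[usable] = np.abs(predicted[usable] - reference[usable]) / predicted[usable]
    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        in_bin = (reference >= lo) & (reference < hi)
        vals = rel[in_bin & usable]
        rows.append({
            "od_lo": lo, "od_hi": hi,
            "mean_relative_error": float(np.mean(vals)) if vals.size else np.nan,
            "n": int(in_bin.sum()),
            "n_excluded": int((in_bin & ~usable).sum()),
        })
    return pd.DataFrame(rows)


def steiger_null_rejection_rate(n: int = 294, n_sims: int = 10_000,
                                rho: float = 0.5, rho_kh: float = 0.3,
                                alpha: float = 0.05,
                                seed: int | np.random.Generator = 0) -> float:
    """Empirical type-I error of the Steiger test under an exact null.

    Simulates trivariate normal samples in which both predictors correlate
    equally (``rho``) with the reference and ``rho_kh`` with each other, runs
    the test on each replicate, and returns the fraction rejected at
    ``alpha``.  A calibrated test returns ~alpha.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cov = np.array([[1.0, rho, rho],
                    [rho, 1.0, rho_kh],
                    [rho, rho_kh, 1.0]])
    L = np.linalg.cholesky(cov)
    rejections = 0
    for _ in range(n_sims):
        sample = rng.standard_normal((n, 3)) @ L.T
        c = np.corrcoef(sample, rowvar=False)
        _, p = steiger_test(c[0, 1], c[0, 2], c[1, 2], n)
        rejections += p < alpha
    return rejections / n_sims


@dataclass
class MethodComparisonReport:
    """Per-method performance plus pairwise dependent-correlation tests."""

    per_method: pd.DataFrame            # index method; columns r, p, rmse
    steiger_z: pd.DataFrame             # method x method Z matrix
    steiger_p: pd.DataFrame
    comparisons: pd.DataFrame           # tested pairs with Z, p, decision
    bonferroni_threshold: float
    relative_error: dict[str, pd.DataFrame] = field(default_factory=dict)
    mean_relative_error: pd.Series = field(default_factory=pd.Series)


def build_comparison_report(predictions: dict[str, np.ndarray],
                            reference: np.ndarray,
                            comparisons: list[tuple[str, str]] | None = None,
                            alpha: float = 0.05,
                            od_bins=DEFAULT_OD_BINS,
                            epsilon: float = RELATIVE_ERROR_EPSILON) -> MethodComparisonReport:
    """Assemble the full comparison of predictor methods against one reference.

    ``comparisons`` defaults to all method pairs, with the Bonferroni N set to
    the number of pairs; pass :data:`ADJACENT_COMPARISONS` for the seven-pair
    headline preset (N = 7, threshold 0.05/7 ~= 0.007).
    """
    reference = np.asarray(reference, dtype=float)
    methods = list(predictions)
    n = reference.size

    stats_rows = {}
    for m in methods:
        r, p = pearson_r(predictions[m], reference)
        stats_rows[m] = {"r": r, "p": p, "rmse": rmse(predictions[m], reference)}
    per_method = pd.DataFrame(stats_rows).T

    z_mat = pd.DataFrame(0.0, index=methods, columns=methods)
    p_mat = pd.DataFrame(1.0, index=methods, columns=methods)
    for i, a in enumerate(methods):
        for b in methods[i + 1:]:
            r_kh, _ = pearson_r(predictions[a], predictions[b])
            try:
                z, p = steiger_test(per_method.loc[a, "r"], per_method.loc[b, "r"],
                                    r_kh, n)
            except ValueError:
                # degenerate pair (some |r| reaches 1, e.g. a noiseless study)
                z, p = np.nan, np.nan
            z_mat.loc[a, b], z_mat.loc[b, a] = z, -z
            p_mat.loc[a, b] = p_mat.loc[b, a] = p

    if comparisons is None:
        comparisons = [(a, b) for i, a in enumerate(methods) for b in methods[i + 1:]]
    missing = [pair for pair in comparisons if pair[0] not in methods or pair[1] not in methods]
    if missing:
        raise ValueError(f"comparison names not among methods: {missing}")
    p_list = [p_mat.loc[a, b] for a, b in comparisons]
    decisions, threshold = bonferroni(p_list, alpha=alpha, n_comparisons=len(comparisons))
    comp_df = pd.DataFrame({
        "method_a": [a for a, _ in comparisons],
        "method_b": [b for _, b in comparisons],
        "z": [z_mat.loc[a, b] for a, b in comparisons],
        "p": p_list,
        "significant": decisions,
    })

    rel = {m: relative_error_profile(predictions[m], reference, od_bins, epsilon)
           for m in methods}
    mean_rel = pd.Series({
        m: float(np.nanmean(np.abs(predictions[m][predictions[m] >= epsilon]
                                   - reference[predictions[m] >= epsilon])
                            / predictions[m][predictions[m] >= epsilon]))
        for m in methods})
    return MethodComparisonReport(per_method=per_method, steiger_z=z_mat,
                                  steiger_p=p_mat, comparisons=comp_df,
                                  bonferroni_threshold=threshold,
                                  relative_error=rel, mean_relative_error=mean_rel)
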