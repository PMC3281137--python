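"""Latent-variable calibration: NIPALS PLS1, principal component regression,
stratified dataset construction, leave-one-out cross-validation with
RMSECV-based component selection, and pixel-wise image prediction.

Both regressors mean-centre X and y and apply no variance scaling (standard
chemometric practice for absorbance data).  They expose the scikit-learn
estimator API plus a ``coef_path_`` attribute holding the regression vector
for every component count 1..n_components_, which makes leave-one-out RMSECV
curves cheap: one fit per fold yields predictions at every k.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

from .preprocess import SpectralPipeline
from .spectral import SpectralImage

__all__ = [
    "StratificationRule",
    "CVResult",
    "NIPALSPLSRegression",
    "PrincipalComponentRegression",
    "fit_plsr",
    "fit_pcr",
    "stratified_select",
    "loo_cv",
    "select_components",
    "predict_image",
]

RANK_TOL = 1e-12


@dataclass(frozen=True)
class StratificationRule:
    """Even coverage of the OD range when building the calibration set.

    All points with OD inside ``full_range`` enter the set; from each interval
    between consecutive ``boundaries`` (last stratum open-ended above) exactly
    ``draw_count`` points are sampled without replacement.
    """

    full_range: tuple[float, float] = (0.0, 1.5)
    boundaries: tuple[float, ...] = (1.5, 2.0, 2.15)
    draw_count: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if list(self.boundaries) != sorted(self.boundaries):
            raise ValueError("strata boundaries must be ascending")
        if self.draw_count < 1:
            raise ValueError("draw_count must be >= 1")

    def stratum_intervals(self) -> list[tuple[float, float]]:
        edges = list(self.boundaries) + [np.inf]
        return [(edges[i], edges[i + 1]) for i in range(len(edges) - 1)]


def stratified_select(y: np.ndarray, rule: StratificationRule) -> np.ndarray:
    """Select calibration indices: full low-OD range plus seeded per-stratum draws.

    Returns a sorted, duplicate-free index array.  Raises if any stratum holds
    fewer than ``draw_count`` points (no silent take-all).
    """
    y = np.asarray(y, dtype=float)
    lo, hi = rule.full_range
    chosen = [np.flatnonzero((y >= lo) & (y <= hi))]
    rng = np.random.default_rng(rule.seed)
    for s_lo, s_hi in rule.stratum_intervals():
        pool = np.flatnonzero((y > s_lo) & (y <= s_hi))
        if pool.size < rule.draw_count:
            raise ValueError(
                f"stratum ({s_lo:g}, {s_hi:g}] holds {pool.size} points; "
                f"{rule.draw_count} required")
        chosen.append(rng.choice(pool, size=rule.draw_count, replace=False))
    return np.unique(np.concatenate(chosen))


def stratum_labels(y: np.ndarray, rule: StratificationRule | None = None) -> np.ndarray:
    """Label each point with its OD stratum (for reporting)."""
    rule = rule or StratificationRule()
    y = np.asarray(y, dtype=float)
    labels = np.full(y.shape, "", dtype=object)
    lo, hi = rule.full_range
    labels[(y >= lo) & (y <= hi)] = f"{lo:g}-{hi:g}"
    for s_lo, s_hi in rule.stratum_intervals():
        tag = f">{s_lo:g}" if np.isinf(s_hi) else f"{s_lo:g}-{s_hi:g}"
        labels[(y > s_lo) & (y <= s_hi)] = tag
    return labels


class _CenteredLatentRegressor(RegressorMixin, BaseEstimator):
    """Shared fitted-surface for PLSR and PCR (mean-centred, single response)."""

    def __init__(self, n_components: int = 7):
        self.n_components = n_components

    def _validate(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).reshape(-1)
        if X.ndim != 2 or X.shape[0] != y.size:
            raise ValueError("X must be 2-D with one response per row")
        if np.ptp(y) <= 0:
            raise ValueError("zero-variance response")
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")
        return X, y

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        return self.y_mean_ + (X - self.x_mean_) @ self.coef_

    def predict_path(self, X) -> np.ndarray:
        """Predictions for every component count 1..n_components_ (columns)."""
        X = np.asarray(X, dtype=float)
        return self.y_mean_ + (X - self.x_mean_) @ self.coef_path_


class NIPALSPLSRegression(_CenteredLatentRegressor):
    """PLS1 regression via the NIPALS algorithm.

    Per component: weight ``w`` proportional to X'y (unit norm), score
    ``t = X w``, x-loading ``p = X't / t't``, y-loading ``q = y't / t't``,
    then deflation of X and y.  The regression vector is assembled from
    (W, P, q); components whose score norm collapses below
    ``1e-12 x`` the initial scale terminate extraction early
    (rank-deficiency guard), recorded in ``n_components_``.
    """

    def fit(self, X, y):
        X, y = self._validate(X, y)
        n, p = X.shape
        self.x_mean_ = X.mean(axis=0)
        self.y_mean_ = y.mean()
        Xc = X - self.x_mean_
        yc = y - self.y_mean_

        k_max = min(self.n_components, n - 1, p)
        W = np.zeros((p, k_max))
        P = np.zeros((p, k_max))
        R = np.zeros((p, k_max))  # W (P'W)^-1, built by Gram-Schmidt recursion
        q = np.zeros(k_max)
        coef_path = np.zeros((p, k_max))
        b = np.zeros(p)
        scale0 = np.linalg.norm(Xc) * np.linalg.norm(yc)
        k = 0
        for a in range(k_max):
            w = Xc.T @ yc
            wn = np.linalg.norm(w)
            if wn <= RANK_TOL * max(scale0, 1.0):
                break
            w /= wn
            t = Xc @ w
            tt = t @ t
            if tt <= (RANK_TOL * max(np.linalg.norm(X), 1.0)) ** 2:
                break
            pa = Xc.T @ t / tt
            qa = (yc @ t) / tt
            Xc = Xc - np.outer(t, pa)
            yc = yc - qa * t
            r = w.copy()
            for j in range(a):
                r -= (P[:, j] @ w) * R[:, j]
            W[:, a], P[:, a], R[:, a], q[a] = w, pa, r, qa
            b = b + qa * r
            coef_path[:, a] = b
            k += 1
        if k == 0:
            raise ValueError("no PLS component could be extracted (rank-deficient problem)")
        self.n_components_ = k
        self.x_weights_ = W[:, :k]
        self.x_loadings_ = P[:, :k]
        self.y_loadings_ = q[:k]
        self.coef_path_ = coef_path[:, :k]
        self.coef_ = coef_path[:, k - 1]
        return self


class PrincipalComponentRegression(_CenteredLatentRegressor):
    """Regression of the response on the leading principal-component scores.

    Scores are projections of centred X onto the leading right singular
    directions; the response is regressed on the (orthogonal) scores, and the
    coefficients are mapped back to the original variables.  Singular values
    below ``1e-12 x`` the largest are dropped (rank guard).
    """

    def fit(self, X, y):
        X, y = self._validate(X, y)
        self.x_mean_ = X.mean(axis=0)
        self.y_mean_ = y.mean()
        Xc = X - self.x_mean_
        yc = y - self.y_mean_
        U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
        rank = int(np.sum(s > RANK_TOL * s[0])) if s.size and s[0] > 0 else 0
        if rank == 0:
            raise ValueError("centred X has rank 0")
        k = min(self.n_components, rank)
        # gamma_a = u_a'y / s_a is the OLS coefficient on orthogonal scores
        gamma = (U[:, :k].T @ yc) / s[:k]
        self.n_components_ = k
        self.components_ = Vt[:k]
        self.singular_values_ = s[:k]
        self.coef_path_ = np.cumsum(Vt[:k].T * gamma[None, :], axis=1)
        self.coef_ = self.coef_path_[:, -1]
        return self


def fit_plsr(X, y, k: int) -> NIPALSPLSRegression:
    return NIPALSPLSRegression(n_components=k).fit(X, y)


def fit_pcr(X, y, k: int) -> PrincipalComponentRegression:
    return PrincipalComponentRegression(n_components=k).fit(X, y)


@dataclass
class CVResult:
    """Leave-one-out cross-validation summary for one latent-variable method."""

    method: str
    rmsecv: np.ndarray                 # indexed by component count 1..k_max
    selected_k: int
    predictions: np.ndarray            # (n, k_max) held-out predictions
    selected_predictions: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.selected_predictions = self.predictions[:, self.selected_k - 1]


_METHODS = {"plsr": NIPALSPLSRegression, "pcr": PrincipalComponentRegression}


def loo_cv(X, y, method: str = "plsr", k_max: int = 15,
           groups=None, rel_tol: float = 0.02) -> CVResult:
    """Leave-one-out cross-validation with RMSECV component selection.

    Each point (or, with ``groups``, each whole specimen) is left out in turn,
    the model refitted on the remainder at ``k_max`` components, and the
    held-out prediction stored for every component count; ``rmsecv(k)`` is the
    root mean squared held-out error.  The component count is then chosen with
    :func:`select_components`.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).reshape(-1)
    n = y.size
    if method not in _METHODS:
        raise ValueError(f"unknown method {method!r}")
    if groups is None:
        folds = [np.array([i]) for i in range(n)]
    else:
        groups = np.asarray(groups)
        folds = [np.flatnonzero(groups == g) for g in pd_unique(groups)]
    if k_max >= n - max(len(f) for f in folds):
        raise ValueError("k_max must be smaller than the training size of every fold")

    predictions = np.full((n, k_max), np.nan)
    k_eff = k_max
    for fold in folds:
        train = np.setdiff1d(np.arange(n), fold, assume_unique=True)
        model = _METHODS[method](n_components=k_max).fit(X[train], y[train])
        path = model.predict_path(X[fold])
        m = model.n_components_
        predictions[fold, :m] = path
        if m < k_max:  # rank-limited fold: pad with the deepest available model
            predictions[fold, m:] = path[:, [m - 1]]
            k_eff = min(k_eff, m)
    rmsecv = np.sqrt(np.mean((predictions - y[:, None]) ** 2, axis=0))
    selected = select_components(rmsecv[:k_eff], rel_tol=rel_tol)
    return CVResult(method=method, rmsecv=rmsecv, selected_k=selected,
                    predictions=predictions)


def pd_unique(values: np.ndarray) -> np.ndarray:
    """Unique values in order of first appearance."""
    _, idx = np.unique(values, return_index=True)
    return values[np.sort(idx)]


def select_components(rmsecv: np.ndarray, rel_tol: float = 0.02) -> int:
    """Smallest k after which RMSECV no longer drops by more than ``rel_tol``.

    Returns the smallest k such that every later RMSECV exceeds
    ``(1 - rel_tol) * rmsecv(k)``; if no k qualifies, returns k_max.
    """
    rmsecv = np.asarray(rmsecv, dtype=float)
    if rmsecv.size == 0:
        raise ValueError("empty RMSECV curve")
    k_max = rmsecv.size
    for k in range(1, k_max + 1):
        if np.all(rmsecv[k:] > (1.0 - rel_tol) * rmsecv[k - 1]):
            return k
    return k_max


def predict_image(model: _CenteredLatentRegressor,
                  image: SpectralImage,
                  pipeline: SpectralPipeline) -> tuple[np.ndarray, np.ndarray]:
    """Pixel-wise OD prediction and transverse-averaged depth profile.

    The image is preprocessed through the same pipeline the model was trained
    with; a wavenumber-grid mismatch raises.  Returns ``(od_map, profile)``
    with ``od_map`` of shape (n_rows, n_cols) and ``profile`` of length n_rows.
    """
    if not np.array_equal(image.wavenumbers, pipeline.wavenumbers):
        raise ValueError("image wavenumber grid does not match the training pipeline")
    n_rows, n_cols, n_wn = image.absorbance.shape
    flat = image.absorbance.reshape(n_rows * n_cols, n_wn)
    variables = pipeline.transform(flat)
    if variables.shape[1] != model.coef_.size:
        raise ValueError("preprocessed variable count does not match the fitted model")
    od_map = model.predict(variables).reshape(n_rows, n_cols)
    return od_map, od_map.mean(axis=1)
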