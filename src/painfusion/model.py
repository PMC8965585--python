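"""Scikit-learn-style estimators for pain-threshold regression.

``CorrelationSelector`` is the mass-univariate filter used inside every
cross-validation fold: a feature survives when the two-sided p-value of
its Pearson correlation with the training thresholds falls below the
threshold. ``SingleTypeRegressor`` chains that filter with per-feature
z-scoring (training statistics only) and one of four regression
back-ends (linear/RBF support-vector regression, partial least squares,
random forest). Both compose with sklearn pipelines and model
selection.
"""

from __future__ import annotations

import logging
from typing import Any

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.cross_decomposition import PLSRegression
from sklearn.ensemble import RandomForestRegressor
from sklearn.feature_selection import SelectorMixin
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR
from sklearn.utils.validation import check_is_fitted, validate_data

from .containers import ALGORITHMS

logger = logging.getLogger(__name__)

__all__ = [
    "correlation_pvalues",
    "CorrelationSelector",
    "SingleTypeRegressor",
    "make_backend",
]


def correlation_pvalues(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-column Pearson r with y and its two-sided p-value.

    p-values use the exact t transform t = r sqrt((n-2)/(1-r^2)) with
    n-2 degrees of freedom. Constant columns get r = 0, p = 1.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = X.shape[0]
    if n < 4:
        raise ValueError("correlation screening needs at least 4 samples")
    if np.ptp(y) == 0:
        raise ValueError("constant target: correlations undefined")
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    sx = np.sqrt((Xc**2).sum(axis=0))
    sy = np.sqrt((yc**2).sum())
    constant = sx == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        r = Xc.T @ yc / (sx * sy)
    r = np.where(constant, 0.0, np.clip(r, -1.0, 1.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r**2, 1e-300))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(constant, 1.0, p)
    return r, p


class CorrelationSelector(SelectorMixin, BaseEstimator):
    """Select features by the p-value of their correlation with the target.

    Parameters
    ----------
    p_threshold : float
        Strict upper bound on the two-sided Pearson p-value.

    Attributes
    ----------
    r_ : ndarray of shape (n_features,)
        Training correlations.
    pvalues_ : ndarray of shape (n_features,)
        Two-sided p-values.
    support_ : boolean mask of selected features. Constant columns are
        never selected; their count is logged.
    """

    def __init__(self, p_threshold: float = 0.01) -> None:
        self.p_threshold = p_threshold

    def fit(self, X, y):
        if not 0 < self.p_threshold < 1:
            raise ValueError("p_threshold must lie in (0, 1)")
        X = validate_data(self, X, dtype=float)
        y = np.asarray(y, dtype=float)
        self.r_, self.pvalues_ = correlation_pvalues(X, y)
        constant = np.ptp(X, axis=0) == 0
        n_const = int(constant.sum())
        if n_const:
            logger.info("excluding %d constant feature column(s)", n_const)
        self.support_ = (self.pvalues_ < self.p_threshold) & ~constant
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "support_")
        return self.support_


def make_backend(
    algorithm: str,
    hyperparams: dict[str, Any] | None = None,
    seed: int = 0,
    n_features: int | None = None,
    n_samples: int | None = None,
):
    """Instantiate a regression back-end by tag.

    Defaults: SVR C=1, epsilon=0.1 (RBF gamma = 1/(d var(X)), sklearn's
    'scale'); PLSR with min(5, rank) components; random forest with 500
    trees.
    """
    hp = dict(hyperparams or {})
    if algorithm == "svr_linear":
        return SVR(kernel="linear", C=hp.pop("C", 1.0), epsilon=hp.pop("epsilon", 0.1), **hp)
    if algorithm == "svr_rbf":
        return SVR(
            kernel="rbf",
            C=hp.pop("C", 1.0),
            epsilon=hp.pop("epsilon", 0.1),
            gamma=hp.pop("gamma", "scale"),
            **hp,
        )
    if algorithm == "plsr":
        n_comp = hp.pop("n_components", 5)
        if n_features is not None and n_samples is not None:
            n_comp = max(1, min(n_comp, n_features, n_samples - 1))
        return PLSRegression(n_components=n_comp, **hp)
    if algorithm == "rf":
        return RandomForestRegressor(
            n_estimators=hp.pop("n_estimators", 500), random_state=seed, **hp
        )
    raise ValueError(f"unknown algorithm {algorithm!r}; expected one of {ALGORITHMS}")


class SingleTypeRegressor(RegressorMixin, BaseEstimator):
    """Correlation filter + training-statistics z-score + regression.

    This is the model fitted inside each leave-one-out fold for one
    feature type. When no feature survives the filter the model falls
    back to predicting the training mean (logged).

    Attributes
    ----------
    selector_ : fitted CorrelationSelector
    scaler_ : fitted StandardScaler (training statistics only)
    model_ : fitted back-end regressor
    selected_idx_ : integer indices of the surviving feature columns
    empty_selection_ : True when the fold fell back to the training mean
    y_mean_ : training-mean fallback prediction
    """

    def __init__(
        self,
        algorithm: str = "svr_linear",
        selection_p: float = 0.001,
        hyperparams: dict[str, Any] | None = None,
        seed: int = 0,
    ) -> None:
        self.algorithm = algorithm
        self.selection_p = selection_p
        self.hyperparams = hyperparams
        self.seed = seed

    def fit(self, X, y):
        X = validate_data(self, X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.shape[0] < 2:
            raise ValueError("need at least 2 training samples")
        self.selector_ = CorrelationSelector(p_threshold=self.selection_p).fit(X, y)
        self.selected_idx_ = np.flatnonzero(self.selector_.support_)
        self.y_mean_ = float(y.mean())
        if self.selected_idx_.size == 0:
            logger.info("no features passed p<%g; predicting training mean", self.selection_p)
            self.empty_selection_ = True
            self.scaler_ = None
            self.model_ = None
            return self
        self.empty_selection_ = False
        Xs = X[:, self.selected_idx_]
        self.scaler_ = StandardScaler().fit(Xs)
        Xz = self.scaler_.transform(Xs)
        self.model_ = make_backend(
            self.algorithm,
            self.hyperparams,
            seed=self.seed,
            n_features=Xz.shape[1],
            n_samples=Xz.shape[0],
        )
        self.model_.fit(Xz, y)
        return self

    def predict(self, X):
        check_is_fitted(self, "y_mean_")
        X = validate_data(self, X, dtype=float, reset=False)
        if self.empty_selection_:
            return np.full(X.shape[0], self.y_mean_)
        Xz = self.scaler_.transform(X[:, self.selected_idx_])
        return np.asarray(self.model_.predict(Xz)).ravel()
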