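"""Leave-one-individual-out prediction and decision-level fusion.

Every fold holds out exactly one subject; feature selection, feature
normalisation and model fitting all use the remaining n-1 subjects
only, so no statistic touching the held-out subject leaks into its
prediction. Multi-type models are formed purely at the decision level:
the fused prediction is the unweighted mean of the constituent
single-type predictions, leaving each constituent's feature and model
selection untouched.

The default nine-model suite mirrors the study design: four single-type
models (ReHo, FC, FA, SC) with per-type algorithm/threshold settings,
and five fused models (Regional = ReHo+FA, Connectivity = FC+SC,
fMRI = ReHo+FC, DTI = FA+SC, Fused = all four).
"""

from __future__ import annotations

import logging
from typing import Iterable

import numpy as np

from .containers import FeatureTable, ModelSpec, PhenotypeVector, PredictionResult
from .model import CorrelationSelector, SingleTypeRegressor

logger = logging.getLogger(__name__)

__all__ = [
    "select_features",
    "zscore_fit",
    "zscore_apply",
    "fit_regressor",
    "loocv_predict",
    "fuse_predictions",
    "run_model_suite",
    "run_model_grid",
    "DEFAULT_TYPE_SETTINGS",
    "SUITE_DEFINITIONS",
]

#: per-type algorithm and selection threshold of the default suite
DEFAULT_TYPE_SETTINGS: dict[str, tuple[str, float]] = {
    "reho": ("svr_linear", 0.001),
    "fa": ("svr_rbf", 0.01),
    "fc": ("svr_linear", 0.001),
    "sc": ("svr_rbf", 0.001),
}

#: the nine models: name -> constituent feature types
SUITE_DEFINITIONS: dict[str, tuple[str, ...]] = {
    "ReHo": ("reho",),
    "FC": ("fc",),
    "FA": ("fa",),
    "SC": ("sc",),
    "Regional": ("reho", "fa"),
    "Connectivity": ("fc", "sc"),
    "fMRI": ("reho", "fc"),
    "DTI": ("fa", "sc"),
    "Fused": ("reho", "fc", "fa", "sc"),
}


def select_features(
    train_X: np.ndarray, train_y: np.ndarray, p_threshold: float
) -> np.ndarray:
    """Indices of columns whose Pearson p-value with y is below threshold."""
    sel = CorrelationSelector(p_threshold=p_threshold).fit(train_X, train_y)
    return np.flatnonzero(sel.support_)


def zscore_fit(train_X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Training mean and sd per column; errors on a zero-sd column."""
    train_X = np.asarray(train_X, dtype=float)
    mean = train_X.mean(axis=0)
    sd = train_X.std(axis=0, ddof=0)
    if np.any(sd == 0):
        bad = np.flatnonzero(sd == 0).tolist()
        raise ValueError(f"zero-sd columns {bad}: exclude before normalization")
    return mean, sd


def zscore_apply(stats: tuple[np.ndarray, np.ndarray], X: np.ndarray) -> np.ndarray:
    """Apply training z-score statistics to any matrix (train or test)."""
    mean, sd = stats
    return (np.asarray(X, dtype=float) - mean) / sd


def fit_regressor(X, y, algorithm: str, hyperparams=None, seed: int = 0):
    """Fit one back-end regressor on already-normalised features."""
    from .model import make_backend

    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    model = make_backend(
        algorithm, hyperparams, seed=seed, n_features=X.shape[1], n_samples=X.shape[0]
    )
    model.fit(X, y)
    return model


def _as_y(y) -> tuple[np.ndarray, list[str]]:
    if isinstance(y, PhenotypeVector):
        return y.threshold_J, list(y.subject_ids)
    arr = np.asarray(y, dtype=float)
    return arr, [f"sub-{i + 1:04d}" for i in range(arr.size)]


def loocv_predict(table: FeatureTable, y, spec: ModelSpec) -> PredictionResult:
    """Leave-one-individual-out prediction for one single-type table.

    For each of the n folds: hold out one subject, select features on
    the remaining n-1 only, z-score with training statistics, fit the
    back-end and predict the held-out subject. Folds with an empty
    selection predict the training mean of y. Selected column indices
    are recorded per fold for stability analysis.
    """
    if len(spec.feature_types) != 1:
        raise ValueError("loocv_predict handles single-type specs; fuse multi-type models")
    ftype = spec.feature_types[0]
    yv, subject_ids = _as_y(y)
    n = table.n_subjects
    if yv.size != n:
        raise ValueError("phenotype length != subject count")
    if n < 5:
        raise ValueError("leave-one-out needs at least 5 subjects")

    algorithm = spec.algorithm.get(ftype, DEFAULT_TYPE_SETTINGS[ftype][0])
    p_thr = spec.selection_p.get(ftype, DEFAULT_TYPE_SETTINGS[ftype][1])
    hyper = spec.hyperparams.get(ftype)

    X = table.matrix
    predicted = np.empty(n)
    per_fold: list[dict[str, np.ndarray]] = []
    for k in range(n):
        train = np.ones(n, dtype=bool)
        train[k] = False
        est = SingleTypeRegressor(
            algorithm=algorithm, selection_p=p_thr, hyperparams=hyper, seed=spec.seed
        ).fit(X[train], yv[train])
        predicted[k] = est.predict(X[k : k + 1])[0]
        per_fold.append({ftype: est.selected_idx_.copy()})
    return PredictionResult(
        predicted=predicted,
        true=yv,
        per_fold_selected=per_fold,
        model_spec=spec,
        subject_ids=subject_ids,
    )


def fuse_predictions(results: Iterable[PredictionResult]) -> PredictionResult:
    """Decision-level fusion: unweighted mean of constituent predictions.

    All constituents must share subjects and true thresholds. The fused
    per-fold selection log is the union of the constituents' logs,
    tagged by source feature type.
    """
    results = list(results)
    if not results:
        raise ValueError("nothing to fuse")
    ref = results[0]
    for r in results[1:]:
        if r.subject_ids != ref.subject_ids or not np.array_equal(r.true, ref.true):
            raise ValueError("fusion constituents disagree on subjects or targets")
    fused_pred = np.mean([r.predicted for r in results], axis=0)
    per_fold: list[dict[str, np.ndarray]] = []
    for k in range(ref.n_subjects):
        merged: dict[str, np.ndarray] = {}
        for r in results:
            for t, idx in r.per_fold_selected[k].items():
                if t in merged:
                    raise ValueError(f"duplicate feature type {t!r} among constituents")
                merged[t] = idx
        per_fold.append(merged)
    types = tuple(t for r in results for t in r.model_spec.feature_types)
    spec = ModelSpec(
        feature_types=types,
        algorithm={k: v for r in results for k, v in r.model_spec.algorithm.items()},
        selection_p={k: v for r in results for k, v in r.model_spec.selection_p.items()},
        seed=ref.model_spec.seed,
    )
    return PredictionResult(
        predicted=fused_pred,
        true=ref.true.copy(),
        per_fold_selected=per_fold,
        model_spec=spec,
        subject_ids=list(ref.subject_ids),
    )


def _single_type_spec(ftype: str, seed: int, settings=None) -> ModelSpec:
    algo, p = (settings or DEFAULT_TYPE_SETTINGS)[ftype]
    return ModelSpec(
        feature_types=(ftype,),
        algorithm={ftype: algo},
        selection_p={ftype: p},
        seed=seed,
    )


def run_model_suite(
    tables: dict[str, FeatureTable],
    y,
    seed: int = 0,
    type_settings: dict[str, tuple[str, float]] | None = None,
) -> dict[str, PredictionResult]:
    """The nine-model comparison suite.

    Runs the four single-type models with their per-type defaults, then
    forms the five multi-type models exclusively by averaging the
    single-type predictions (fusion never re-runs selection or
    fitting).
    """
    for ftype in ("reho", "fc", "fa", "sc"):
        if ftype not in tables:
            raise ValueError(f"missing feature table for type {ftype!r}")
    singles: dict[str, PredictionResult] = {}
    for ftype in ("reho", "fc", "fa", "sc"):
        spec = _single_type_spec(ftype, seed, type_settings)
        singles[ftype] = loocv_predict(tables[ftype], y, spec)

    out: dict[str, PredictionResult] = {}
    for name, types in SUITE_DEFINITIONS.items():
        if len(types) == 1:
            out[name] = singles[types[0]]
        else:
            out[name] = fuse_predictions([singles[t] for t in types])
    return out


def run_model_grid(
    tables: dict[str, FeatureTable],
    y,
    seed: int = 0,
    algorithms: tuple[str, ...] = ("svr_linear", "svr_rbf", "plsr", "rf"),
    thresholds: tuple[float, ...] = (0.05, 0.01, 0.001),
) -> dict[tuple[str, str, float], PredictionResult]:
    """Model-selection screening: every (type, algorithm, threshold) cell.

    This reproduces the supplementary screening that fixed the per-type
    defaults. Because the same leave-one-out predictions later serve as
    the reported performance, screening on them is optimistically
    biased; the grid is exposed for exploration and the default suite
    pins the per-type settings instead.
    """
    out: dict[tuple[str, str, float], PredictionResult] = {}
    for ftype, table in tables.items():
        for algo in algorithms:
            for p in thresholds:
                spec = ModelSpec(
                    feature_types=(ftype,),
                    algorithm={ftype: algo},
                    selection_p={ftype: p},
                    seed=seed,
                )
                out[(ftype, algo, p)] = loocv_predict(table, y, spec)
    return out
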