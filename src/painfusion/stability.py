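"""Selection-frequency stability of the cross-validated feature filter.

Features chosen in more than half of the leave-one-individual-out folds
("common predictive features") are the reportable outcome of the
selection procedure; regional features are mapped to their parcellation
region and connectivity features to named ROI pairs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import ParcellationMask, PredictionResult

__all__ = [
    "selection_frequency",
    "common_features",
    "annotate_regions",
    "region_counts",
]


def selection_frequency(
    result: PredictionResult, feature_meta: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Per-feature selection frequency across all folds, per feature type.

    Returns a table with columns ``type``, ``feature_index`` and
    ``frequency`` = (folds selecting the feature) / (total folds); the
    per-feature metadata is joined when provided.
    """
    folds = result.per_fold_selected
    if not folds:
        raise ValueError("result carries no per-fold selection log")
    n_folds = len(folds)
    types = sorted({t for fold in folds for t in fold})
    if not types:
        raise ValueError("per-fold selection log is empty")
    frames = []
    for t in types:
        missing = [k for k, fold in enumerate(folds) if t not in fold]
        if missing:
            raise ValueError(
                f"feature type {t!r} missing from fold(s) {missing[:5]}"
            )
        max_idx = max(
            (int(fold[t].max()) for fold in folds if fold[t].size), default=-1
        )
        size = max_idx + 1
        if feature_meta is not None:
            size = max(size, len(feature_meta))
        counts = np.zeros(size, dtype=int)
        for fold in folds:
            counts[fold[t]] += 1
        frame = pd.DataFrame(
            {
                "type": t,
                "feature_index": np.arange(counts.size),
                "frequency": counts / n_folds,
            }
        )
        frames.append(frame)
    table = pd.concat(frames, ignore_index=True)
    if feature_meta is not None:
        meta = feature_meta.reset_index().rename(columns={"index": "feature_index"})
        drop = [c for c in ("type",) if c in meta.columns]
        table = table.merge(meta.drop(columns=drop), on="feature_index", how="left")
    return table


def common_features(table: pd.DataFrame, threshold: float = 0.5) -> pd.DataFrame:
    """Features selected strictly more than ``threshold`` of the folds.

    The inequality is strict: a feature chosen in exactly half of the
    folds is not retained.
    """
    out = table.copy()
    out["retained"] = out["frequency"] > threshold
    return out[out["retained"]].reset_index(drop=True)


def annotate_regions(
    features: pd.DataFrame,
    parcellation: ParcellationMask | None = None,
    label_names: dict[int, str] | None = None,
) -> pd.DataFrame:
    """Attach region names to retained features.

    Regional features (voxel coordinates ``vx, vy, vz``) are mapped to
    their parcellation label; connectivity features (``roi_a, roi_b``)
    get an order-normalised named pair (smaller label first).
    """
    names = label_names or {}

    def _name(lbl: int) -> str:
        return names.get(int(lbl), f"ROI_{int(lbl)}")

    out = features.copy()
    regions = []
    for _, row in out.iterrows():
        if {"vx", "vy", "vz"} <= set(row.index) and not pd.isna(row.get("vx")):
            if parcellation is None:
                raise ValueError("regional features need a parcellation")
            v = (int(row["vx"]), int(row["vy"]), int(row["vz"]))
            for axis, size in zip(v, parcellation.shape):
                if not 0 <= axis < size:
                    raise ValueError(f"voxel index {v} outside grid {parcellation.shape}")
            regions.append(_name(parcellation.labels[v]))
        elif {"roi_a", "roi_b"} <= set(row.index) and not pd.isna(row.get("roi_a")):
            a, b = int(row["roi_a"]), int(row["roi_b"])
            lo, hi = sorted((a, b))
            regions.append(f"{_name(lo)}-{_name(hi)}")
        else:
            raise ValueError("feature row has neither voxel nor ROI-pair metadata")
    out["region"] = regions
    return out


def region_counts(annotated: pd.DataFrame) -> pd.DataFrame:
    """Retained-feature counts per region (regional) or region pair
    (connectivity); counts sum to the number of retained features."""
    return (
        annotated.groupby(["type", "region"], as_index=False)
        .size()
        .rename(columns={"size": "count"})
        .sort_values(["type", "count"], ascending=[True, False])
        .reset_index(drop=True)
    )
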