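"""In-memory containers shared across the pipeline stages.

All voxel indices are 0-based. Spatial grids are (x, y, z); 4D grids are
(x, y, z, t). Parcellation labels are integers with 0 = background and
1..R = regions of interest; both imaging modalities share one parcellation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

__all__ = [
    "ParcellationMask",
    "BoldVolume",
    "MotionParams",
    "TensorField",
    "RegionalMap",
    "ConnectivityMatrix",
    "FeatureTable",
    "PhenotypeVector",
    "ModelSpec",
    "PredictionResult",
    "FEATURE_TYPES",
    "ALGORITHMS",
]

#: canonical feature-type tags, in the fixed reporting order
FEATURE_TYPES = ("reho", "fc", "fa", "sc")

#: supported regression back-ends
ALGORITHMS = ("svr_linear", "svr_rbf", "plsr", "rf")


@dataclass
class ParcellationMask:
    """3D integer label volume; 0 = background, 1..n_rois = ROIs."""

    labels: np.ndarray
    n_rois: int
    voxel_size_mm: tuple[float, float, float] = (3.0, 3.0, 3.0)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("parcellation labels must be a 3D array")
        present = np.unique(self.labels)
        bad = present[(present < 0) | (present > self.n_rois)]
        if bad.size:
            raise ValueError(
                f"parcellation contains labels outside 0..{self.n_rois}: "
                f"{bad.tolist()}"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape  # type: ignore[return-value]

    def roi_voxels(self, label: int) -> np.ndarray:
        """(k, 3) voxel indices of one ROI."""
        return np.argwhere(self.labels == label)

    def brain_mask(self) -> np.ndarray:
        return self.labels > 0


@dataclass
class BoldVolume:
    """4D BOLD signal (x, y, z, t) with repetition time and brain mask."""

    data: np.ndarray
    tr_s: float
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("BOLD data must be 4D (x, y, z, t)")
        if self.data.shape[-1] < 2:
            raise ValueError("BOLD series needs at least 2 timepoints")
        if self.tr_s <= 0:
            raise ValueError("tr_s must be positive")
        if self.mask is None:
            self.mask = np.ones(self.data.shape[:3], dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.data.shape[:3]:
                raise ValueError("mask shape must match BOLD spatial shape")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[-1]


@dataclass
class MotionParams:
    """t x 6 rigid-body motion table: 3 translations (mm), 3 rotations (rad)."""

    table: np.ndarray

    def __post_init__(self) -> None:
        self.table = np.asarray(self.table, dtype=float)
        if self.table.ndim != 2 or self.table.shape[1] != 6:
            raise ValueError(
                f"motion table must have 6 columns, got shape {self.table.shape}"
            )

    @property
    def n_frames(self) -> int:
        return self.table.shape[0]


#: order of the unique tensor components in `TensorField.components`
TENSOR_COMPONENT_ORDER = ("xx", "xy", "xz", "yy", "yz", "zz")


@dataclass
class TensorField:
    """Per-voxel symmetric diffusion tensors stored as 6 unique components.

    Component order along the last axis is xx, xy, xz, yy, yz, zz.
    """

    components: np.ndarray
    voxel_size_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.components = np.asarray(self.components, dtype=float)
        if self.components.ndim != 4 or self.components.shape[-1] != 6:
            raise ValueError("tensor components must have shape (x, y, z, 6)")
        if self.mask is None:
            self.mask = np.ones(self.components.shape[:3], dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.components.shape[:3]:
                raise ValueError("mask shape must match tensor spatial shape")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.components.shape[:3]  # type: ignore[return-value]

    def as_matrices(self) -> np.ndarray:
        """Reassemble the full (..., 3, 3) symmetric tensor array."""
        c = self.components
        out = np.empty(c.shape[:3] + (3, 3), dtype=float)
        out[..., 0, 0] = c[..., 0]
        out[..., 0, 1] = out[..., 1, 0] = c[..., 1]
        out[..., 0, 2] = out[..., 2, 0] = c[..., 2]
        out[..., 1, 1] = c[..., 3]
        out[..., 1, 2] = out[..., 2, 1] = c[..., 4]
        out[..., 2, 2] = c[..., 5]
        return out

    @staticmethod
    def from_matrices(
        matrices: np.ndarray,
        voxel_size_mm: tuple[float, float, float] = (2.0, 2.0, 2.0),
        mask: np.ndarray | None = None,
    ) -> "TensorField":
        m = np.asarray(matrices, dtype=float)
        comp = np.stack(
            [
                m[..., 0, 0],
                m[..., 0, 1],
                m[..., 0, 2],
                m[..., 1, 1],
                m[..., 1, 2],
                m[..., 2, 2],
            ],
            axis=-1,
        )
        return TensorField(comp, voxel_size_mm=voxel_size_mm, mask=mask)


@dataclass
class RegionalMap:
    """3D scalar map (ReHo or FA) with its brain mask."""

    data: np.ndarray
    kind: str
    mask: np.ndarray

    def __post_init__(self) -> None:
        if self.kind not in ("reho", "fa"):
            raise ValueError(f"unknown regional map kind {self.kind!r}")
        self.data = np.asarray(self.data, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.data.shape != self.mask.shape:
            raise ValueError("map and mask shapes differ")
        if not np.all(np.isfinite(self.data[self.mask])):
            raise ValueError("non-finite values inside the mask")


@dataclass
class ConnectivityMatrix:
    """R x R ROI-pair matrix: Fisher-z FC or streamline-probability SC."""

    values: np.ndarray
    kind: str
    roi_labels: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.kind not in ("fc_fisher_z", "sc_probability"):
            raise ValueError(f"unknown connectivity kind {self.kind!r}")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("connectivity matrix must be square")
        if not self.roi_labels:
            self.roi_labels = list(range(1, self.values.shape[0] + 1))
        if self.kind == "sc_probability":
            if self.values.min() < 0 or self.values.max() > 1 + 1e-12:
                raise ValueError("SC probabilities must lie in [0, 1]")

    @property
    def n_rois(self) -> int:
        return self.values.shape[0]


class FeatureTable:
    """Subjects x features matrix with per-feature metadata.

    ``feature_meta`` is a DataFrame with a ``type`` column (reho/fa/fc/sc)
    plus either voxel coordinates (``vx``, ``vy``, ``vz``) for regional
    features or an ROI pair (``roi_a``, ``roi_b``) for connectivity
    features.
    """

    def __init__(
        self,
        matrix: np.ndarray,
        feature_meta: pd.DataFrame,
        subject_ids: list[str] | None = None,
    ) -> None:
        self.matrix = np.asarray(matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise ValueError("feature matrix must be 2D (subjects x features)")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("feature matrix contains non-finite values")
        if len(feature_meta) != self.matrix.shape[1]:
            raise ValueError(
                f"feature_meta rows ({len(feature_meta)}) != feature columns "
                f"({self.matrix.shape[1]})"
            )
        self.feature_meta = feature_meta.reset_index(drop=True)
        if subject_ids is None:
            subject_ids = [f"sub-{i + 1:04d}" for i in range(self.matrix.shape[0])]
        if len(subject_ids) != self.matrix.shape[0]:
            raise ValueError("subject_ids length != number of rows")
        self.subject_ids = list(subject_ids)

    @property
    def n_subjects(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_features(self) -> int:
        return self.matrix.shape[1]

    @property
    def feature_type(self) -> str:
        types = self.feature_meta["type"].unique()
        if len(types) != 1:
            raise ValueError("feature table mixes feature types")
        return str(types[0])


@dataclass
class PhenotypeVector:
    """Per-subject laser pain thresholds in Joules."""

    subject_ids: list[str]
    threshold_J: np.ndarray

    def __post_init__(self) -> None:
        self.threshold_J = np.asarray(self.threshold_J, dtype=float)
        if self.threshold_J.ndim != 1:
            raise ValueError("thresholds must be a 1D vector")
        if len(self.subject_ids) != self.threshold_J.size:
            raise ValueError("subject_ids length != thresholds length")
        if np.any(self.threshold_J <= 0):
            raise ValueError("pain thresholds must be positive")

    def __len__(self) -> int:
        return self.threshold_J.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"subject_id": self.subject_ids, "threshold_J": self.threshold_J}
        )


@dataclass
class ModelSpec:
    """Configuration of one prediction model.

    ``feature_types`` lists the blocks entering the model; a multi-type
    spec is realised by decision-level fusion of the single-type models.
    """

    feature_types: tuple[str, ...]
    algorithm: dict[str, str] = field(default_factory=dict)
    selection_p: dict[str, float] = field(default_factory=dict)
    hyperparams: dict[str, dict[str, Any]] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.feature_types:
            raise ValueError("ModelSpec needs at least one feature type")
        for t in self.feature_types:
            if t not in FEATURE_TYPES:
                raise ValueError(f"unknown feature type {t!r}")
        for t, algo in self.algorithm.items():
            if algo not in ALGORITHMS:
                raise ValueError(f"unknown algorithm {algo!r} for type {t!r}")
        for t, p in self.selection_p.items():
            if not 0 < p < 1:
                raise ValueError(f"selection_p for {t!r} must be in (0, 1)")


@dataclass
class PredictionResult:
    """Out-of-fold predictions plus the per-fold selected-feature log."""

    predicted: np.ndarray
    true: np.ndarray
    per_fold_selected: list[dict[str, np.ndarray]]
    model_spec: ModelSpec
    subject_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.predicted = np.asarray(self.predicted, dtype=float)
        self.true = np.asarray(self.true, dtype=float)
        if self.predicted.shape != self.true.shape:
            raise ValueError("predicted and true lengths differ")
        if len(self.per_fold_selected) != self.predicted.size:
            raise ValueError("one selection record per fold is required")
        if not self.subject_ids:
            self.subject_ids = [
                f"sub-{i + 1:04d}" for i in range(self.predicted.size)
            ]

    @property
    def n_subjects(self) -> int:
        return self.predicted.size
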