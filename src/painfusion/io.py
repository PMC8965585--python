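"""File I/O: NIfTI volumes, TSV tables, JSON configs, provenance sidecars.

Voxel indices are 0-based internally. NIfTI affines are respected only
for physical voxel sizes; no reorientation is performed (inputs are
assumed co-registered). Every file written through this module gets a
``<name>.meta.json`` sidecar recording the seed and a hash of the
configuration that produced it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .containers import MotionParams, ParcellationMask, TensorField

__all__ = [
    "RunConfig",
    "read_config",
    "write_config",
    "write_nifti",
    "read_nifti",
    "write_tensor_field",
    "read_tensor_field",
    "read_parcellation",
    "write_parcellation",
    "read_motion_tsv",
    "write_tsv",
    "read_tsv",
    "write_provenance",
    "config_hash",
]


@dataclass
class RunConfig:
    """End-to-end study configuration (serialises losslessly to JSON)."""

    # cohort and grid
    grid_dims: tuple[int, int, int] = (8, 8, 8)
    n_rois: int = 6
    n_subjects: int = 40
    n_timepoints: int = 90
    tr_s: float = 2.0
    voxel_size_mm: tuple[float, float, float] = (3.0, 3.0, 3.0)
    # BOLD simulation
    fc_strength: float = 0.5
    local_coherence: float = 0.7
    bold_noise_sd: float = 1.0
    spike_fraction: float = 0.05
    # tensor simulation
    fa_background: float = 0.25
    fa_background_sd: float = 0.05
    bundle_fa: float = 0.8
    bundle_pairs: tuple[tuple[int, int], ...] = ((1, 2),)
    # tractography
    samples_per_voxel: int = 10
    max_steps: int = 60
    fa_stop: float = 0.15
    angle_limit_deg: float = 45.0
    direction_jitter_kappa: float = 50.0
    # planted threshold signal (per feature type, on extracted features)
    n_planted: int = 2
    planted_weight: float = 0.3
    measurement_noise_sd: float = 0.1
    # selection threshold override for every feature type; None keeps the
    # per-type defaults, which suit cohort sizes in the hundreds — small
    # demonstration cohorts need a more permissive filter
    selection_p: float | None = None
    # bookkeeping
    seed: int = 0
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs = dict(d)
        for key in ("grid_dims", "voxel_size_mm"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        if "bundle_pairs" in kwargs:
            kwargs["bundle_pairs"] = tuple(tuple(p) for p in kwargs["bundle_pairs"])
        return cls(**kwargs)


def config_hash(config) -> str:
    """Stable short hash of a config-like object."""
    if hasattr(config, "to_dict"):
        config = config.to_dict()
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def read_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        return RunConfig.from_dict(json.load(fh))


def write_config(config: RunConfig, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(config.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")


def write_provenance(path: str | Path, config, seed: int) -> None:
    """Sidecar JSON naming the config hash and seed behind an output."""
    sidecar = Path(str(path) + ".meta.json")
    with open(sidecar, "w") as fh:
        json.dump({"config_hash": config_hash(config), "seed": int(seed)}, fh, indent=2)
        fh.write("\n")


def _affine(voxel_size_mm) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = voxel_size_mm
    return aff


def write_nifti(
    path: str | Path,
    data: np.ndarray,
    voxel_size_mm=(3.0, 3.0, 3.0),
    affine: np.ndarray | None = None,
) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    if affine is None:
        affine = _affine(voxel_size_mm)
    nib.save(nib.Nifti1Image(np.asarray(data), affine), str(path))


def read_nifti(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Array and affine; raises FileNotFoundError with the path."""
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"no such file: {p}")
    img = nib.load(str(p))
    return np.asarray(img.dataobj), img.affine


def _voxel_size_from_affine(affine: np.ndarray) -> tuple[float, float, float]:
    return tuple(float(np.linalg.norm(affine[:3, i])) for i in range(3))


def write_tensor_field(path: str | Path, field: TensorField) -> None:
    """6-volume 4D NIfTI in component order xx, xy, xz, yy, yz, zz."""
    write_nifti(path, field.components, voxel_size_mm=field.voxel_size_mm)


def read_tensor_field(path: str | Path, mask: np.ndarray | None = None) -> TensorField:
    data, affine = read_nifti(path)
    if data.ndim != 4 or data.shape[-1] != 6:
        raise ValueError(f"tensor file must hold 6 component volumes, got {data.shape}")
    return TensorField(data, voxel_size_mm=_voxel_size_from_affine(affine), mask=mask)


def write_parcellation(path: str | Path, parcellation: ParcellationMask) -> None:
    write_nifti(
        path,
        parcellation.labels.astype(np.int16),
        voxel_size_mm=parcellation.voxel_size_mm,
    )


def read_parcellation(path: str | Path, n_rois: int | None = None) -> ParcellationMask:
    """Read an integer label volume; labels must cover 1..R without gaps."""
    data, affine = read_nifti(path)
    if not np.allclose(data, np.round(data)):
        raise ValueError("parcellation volume contains non-integer labels")
    labels = np.round(data).astype(np.int32)
    if labels.min() < 0:
        offenders = np.unique(labels[labels < 0]).tolist()
        raise ValueError(f"negative parcellation labels: {offenders}")
    R = n_rois if n_rois is not None else int(labels.max())
    present = set(np.unique(labels).tolist()) - {0}
    expected = set(range(1, R + 1))
    if present != expected:
        extra = sorted(present - expected)
        missing = sorted(expected - present)
        raise ValueError(
            f"parcellation labels not in 1..{R}: extra {extra}, missing {missing}"
        )
    return ParcellationMask(
        labels, n_rois=R, voxel_size_mm=_voxel_size_from_affine(affine)
    )


def write_tsv(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index)


def read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"no such file: {p}")
    return pd.read_csv(p, sep="\t", **kwargs)


def read_motion_tsv(path: str | Path) -> MotionParams:
    """Six-column motion table; a non-numeric first row is treated as header."""
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"no such file: {p}")
    try:
        df = pd.read_csv(p, sep="\t", header=None).astype(float)
    except ValueError:
        df = pd.read_csv(p, sep="\t").astype(float)
    return MotionParams(df.to_numpy())
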