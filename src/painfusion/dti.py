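"""Diffusion-tensor features: fractional anisotropy and structural
connectivity by stochastic streamline sampling.

The pipeline starts from an already-fitted tensor field (tensor fitting,
eddy correction and spatial normalisation are out of scope). Fractional
anisotropy is the normalised eigenvalue dispersion

    FA = sqrt(1/2) * sqrt(((l1-l2)^2 + (l2-l3)^2 + (l3-l1)^2)
                          / (l1^2 + l2^2 + l3^2)),

zero for isotropic diffusion and 1 in the single-axis limit. Structural
connectivity between ROIs i and j is the fraction of stochastic
streamlines seeded in i whose path intersects j, with a fixed number of
samples per seed voxel. Directions are drawn from a von Mises-Fisher
perturbation of the local principal tensor axis; each sample is tracked
in both directions from its seed, FSL-style, and the two half-tracks
count as one fiber.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import ConnectivityMatrix, ParcellationMask, RegionalMap, TensorField

__all__ = [
    "TractographyParams",
    "fa_from_eigenvalues",
    "fa_map",
    "principal_direction",
    "track_streamline",
    "structural_connectivity",
]


@dataclass
class TractographyParams:
    """Stopping and sampling rules of the streamline propagator.

    ``samples_per_voxel`` defaults to 5000 fibers per seed voxel but is
    freely scalable; connectivity estimates are binomial proportions, so
    their standard error shrinks as 1/sqrt(samples).
    """

    samples_per_voxel: int = 5000
    step_mm: float | None = None  # default: half the smallest voxel size
    max_steps: int = 500
    angle_limit_deg: float = 45.0
    fa_stop: float = 0.15
    direction_jitter_kappa: float = np.inf
    first_hit_only: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.samples_per_voxel < 1:
            raise ValueError("samples_per_voxel must be >= 1")
        if self.step_mm is not None and self.step_mm <= 0:
            raise ValueError("step_mm must be positive")
        if not 0.0 <= self.fa_stop <= 1.0:
            raise ValueError("fa_stop must lie in [0, 1]")
        if self.direction_jitter_kappa <= 0:
            raise ValueError("direction_jitter_kappa must be positive")


def fa_from_eigenvalues(l1, l2, l3):
    """Fractional anisotropy from the three tensor eigenvalues.

    Scale-invariant, in [0, 1]; (1, 1, 1) -> 0 (spherical diffusion) and
    (1, 0, 0) -> 1 (degenerate line tensor). Accepts scalars or arrays.
    """
    l1 = np.asarray(l1, dtype=float)
    l2 = np.asarray(l2, dtype=float)
    l3 = np.asarray(l3, dtype=float)
    if np.any(l1 < 0) or np.any(l2 < 0) or np.any(l3 < 0):
        raise ValueError("eigenvalues must be non-negative")
    ssq = l1**2 + l2**2 + l3**2
    if np.any(ssq == 0):
        raise ValueError("all eigenvalues zero: FA undefined")
    num = (l1 - l2) ** 2 + (l2 - l3) ** 2 + (l3 - l1) ** 2
    fa = np.clip(np.sqrt(0.5) * np.sqrt(num / ssq), 0.0, 1.0)
    return fa if fa.ndim else float(fa)


#: eigenvalue tolerance for the PSD check, relative to the largest eigenvalue
PSD_TOL = 1e-8


def _eigendecompose(field: TensorField) -> tuple[np.ndarray, np.ndarray]:
    """Batched eigendecomposition of in-mask tensors (ascending order)."""
    tensors = field.as_matrices()
    vals, vecs = np.linalg.eigh(tensors)
    return vals, vecs


def fa_map(field: TensorField) -> RegionalMap:
    """Voxel-wise FA from the tensor eigenvalues; out-of-mask voxels 0."""
    vals, _ = _eigendecompose(field)
    scale = np.abs(vals).max(axis=-1)
    bad = field.mask & (vals[..., 0] < -PSD_TOL * np.maximum(scale, 1e-300))
    if np.any(bad):
        idx = tuple(int(i) for i in np.argwhere(bad)[0])
        raise ValueError(f"tensor at voxel {idx} is not positive semi-definite")
    vals = np.clip(vals, 0.0, None)
    out = np.zeros(field.shape)
    m = field.mask
    nonzero = m & (vals.sum(axis=-1) > 0)
    out[nonzero] = fa_from_eigenvalues(
        vals[nonzero][:, 2], vals[nonzero][:, 1], vals[nonzero][:, 0]
    )
    return RegionalMap(out, kind="fa", mask=m)


def principal_direction(tensor: np.ndarray) -> np.ndarray:
    """Unit eigenvector of the largest eigenvalue (sign-ambiguous).

    Degenerate spectra get a deterministic arbitrary choice; the sign is
    fixed so the largest-magnitude component is positive.
    """
    tensor = np.asarray(tensor, dtype=float)
    vals, vecs = np.linalg.eigh(tensor)
    v = vecs[:, -1]
    i = np.argmax(np.abs(v))
    if v[i] < 0:
        v = -v
    return v


def _principal_axes(field: TensorField) -> np.ndarray:
    """(x, y, z, 3) principal axes, deterministic sign convention."""
    _, vecs = _eigendecompose(field)
    axes = vecs[..., :, -1]
    comp = np.abs(axes).argmax(axis=-1)
    sign = np.take_along_axis(axes, comp[..., None], axis=-1)[..., 0]
    axes = axes * np.where(sign < 0, -1.0, 1.0)[..., None]
    return axes


def _sample_vmf(mu: np.ndarray, kappa: float, rng: np.random.Generator) -> np.ndarray:
    """One draw from von Mises-Fisher on S^2 around unit rows of ``mu``.

    Wood's rejection-free inversion for p=3: W = 1 + log(U + (1-U)e^{-2k})/k.
    ``kappa = inf`` returns the mean directions exactly.
    """
    mu = np.atleast_2d(mu)
    n = mu.shape[0]
    if np.isinf(kappa):
        return mu.copy()
    u = rng.random(n)
    w = 1.0 + np.log(u + (1.0 - u) * np.exp(-2.0 * kappa)) / kappa
    phi = rng.random(n) * 2.0 * np.pi
    s = np.sqrt(np.clip(1.0 - w**2, 0.0, None))
    # orthonormal frame per mean direction
    helper = np.where(
        np.abs(mu[:, 2:3]) < 0.9, [[0.0, 0.0, 1.0]], [[0.0, 1.0, 0.0]]
    )
    b1 = np.cross(mu, helper)
    b1 /= np.linalg.norm(b1, axis=1, keepdims=True)
    b2 = np.cross(mu, b1)
    return (
        w[:, None] * mu
        + s[:, None] * (np.cos(phi)[:, None] * b1 + np.sin(phi)[:, None] * b2)
    )


def _voxel_of(pos_mm: np.ndarray, voxel_size: np.ndarray) -> np.ndarray:
    return np.floor(pos_mm / voxel_size).astype(int)


def track_streamline(
    field: TensorField,
    fa: RegionalMap,
    start_voxel: tuple[int, int, int],
    params: TractographyParams,
    rng: np.random.Generator,
    initial_sign: float = 1.0,
) -> list[tuple[int, int, int]]:
    """One stochastic half-track from a seed voxel; returns visited voxels.

    Steps of ``step_mm`` follow directions sampled around the local
    principal axis (concentration ``direction_jitter_kappa``), with the
    sign chosen to keep the turning angle minimal; propagation stops on
    mask exit, FA below ``fa_stop``, a turn beyond ``angle_limit_deg``,
    or ``max_steps``. A seed below the FA threshold yields a length-1
    path.
    """
    shape = np.array(field.shape)
    voxel_size = np.asarray(field.voxel_size_mm, dtype=float)
    step = params.step_mm or 0.5 * voxel_size.min()
    cos_limit = np.cos(np.deg2rad(params.angle_limit_deg))
    axes = _principal_axes(field)
    fa_data = fa.data

    v = np.asarray(start_voxel, dtype=int)
    path = [tuple(int(i) for i in v)]
    if not field.mask[tuple(v)] or fa_data[tuple(v)] < params.fa_stop:
        return path

    pos = (v + 0.5) * voxel_size
    prev_dir = initial_sign * axes[tuple(v)]
    for _ in range(params.max_steps):
        vox = tuple(_voxel_of(pos, voxel_size))
        mu = axes[vox]
        d = _sample_vmf(mu, params.direction_jitter_kappa, rng)[0]
        if d @ prev_dir < 0:
            d = -d
        if d @ prev_dir < cos_limit:
            break
        pos = pos + step * d
        prev_dir = d
        nv = _voxel_of(pos, voxel_size)
        if np.any(nv < 0) or np.any(nv >= shape):
            break
        tv = tuple(int(i) for i in nv)
        if not field.mask[tv] or fa_data[tv] < params.fa_stop:
            break
        if tv != path[-1]:
            path.append(tv)
    return path


def structural_connectivity(
    field: TensorField,
    parcellation: ParcellationMask,
    params: TractographyParams,
) -> ConnectivityMatrix:
    """Streamline-probability connectivity matrix.

    Entry (i, j), i != j, is the number of fibers seeded in ROI i whose
    path passes through ROI j, divided by the total number of fibers
    sampled from ROI i (samples_per_voxel x seed-voxel count). Each
    fiber is tracked in both directions from its seed and counted once
    per target ROI it touches (or only for its first ROI encounter when
    ``first_hit_only``). The diagonal is 0.
    """
    if field.shape != parcellation.shape:
        raise ValueError("tensor field and parcellation grids differ")
    R = parcellation.n_rois
    labels = parcellation.labels
    mask = np.asarray(field.mask)
    voxel_size = np.asarray(field.voxel_size_mm, dtype=float)
    step = params.step_mm or 0.5 * voxel_size.min()
    cos_limit = np.cos(np.deg2rad(params.angle_limit_deg))
    axes = _principal_axes(field)
    fa_data = fa_map(field).data
    shape = np.array(field.shape)

    counts = np.zeros((R, R))
    totals = np.zeros(R)
    rng = np.random.default_rng(params.seed)

    for i in range(1, R + 1):
        seeds = np.argwhere((labels == i) & mask)
        if seeds.size == 0:
            raise ValueError(f"ROI {i} has no in-mask voxels")
        n_seed = seeds.shape[0]
        S = params.samples_per_voxel
        N = n_seed * S
        totals[i - 1] = N
        seed_vox = np.repeat(seeds, S, axis=0)  # (N, 3)

        # ROI-membership record per fiber; seeds count as visited
        visited = np.zeros((N, R + 1), dtype=bool)
        visited[np.arange(N), labels[tuple(seed_vox.T)]] = True
        # first non-seed ROI each fiber enters (0 = none yet)
        first_target = np.zeros(N, dtype=int)

        for direction_sign in (1.0, -1.0):
            pos = (seed_vox + 0.5) * voxel_size
            prev = direction_sign * axes[tuple(seed_vox.T)]
            active = fa_data[tuple(seed_vox.T)] >= params.fa_stop
            cur_pos = pos.copy()
            cur_prev = prev.copy()
            for _ in range(params.max_steps):
                if not active.any():
                    break
                idx = np.flatnonzero(active)
                vox = np.floor(cur_pos[idx] / voxel_size).astype(int)
                mu = axes[tuple(vox.T)]
                d = _sample_vmf(mu, params.direction_jitter_kappa, rng)
                dots = np.einsum("ij,ij->i", d, cur_prev[idx])
                flip = dots < 0
                d[flip] = -d[flip]
                dots = np.abs(dots)
                stop_angle = dots < cos_limit
                newpos = cur_pos[idx] + step * d
                nv = np.floor(newpos / voxel_size).astype(int)
                oob = np.any(nv < 0, axis=1) | np.any(nv >= shape, axis=1)
                ok = ~stop_angle & ~oob
                nv_ok = nv[ok]
                inmask = mask[tuple(nv_ok.T)]
                low_fa = fa_data[tuple(nv_ok.T)] < params.fa_stop
                keep = inmask & ~low_fa
                ok_idx = idx[ok]
                surv = ok_idx[keep]
                # record ROI membership of surviving positions
                lab = labels[tuple(nv_ok[keep].T)]
                visited[surv, lab] = True
                fresh = (first_target[surv] == 0) & (lab != i) & (lab != 0)
                first_target[surv[fresh]] = lab[fresh]
                cur_pos[ok_idx] = newpos[ok]
                cur_prev[ok_idx] = d[ok]
                newactive = np.zeros_like(active)
                newactive[surv] = True
                active = newactive

        if params.first_hit_only:
            row = np.bincount(first_target, minlength=R + 1)[1:]
        else:
            h = visited[:, 1:].copy()  # drop background column
            h[:, i - 1] = False
            row = h.sum(axis=0)
        counts[i - 1] = row

    probs = counts / totals[:, None]
    np.fill_diagonal(probs, 0.0)
    return ConnectivityMatrix(
        np.clip(probs, 0.0, 1.0), kind="sc_probability", roi_labels=list(range(1, R + 1))
    )


def symmetrize(matrix: np.ndarray) -> np.ndarray:
    """Average a possibly asymmetric connectivity matrix with its transpose."""
    m = np.asarray(matrix, dtype=float)
    return (m + m.T) / 2.0
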