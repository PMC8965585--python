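"""Resting-state fMRI temporal preprocessing and feature extraction.

The temporal chain operates on already-aligned volumes: discard of the
first volumes, Friston-24 motion expansion plus motion-spike regressors,
voxel-wise nuisance regression, and an ideal 0.01-0.1 Hz bandpass. Two
feature types follow: voxel-wise regional homogeneity (Kendall's W of a
voxel's time series with its 3x3x3 neighbourhood) and ROI-pair
functional connectivity (Pearson correlation of mean ROI time courses,
Fisher z-transformed, lower triangle vectorized).

Spatial steps requiring a registration toolchain (realignment, slice
timing, segmentation, template normalisation) are out of scope.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from scipy.linalg import qr as _qr_pivoted

from .containers import (
    BoldVolume,
    ConnectivityMatrix,
    FeatureTable,
    MotionParams,
    ParcellationMask,
    RegionalMap,
)

logger = logging.getLogger(__name__)

__all__ = [
    "discard_initial_volumes",
    "friston24",
    "framewise_displacement",
    "scrub_mask",
    "nuisance_regress",
    "bandpass",
    "reho_map",
    "smooth_gaussian",
    "equalize",
    "roi_timecourses",
    "fc_matrix",
    "vectorize_lower",
    "devectorize_lower",
    "preprocess_bold",
    "extract_fmri_features",
    "FMRI_PIPELINE_STAGES",
]

#: fixed stage order of the full fMRI chain
FMRI_PIPELINE_STAGES = (
    "discard",
    "regress",
    "bandpass",
    "reho",
    "smooth",
    "equalize",
)

#: Fisher-z clip: correlations are bounded away from +-1 so z stays finite
FISHER_Z_CLIP = 1.0 - 1e-7


def discard_initial_volumes(bold: BoldVolume, n: int = 10) -> BoldVolume:
    """Drop the first ``n`` volumes (magnetisation-equilibration frames)."""
    if n < 0:
        raise ValueError("n must be >= 0")
    t = bold.n_timepoints
    if t <= n:
        raise ValueError(f"cannot discard {n} of {t} volumes")
    return BoldVolume(bold.data[..., n:], tr_s=bold.tr_s, mask=bold.mask)


def friston24(motion: MotionParams) -> np.ndarray:
    """24-parameter motion expansion: [p(t), p(t-1), p(t)^2, p(t-1)^2].

    The lagged block's first row is zero-filled.
    """
    p = motion.table
    lagged = np.vstack([np.zeros((1, 6)), p[:-1]])
    return np.hstack([p, lagged, p**2, lagged**2])


def framewise_displacement(
    motion: MotionParams, head_radius_mm: float = 50.0
) -> np.ndarray:
    """Power-style FD: sum of absolute frame-to-frame motion increments.

    Rotations (rad) are converted to arc length on a sphere of
    ``head_radius_mm``. FD of the first frame is 0.
    """
    p = motion.table
    if p.shape[0] < 2:
        raise ValueError("framewise displacement needs at least 2 frames")
    d = np.diff(p, axis=0)
    fd = np.abs(d[:, :3]).sum(axis=1) + head_radius_mm * np.abs(d[:, 3:]).sum(axis=1)
    return np.concatenate([[0.0], fd])


def scrub_mask(
    fd: np.ndarray, threshold: float = 0.2
) -> tuple[np.ndarray, np.ndarray]:
    """Keep-vector and spike-regressor matrix for high-motion frames.

    A frame is scrubbed when FD exceeds the threshold strictly (a frame
    at exactly the threshold is kept). Each scrubbed frame contributes
    one indicator column, so its variance is absorbed in regression
    rather than the frame being deleted; this preserves temporal
    continuity for the subsequent bandpass.
    """
    fd = np.asarray(fd, dtype=float)
    if not np.all(np.isfinite(fd)):
        raise ValueError("FD contains non-finite values")
    keep = fd <= threshold
    scrubbed = np.flatnonzero(~keep)
    spikes = np.zeros((fd.size, scrubbed.size))
    spikes[scrubbed, np.arange(scrubbed.size)] = 1.0
    return keep, spikes


def nuisance_regress(bold: BoldVolume, design: np.ndarray) -> BoldVolume:
    """Voxel-wise OLS residuals against the design (intercept added)."""
    t = bold.n_timepoints
    design = np.asarray(design, dtype=float)
    if design.ndim == 1:
        design = design[:, None]
    if design.shape[0] != t:
        raise ValueError(f"design has {design.shape[0]} rows, BOLD has {t} frames")
    D = np.hstack([np.ones((t, 1)), design])
    rank = np.linalg.matrix_rank(D)
    if rank < D.shape[1]:
        # name the columns a pivoted QR leaves without a pivot
        _, _, piv = _qr_pivoted(D, mode="economic", pivoting=True)
        dependent = sorted(piv[rank:])
        # column 0 is the implicit intercept
        offenders = [c - 1 for c in dependent if c > 0]
        raise ValueError(
            f"rank-deficient nuisance design: columns {offenders} are "
            "linearly dependent (after intercept augmentation)"
        )
    Y = bold.data.reshape(-1, t).T  # t x voxels
    beta, *_ = np.linalg.lstsq(D, Y, rcond=None)
    resid = (Y - D @ beta).T.reshape(bold.data.shape)
    return BoldVolume(resid, tr_s=bold.tr_s, mask=bold.mask)


def bandpass(
    bold: BoldVolume, low_hz: float = 0.01, high_hz: float = 0.1
) -> BoldVolume:
    """Ideal frequency-domain bandpass applied per voxel after demeaning.

    Frequency bins with low_hz <= f <= high_hz are retained exactly; all
    other bins (including DC) are zeroed.
    """
    nyquist = 1.0 / (2.0 * bold.tr_s)
    if not 0 <= low_hz < high_hz:
        raise ValueError("need 0 <= low_hz < high_hz")
    if high_hz > nyquist + 1e-12:
        raise ValueError(
            f"high_hz {high_hz} exceeds Nyquist {nyquist:.4g} Hz at TR {bold.tr_s}s"
        )
    t = bold.n_timepoints
    data = bold.data - bold.data.mean(axis=-1, keepdims=True)
    spectrum = np.fft.rfft(data, axis=-1)
    freqs = np.fft.rfftfreq(t, d=bold.tr_s)
    keep = (freqs >= low_hz - 1e-12) & (freqs <= high_hz + 1e-12)
    spectrum[..., ~keep] = 0.0
    out = np.fft.irfft(spectrum, n=t, axis=-1)
    return BoldVolume(out, tr_s=bold.tr_s, mask=bold.mask)


_NEIGHBORHOOD_KERNELS: dict[int, np.ndarray] = {}


def _neighborhood_kernel(neighborhood: int) -> np.ndarray:
    """3x3x3 structuring element: 7 = faces, 19 = faces+edges, 27 = full."""
    if neighborhood in _NEIGHBORHOOD_KERNELS:
        return _NEIGHBORHOOD_KERNELS[neighborhood]
    offs = np.stack(
        np.meshgrid([-1, 0, 1], [-1, 0, 1], [-1, 0, 1], indexing="ij"), axis=-1
    )
    cheb = np.abs(offs).sum(axis=-1)
    if neighborhood == 27:
        kern = np.ones((3, 3, 3), dtype=bool)
    elif neighborhood == 19:
        kern = cheb <= 2
    elif neighborhood == 7:
        kern = cheb <= 1
    else:
        raise ValueError("neighborhood must be one of 7, 19, 27")
    _NEIGHBORHOOD_KERNELS[neighborhood] = kern
    return kern


def kendalls_w(series: np.ndarray, tie_correction: bool = False) -> float:
    """Kendall's coefficient of concordance of K series over n timepoints.

    Each series is ranked over time (average ranks at ties); with rank
    sums R_t, S = sum_t (R_t - mean R)^2 and W = 12 S / (K^2 (n^3 - n)).
    The optional tie correction subtracts K * sum_j T_j from the
    denominator with T_j = sum over tie groups of (g^3 - g).
    """
    series = np.asarray(series, dtype=float)
    if series.ndim != 2:
        raise ValueError("series must be K x n")
    K, n = series.shape
    ranks = stats.rankdata(series, axis=1)
    if np.ptp(series, axis=1).max() == 0:
        logger.warning("all series constant in neighbourhood; W undefined, set to 0")
        return 0.0
    R = ranks.sum(axis=0)
    S = ((R - R.mean()) ** 2).sum()
    denom = K**2 * (n**3 - n)
    if tie_correction:
        T = 0.0
        for j in range(K):
            _, counts = np.unique(series[j], return_counts=True)
            T += float(((counts**3) - counts).sum())
        denom -= K * T
    if denom <= 0:
        return 0.0
    return float(12.0 * S / denom)


def reho_map(
    bold: BoldVolume,
    mask: np.ndarray | None = None,
    neighborhood: int = 27,
    k_min: int = 4,
    tie_correction: bool = False,
) -> RegionalMap:
    """Voxel-wise regional homogeneity (Kendall's W over the neighbourhood).

    For each in-mask voxel, W is computed over the K <= 27 in-mask time
    series of the 3x3x3 block centred there (truncated at mask and grid
    edges); voxels with fewer than ``k_min`` contributing series get 0.
    Fully vectorised: time ranks once per voxel, rank sums by spatial
    correlation with the neighbourhood kernel.
    """
    if bold.n_timepoints < 3:
        raise ValueError("ReHo needs at least 3 timepoints")
    mask = bold.mask if mask is None else np.asarray(mask, dtype=bool)
    kern = _neighborhood_kernel(neighborhood).astype(float)
    t = bold.n_timepoints
    n = t

    ranks = stats.rankdata(bold.data, axis=-1)
    ranks = np.where(mask[..., None], ranks, 0.0)

    K = ndimage.correlate(mask.astype(float), kern, mode="constant", cval=0.0)
    K = np.round(K).astype(int)

    # rank sums over the neighbourhood, per timepoint
    R = np.empty_like(bold.data)
    for ti in range(t):
        R[..., ti] = ndimage.correlate(ranks[..., ti], kern, mode="constant", cval=0.0)
    S = ((R - R.mean(axis=-1, keepdims=True)) ** 2).sum(axis=-1)

    denom = (K.astype(float) ** 2) * (n**3 - n)
    if tie_correction:
        T = np.zeros(mask.shape)
        flat = bold.data[mask]
        Tvox = np.zeros(flat.shape[0])
        for i, row in enumerate(flat):
            _, counts = np.unique(row, return_counts=True)
            Tvox[i] = ((counts**3) - counts).sum()
        T[mask] = Tvox
        denom -= K * ndimage.correlate(T, kern, mode="constant", cval=0.0)

    with np.errstate(divide="ignore", invalid="ignore"):
        W = np.where(denom > 0, 12.0 * S / denom, 0.0)
    W = np.where(mask & (K >= k_min), W, 0.0)

    # neighbourhoods whose series are all constant have S == 0 trivially;
    # they are already 0 but deserve the documented warning
    if np.any(mask & (np.ptp(bold.data, axis=-1) == 0)):
        logger.warning("constant time series inside mask; affected ReHo set by ties")
    W = np.clip(W, 0.0, 1.0)
    return RegionalMap(W, kind="reho", mask=mask)


def smooth_gaussian(
    regional: RegionalMap,
    fwhm_mm: float = 6.0,
    voxel_size_mm: tuple[float, float, float] = (3.0, 3.0, 3.0),
) -> RegionalMap:
    """Mask-aware separable Gaussian smoothing.

    sigma = FWHM / (2 sqrt(2 ln 2)) per axis, in voxel units; smoothing
    weights are renormalised over in-mask voxels so values near the mask
    edge are not diluted by the background.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be >= 0")
    if fwhm_mm == 0:
        return RegionalMap(regional.data.copy(), kind=regional.kind, mask=regional.mask)
    sigma = np.array(
        [fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / v for v in voxel_size_mm]
    )
    m = regional.mask.astype(float)
    num = ndimage.gaussian_filter(regional.data * m, sigma=sigma, mode="constant")
    den = ndimage.gaussian_filter(m, sigma=sigma, mode="constant")
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(regional.mask, num / np.maximum(den, 1e-300), 0.0)
    return RegionalMap(out, kind=regional.kind, mask=regional.mask)


def equalize(regional: RegionalMap, mask: np.ndarray | None = None) -> RegionalMap:
    """Whole-brain equalisation: divide by the in-mask mean (mReHo style)."""
    mask = regional.mask if mask is None else np.asarray(mask, dtype=bool)
    mean = regional.data[mask].mean()
    if mean == 0:
        raise ValueError("in-mask mean is zero; cannot equalize")
    out = np.where(mask, regional.data / mean, 0.0)
    return RegionalMap(out, kind=regional.kind, mask=mask)


def zscore_equalize(regional: RegionalMap, mask: np.ndarray | None = None) -> RegionalMap:
    """Alternative equalisation: in-mask z-standardisation."""
    mask = regional.mask if mask is None else np.asarray(mask, dtype=bool)
    vals = regional.data[mask]
    sd = vals.std()
    if sd == 0:
        raise ValueError("in-mask sd is zero; cannot z-standardize")
    out = np.where(mask, (regional.data - vals.mean()) / sd, 0.0)
    return RegionalMap(out, kind=regional.kind, mask=mask)


def roi_timecourses(bold: BoldVolume, parcellation: ParcellationMask) -> np.ndarray:
    """R x t matrix of unweighted mean in-mask voxel series per ROI."""
    if parcellation.shape != bold.data.shape[:3]:
        raise ValueError("parcellation grid does not match BOLD spatial grid")
    R = parcellation.n_rois
    out = np.empty((R, bold.n_timepoints))
    labels = parcellation.labels
    for r in range(1, R + 1):
        sel = (labels == r) & bold.mask
        if not np.any(sel):
            raise ValueError(f"ROI {r} has no in-mask voxels")
        out[r - 1] = bold.data[sel].mean(axis=0)
    return out


def fc_matrix(timecourses: np.ndarray, roi_labels: list[int] | None = None) -> ConnectivityMatrix:
    """Fisher-z functional connectivity from ROI mean time courses.

    Pearson r per ROI pair, clipped to +-(1 - 1e-7) before arctanh so z
    stays finite when two courses are numerically collinear; diagonal
    stored as 0.
    """
    tc = np.asarray(timecourses, dtype=float)
    sd = tc.std(axis=1)
    if np.any(sd == 0):
        bad = int(np.flatnonzero(sd == 0)[0]) + 1
        raise ValueError(f"ROI {bad} has a constant time course")
    r = np.corrcoef(tc)
    r = np.clip(r, -FISHER_Z_CLIP, FISHER_Z_CLIP)
    z = np.arctanh(r)
    np.fill_diagonal(z, 0.0)
    z = (z + z.T) / 2.0
    return ConnectivityMatrix(z, kind="fc_fisher_z", roi_labels=roi_labels or [])


def vectorize_lower(matrix: np.ndarray) -> tuple[np.ndarray, pd.DataFrame]:
    """Strict lower triangle in row-major order, with (row, col) metadata.

    A 90-ROI matrix yields 90*89/2 = 4005 features.
    """
    m = np.asarray(matrix)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("vectorize_lower expects a square matrix")
    rows, cols = np.tril_indices(m.shape[0], k=-1)
    meta = pd.DataFrame({"roi_a": rows + 1, "roi_b": cols + 1})
    return m[rows, cols], meta


def devectorize_lower(vector: np.ndarray, n_rois: int) -> np.ndarray:
    """Rebuild the symmetric matrix (zero diagonal) from a lower-triangle vector."""
    vector = np.asarray(vector, dtype=float)
    expected = n_rois * (n_rois - 1) // 2
    if vector.size != expected:
        raise ValueError(f"expected {expected} entries for {n_rois} ROIs, got {vector.size}")
    out = np.zeros((n_rois, n_rois))
    rows, cols = np.tril_indices(n_rois, k=-1)
    out[rows, cols] = vector
    out[cols, rows] = vector
    return out


def preprocess_bold(
    bold: BoldVolume,
    motion: MotionParams,
    n_discard: int = 10,
    fd_threshold: float = 0.2,
    low_hz: float = 0.01,
    high_hz: float = 0.1,
) -> BoldVolume:
    """Temporal preprocessing chain: discard -> regress -> bandpass.

    The motion table must cover the pre-discard series; its first
    ``n_discard`` rows are dropped alongside the volumes. Nuisance
    regressors are the Friston-24 expansion plus one spike column per
    scrubbed frame (FD > threshold).
    """
    if motion.n_frames != bold.n_timepoints:
        raise ValueError(
            f"motion rows ({motion.n_frames}) != BOLD frames ({bold.n_timepoints})"
        )
    bold = discard_initial_volumes(bold, n_discard)
    motion = MotionParams(motion.table[n_discard:])
    design = friston24(motion)
    fd = framewise_displacement(motion)
    _, spikes = scrub_mask(fd, threshold=fd_threshold)
    if spikes.shape[1]:
        design = np.hstack([design, spikes])
    bold = nuisance_regress(bold, design)
    return bandpass(bold, low_hz=low_hz, high_hz=high_hz)


def extract_fmri_features(
    bold: BoldVolume,
    motion: MotionParams,
    parcellation: ParcellationMask,
    n_discard: int = 10,
    fwhm_mm: float = 6.0,
    neighborhood: int = 27,
) -> tuple[RegionalMap, np.ndarray, pd.DataFrame, ConnectivityMatrix]:
    """Full single-subject fMRI chain in the fixed stage order.

    Returns the equalized ReHo map, the vectorized FC features with ROI-
    pair metadata, and the FC matrix itself. Stage order is the module
    constant ``FMRI_PIPELINE_STAGES``: discard -> regress -> bandpass ->
    reho -> smooth -> equalize; FC is computed from the same
    preprocessed series.
    """
    clean = preprocess_bold(bold, motion, n_discard=n_discard)
    reho = reho_map(clean, neighborhood=neighborhood)
    reho = smooth_gaussian(reho, fwhm_mm=fwhm_mm, voxel_size_mm=parcellation.voxel_size_mm)
    reho = equalize(reho)
    tc = roi_timecourses(clean, parcellation)
    fc = fc_matrix(tc)
    fc_vec, fc_meta = vectorize_lower(fc.values)
    fc_meta.insert(0, "type", "fc")
    return reho, fc_vec, fc_meta, fc
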