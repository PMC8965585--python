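"""End-to-end synthetic study: images -> features -> prediction -> report.

``run_study`` drives the whole chain at a configurable scale: it builds
a parcellation, simulates per-subject BOLD series (with motion), and
diffusion-tensor fields (with fiber bundles), extracts the four feature
blocks (ReHo, FC, FA, SC), plants a linear threshold signal on a few
extracted feature columns, observes it through the two-run staircase,
runs the nine-model leave-one-out suite, and assembles the evaluation
and stability tables.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from . import dti, fmri, synthetic
from .containers import FeatureTable, ParcellationMask, PhenotypeVector
from .evaluate import EvaluationReport, build_report
from .io import RunConfig
from .predict import run_model_suite
from .stability import annotate_regions, common_features, region_counts, selection_frequency

logger = logging.getLogger(__name__)

__all__ = ["extract_subject_features", "build_feature_tables", "run_study", "StudyOutput"]


def _roi_cov(n_rois: int, fc_strength: float) -> np.ndarray:
    """Identity covariance with one planted strong off-diagonal pair (1, 2)."""
    cov = np.eye(n_rois)
    cov[0, 1] = cov[1, 0] = fc_strength
    return cov


def extract_subject_features(
    parcellation: ParcellationMask,
    config: RunConfig,
    subject_seed: int,
) -> dict[str, np.ndarray]:
    """Simulate one subject's images and extract all four feature vectors."""
    rng = np.random.default_rng(subject_seed)
    seeds = rng.integers(2**31 - 1, size=4)

    # fMRI: latent ROI series with one strong FC pair, then the fixed chain
    bold = synthetic.simulate_bold(
        parcellation,
        n_timepoints=config.n_timepoints,
        tr_s=config.tr_s,
        roi_cov=_roi_cov(config.n_rois, config.fc_strength),
        local_coherence=config.local_coherence,
        noise_sd=config.bold_noise_sd,
        seed=int(seeds[0]),
    )
    motion = synthetic.simulate_motion(
        config.n_timepoints, seed=int(seeds[1]), spike_fraction=config.spike_fraction
    )
    reho_map_eq, fc_vec, _, _ = fmri.extract_fmri_features(
        bold, motion, parcellation
    )
    mask = parcellation.brain_mask()
    reho_vec = reho_map_eq.data[mask]

    # DTI: noisy background FA plus fixed bundles, then FA map and SC
    fa_bg = np.clip(
        config.fa_background
        + config.fa_background_sd * rng.standard_normal(parcellation.shape),
        0.01,
        0.95,
    )
    bundles = [
        synthetic.BundleSpec(a, b, width_vox=1.0, fa=config.bundle_fa)
        for a, b in config.bundle_pairs
    ]
    field = synthetic.simulate_tensor_field(
        parcellation,
        fa_targets=fa_bg,
        bundle_specs=bundles,
        seed=int(seeds[2]),
        voxel_size_mm=config.voxel_size_mm,
    )
    fa_vec = dti.fa_map(field).data[mask]
    params = dti.TractographyParams(
        samples_per_voxel=config.samples_per_voxel,
        max_steps=config.max_steps,
        fa_stop=config.fa_stop,
        angle_limit_deg=config.angle_limit_deg,
        direction_jitter_kappa=config.direction_jitter_kappa,
        seed=int(seeds[3]),
    )
    sc = dti.structural_connectivity(field, parcellation, params)
    sc_vec, _ = fmri.vectorize_lower(dti.symmetrize(sc.values))
    return {"reho": reho_vec, "fc": fc_vec, "fa": fa_vec, "sc": sc_vec}


def build_feature_tables(
    parcellation: ParcellationMask, config: RunConfig
) -> dict[str, FeatureTable]:
    """Simulate and extract features for the whole cohort."""
    rng = np.random.default_rng(config.seed)
    subject_seeds = rng.integers(2**31 - 1, size=config.n_subjects)
    rows: dict[str, list[np.ndarray]] = {t: [] for t in ("reho", "fc", "fa", "sc")}
    for s in range(config.n_subjects):
        feats = extract_subject_features(parcellation, config, int(subject_seeds[s]))
        for t in rows:
            rows[t].append(feats[t])
        if (s + 1) % 10 == 0:
            logger.info("extracted features for %d/%d subjects", s + 1, config.n_subjects)

    mask = parcellation.brain_mask()
    vox = np.argwhere(mask)
    regional_meta = pd.DataFrame({"vx": vox[:, 0], "vy": vox[:, 1], "vz": vox[:, 2]})
    _, pair_meta = fmri.vectorize_lower(np.zeros((config.n_rois, config.n_rois)))

    subject_ids = [f"sub-{i + 1:04d}" for i in range(config.n_subjects)]
    tables = {}
    for t in ("reho", "fc", "fa", "sc"):
        meta = (regional_meta if t in ("reho", "fa") else pair_meta).copy()
        meta.insert(0, "type", t)
        tables[t] = FeatureTable(np.vstack(rows[t]), meta, subject_ids=subject_ids)
    return tables


def _plant_thresholds(
    tables: dict[str, FeatureTable], config: RunConfig
) -> PhenotypeVector:
    """Latent threshold = calibrated mean + weighted z-scored features.

    ``n_planted`` columns per feature type (highest-variance columns, a
    deterministic choice) contribute ``planted_weight`` each after
    z-scoring, observed through the two-measurement staircase.
    """
    rng = np.random.default_rng(config.seed + 1)
    latent = np.zeros(config.n_subjects)
    for t, table in tables.items():
        sd = table.matrix.std(axis=0)
        usable = np.flatnonzero(sd > 1e-12)
        if usable.size == 0:
            logger.warning("feature block %s is constant; no signal planted", t)
            continue
        order = usable[np.argsort(sd[usable])[::-1]]
        chosen = order[: config.n_planted]
        z = (table.matrix[:, chosen] - table.matrix[:, chosen].mean(axis=0)) / sd[chosen]
        latent += config.planted_weight * z.sum(axis=1)
    return synthetic.simulate_thresholds(
        latent[:, None],
        planted_weights={0: 1.0},
        noise_sd=config.measurement_noise_sd,
        seed=int(rng.integers(2**31 - 1)),
        latent_noise_sd=0.15,
    )


class StudyOutput:
    """Bundle of everything the end-to-end run produces."""

    def __init__(self, parcellation, tables, thresholds, suite, report, stability_tables):
        self.parcellation = parcellation
        self.tables = tables
        self.thresholds = thresholds
        self.suite = suite
        self.report: EvaluationReport = report
        self.stability_tables: dict[str, pd.DataFrame] = stability_tables


def run_study(config: RunConfig) -> StudyOutput:
    """Run the full synthetic study at the configured scale."""
    parcellation = synthetic.make_parcellation(
        config.grid_dims,
        config.n_rois,
        seed=config.seed,
        voxel_size_mm=config.voxel_size_mm,
    )
    tables = build_feature_tables(parcellation, config)
    thresholds = _plant_thresholds(tables, config)
    type_settings = None
    if config.selection_p is not None:
        from .predict import DEFAULT_TYPE_SETTINGS

        type_settings = {
            t: (algo, config.selection_p)
            for t, (algo, _) in DEFAULT_TYPE_SETTINGS.items()
        }
    suite = run_model_suite(tables, thresholds, seed=config.seed, type_settings=type_settings)
    report = build_report(suite)

    stability_tables: dict[str, pd.DataFrame] = {}
    for t in ("reho", "fc", "fa", "sc"):
        name = {"reho": "ReHo", "fc": "FC", "fa": "FA", "sc": "SC"}[t]
        freq = selection_frequency(suite[name], feature_meta=tables[t].feature_meta)
        freq["type"] = t
        retained = common_features(freq)
        if len(retained):
            annotated = annotate_regions(retained, parcellation=parcellation)
            stability_tables[t] = region_counts(annotated)
        else:
            stability_tables[t] = pd.DataFrame(columns=["type", "region", "count"])
    return StudyOutput(parcellation, tables, thresholds, suite, report, stability_tables)
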