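import numpy as np
import pytest

from painfusion import synthetic as syn
from painfusion.containers import BoldVolume, ParcellationMask


@pytest.fixture(scope="session")
def small_parcellation() -> ParcellationMask:
    return syn.make_parcellation((10, 10, 10), 8, seed=7)


@pytest.fixture(scope="session")
def two_roi_phantom():
    """12x5x5 grid split into two ROIs along x, with an x-aligned bundle."""
    labels = np.zeros((12, 5, 5), dtype=int)
    labels[:6] = 1
    labels[6:] = 2
    parc = ParcellationMask(labels, n_rois=2, voxel_size_mm=(2.0, 2.0, 2.0))
    field = syn.simulate_tensor_field(
        parc,
        fa_targets=0.05,
        bundle_specs=[syn.BundleSpec(1, 2, width_vox=1.0, fa=0.8)],
        seed=0,
    )
    return parc, field


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """Small planted-signal cohort for prediction-layer tests."""
    cfg = syn.GeneratorConfig(
        n_subjects=80,
        n_regional_features=80,
        n_connectivity_features=120,
        n_planted=5,
        feature_noise_sd=0.2,
        seed=42,
    )
    tables, thresholds = syn.simulate_feature_tables(cfg)
    return cfg, tables, thresholds


def make_bold(rng: np.random.Generator, shape=(4, 4, 4), t=40, tr_s=2.0) -> BoldVolume:
    return BoldVolume(rng.normal(size=shape + (t,)), tr_s=tr_s)
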