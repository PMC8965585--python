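"""fMRI preprocessing and feature extraction contracts, with independent
oracles for Kendall's W and the bandpass/regression algebra."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata

from painfusion import fmri
from painfusion.containers import BoldVolume, MotionParams, RegionalMap
from tests.conftest import make_bold


def brute_force_w(series: np.ndarray) -> float:
    """Independent rank-sum implementation of Kendall's W (no tie term)."""
    K, n = series.shape
    ranks = np.array([rankdata(s) for s in series])
    R = ranks.sum(axis=0)
    S = ((R - R.mean()) ** 2).sum()
    return 12.0 * S / (K**2 * (n**3 - n))


class TestDiscard:
    def test_300_minus_10_leaves_290(self, rng):
        bold = make_bold(rng, t=300)
        assert fmri.discard_initial_volumes(bold, 10).n_timepoints == 290

    def test_zero_is_identity(self, rng):
        bold = make_bold(rng, t=20)
        out = fmri.discard_initial_volumes(bold, 0)
        assert np.array_equal(out.data, bold.data)

    def test_too_few_frames_errors(self, rng):
        with pytest.raises(ValueError, match="discard"):
            fmri.discard_initial_volumes(make_bold(rng, t=5), 10)


class TestFriston24:
    def test_zero_motion_gives_zero_block(self):
        out = fmri.friston24(MotionParams(np.zeros((10, 6))))
        assert out.shape == (10, 24)
        assert np.all(out == 0)

    def test_lag_and_square_expansion(self):
        # ramp in the first column over 4 frames
        m = np.zeros((4, 6))
        m[:, 0] = [0, 1, 2, 3]
        out = fmri.friston24(MotionParams(m))
        assert np.array_equal(out[:, 0], [0, 1, 2, 3])
        assert np.array_equal(out[:, 6], [0, 0, 1, 2])  # lagged
        assert np.array_equal(out[:, 12], [0, 1, 4, 9])  # squared
        assert np.array_equal(out[:, 18], [0, 0, 1, 4])  # lagged squared

    def test_wrong_column_count_rejected(self):
        with pytest.raises(ValueError, match="6 columns"):
            MotionParams(np.zeros((5, 4)))


class TestFramewiseDisplacement:
    def test_constant_motion_gives_zero(self):
        fd = fmri.framewise_displacement(MotionParams(np.ones((8, 6))))
        assert np.all(fd == 0)

    def test_translation_step(self):
        m = np.zeros((3, 6))
        m[1, :3] = 0.1  # +0.1 mm on each translation axis
        fd = fmri.framewise_displacement(MotionParams(m))
        assert fd[1] == pytest.approx(0.3)

    def test_rotation_arc_length(self):
        m = np.zeros((3, 6))
        m[1, 3] = 0.001  # 1 mrad at 50 mm radius -> 0.05 mm
        fd = fmri.framewise_displacement(MotionParams(m))
        assert fd[1] == pytest.approx(0.05)


class TestScrubMask:
    def test_no_motion_no_spikes(self):
        keep, spikes = fmri.scrub_mask(np.zeros(10))
        assert keep.all() and spikes.shape == (10, 0)

    def test_single_spike_column(self):
        keep, spikes = fmri.scrub_mask(np.array([0.0, 0.3, 0.1]))
        assert np.array_equal(keep, [True, False, True])
        assert spikes.shape == (3, 1)
        assert np.array_equal(spikes[:, 0], [0, 1, 0])

    def test_threshold_boundary_is_kept(self):
        keep, spikes = fmri.scrub_mask(np.array([0.0, 0.2, 0.2000001]))
        assert np.array_equal(keep, [True, True, False])


class TestNuisanceRegress:
    def test_intercept_only_demeans(self, rng):
        bold = make_bold(rng, t=30)
        out = fmri.nuisance_regress(bold, np.zeros((30, 0)))
        assert np.allclose(out.data, bold.data - bold.data.mean(-1, keepdims=True))

    def test_series_in_design_space_vanishes(self, rng):
        t = 25
        col = rng.normal(size=t)
        data = np.tile(col, (2, 2, 2, 1))
        out = fmri.nuisance_regress(BoldVolume(data, 2.0), col[:, None])
        assert np.abs(out.data).max() < 1e-10

    def test_residuals_orthogonal_to_design(self, rng):
        t = 40
        design = rng.normal(size=(t, 5))
        bold = make_bold(rng, t=t)
        out = fmri.nuisance_regress(bold, design)
        resid = out.data.reshape(-1, t)
        dots = np.abs(resid @ design)
        scale = np.linalg.norm(resid, axis=1)[:, None] * np.linalg.norm(design, axis=0)
        assert (dots / np.maximum(scale, 1e-300)).max() < 1e-8

    def test_rank_deficient_design_names_columns(self, rng):
        t = 20
        a = rng.normal(size=t)
        design = np.stack([a, 2 * a], axis=1)
        with pytest.raises(ValueError, match="rank-deficient"):
            fmri.nuisance_regress(make_bold(rng, t=t), design)


class TestBandpass:
    @pytest.mark.parametrize(
        "freq,expect_kept", [(0.05, True), (0.2, False)]
    )
    def test_sinusoid_retention(self, freq, expect_kept):
        t, tr = 290, 2.0
        time = np.arange(t) * tr
        sig = np.sin(2 * np.pi * freq * time)
        bold = BoldVolume(np.tile(sig, (1, 1, 1, 1)), tr_s=tr)
        out = fmri.bandpass(bold).data[0, 0, 0]
        ratio = out.std() / sig.std()
        assert (ratio > 0.95) if expect_kept else (ratio < 0.05)

    def test_constant_series_zeroed(self):
        bold = BoldVolume(np.full((1, 1, 1, 64), 7.0), tr_s=2.0)
        assert np.abs(fmri.bandpass(bold).data).max() < 1e-12

    def test_above_nyquist_rejected(self, rng):
        with pytest.raises(ValueError, match="Nyquist"):
            fmri.bandpass(make_bold(rng, t=64), high_hz=0.3)


class TestReho:
    def test_identical_series_give_w_one(self, rng):
        data = np.tile(rng.normal(size=30), (3, 3, 3, 1))
        m = fmri.reho_map(BoldVolume(data, 2.0), k_min=1)
        assert m.data[1, 1, 1] == pytest.approx(1.0)

    def test_matches_brute_force_oracle(self, rng):
        """Vectorised W equals the independent rank-sum oracle on random
        neighbourhoods of varied size and length, interior and edge."""
        for trial in range(25):
            t = int(rng.integers(3, 21))
            data = rng.normal(size=(4, 4, 4, t))
            if trial % 3 == 0:
                data = np.round(data)  # force ties
            bold = BoldVolume(data, 2.0)
            m = fmri.reho_map(bold, k_min=1)
            for v in [(1, 2, 1), (0, 0, 0), (3, 3, 3), (2, 1, 3)]:
                x, y, z = v
                block = data[
                    max(0, x - 1) : x + 2, max(0, y - 1) : y + 2, max(0, z - 1) : z + 2
                ].reshape(-1, t)
                assert m.data[v] == pytest.approx(brute_force_w(block), abs=1e-12)

    def test_null_reho_is_small(self, rng):
        data = rng.normal(size=(6, 6, 6, 300))
        m = fmri.reho_map(BoldVolume(data, 2.0))
        inner = m.data[1:-1, 1:-1, 1:-1]
        assert 0 < inner.mean() < 0.2

    def test_bounded_and_kmin(self, rng):
        data = rng.normal(size=(5, 5, 5, 12))
        mask = np.zeros((5, 5, 5), bool)
        mask[2, 2, 2] = True  # K=1 < k_min
        m = fmri.reho_map(BoldVolume(data, 2.0, mask=mask), k_min=4)
        assert np.all(m.data == 0)
        full = fmri.reho_map(BoldVolume(data, 2.0))
        assert full.data.min() >= 0 and full.data.max() <= 1


class TestSmoothEqualize:
    def test_fwhm_zero_is_identity(self, rng):
        m = RegionalMap(rng.random((5, 5, 5)), "reho", np.ones((5, 5, 5), bool))
        out = fmri.smooth_gaussian(m, fwhm_mm=0)
        assert np.array_equal(out.data, m.data)

    def test_constant_map_unchanged(self):
        mask = np.zeros((7, 7, 7), bool)
        mask[2:5, 2:5, 2:5] = True
        m = RegionalMap(np.where(mask, 3.3, 0.0), "reho", mask)
        out = fmri.smooth_gaussian(m, fwhm_mm=6, voxel_size_mm=(3, 3, 3))
        assert np.allclose(out.data[mask], 3.3, atol=1e-10)

    def test_impulse_matches_gaussian_kernel(self):
        shape = (15, 15, 15)
        c = 7
        m = np.zeros(shape)
        m[c, c, c] = 1.0
        fwhm, vs = 6.0, (3.0, 3.0, 3.0)
        out = fmri.smooth_gaussian(
            RegionalMap(m, "reho", np.ones(shape, bool)), fwhm, vs
        )
        # kernel values relative to the impulse center follow the
        # closed-form Gaussian on the offset grid (interior voxels only,
        # away from the edge renormalisation)
        sigma = fwhm / (2 * np.sqrt(2 * np.log(2))) / vs[0]
        for d in (1, 2, 3):
            expected = np.exp(-(d**2) / (2 * sigma**2))
            assert out.data[c + d, c, c] / out.data[c, c, c] == pytest.approx(
                expected, rel=1e-4
            )
            assert out.data[c, c - d, c] / out.data[c, c, c] == pytest.approx(
                expected, rel=1e-4
            )

    def test_equalize_sets_mean_one(self, rng):
        mask = rng.random((6, 6, 6)) > 0.3
        m = RegionalMap(np.where(mask, rng.random((6, 6, 6)) + 0.5, 0), "reho", mask)
        out = fmri.equalize(m)
        assert out.data[mask].mean() == pytest.approx(1.0, abs=1e-12)

    def test_equalize_two_voxels(self):
        mask = np.array([[[True, True]]])
        m = RegionalMap(np.array([[[1.0, 3.0]]]), "reho", mask)
        out = fmri.equalize(m)
        assert np.allclose(out.data, [[[0.5, 1.5]]])


class TestFcPath:
    def test_single_voxel_roi_timecourse(self, small_parcellation, rng):
        from painfusion.synthetic import make_parcellation

        parc = make_parcellation((4, 4, 4), 3, seed=0)
        bold = make_bold(rng, shape=(4, 4, 4), t=25)
        tc = fmri.roi_timecourses(bold, parc)
        # brute-force oracle per ROI
        for r in range(1, 4):
            sel = parc.labels == r
            assert np.allclose(tc[r - 1], bold.data[sel].mean(axis=0))

    def test_empty_roi_errors(self, rng):
        from painfusion.containers import ParcellationMask

        labels = np.ones((3, 3, 3), int)
        parc = ParcellationMask(labels, n_rois=2)  # ROI 2 empty
        with pytest.raises(ValueError, match="ROI 2"):
            fmri.roi_timecourses(make_bold(rng, shape=(3, 3, 3), t=10), parc)

    def test_identical_rows_clip_to_finite_z(self, rng):
        row = rng.normal(size=50)
        fc = fmri.fc_matrix(np.stack([row, row, rng.normal(size=50)]))
        expected = np.arctanh(1 - 1e-7)
        assert fc.values[0, 1] == pytest.approx(expected)
        assert np.isfinite(fc.values).all()

    def test_orthogonal_rows_give_zero_z(self):
        t = np.linspace(0, 2 * np.pi, 100, endpoint=False)
        fc = fmri.fc_matrix(np.stack([np.sin(t), np.cos(t)]))
        assert abs(fc.values[0, 1]) < 1e-6

    def test_fisher_antisymmetry(self, rng):
        a, b = rng.normal(size=(2, 60))
        z1 = fmri.fc_matrix(np.stack([a, b])).values[0, 1]
        z2 = fmri.fc_matrix(np.stack([a, -b])).values[0, 1]
        assert z1 == pytest.approx(-z2, abs=1e-12)

    def test_constant_row_errors(self, rng):
        with pytest.raises(ValueError, match="ROI 1"):
            fmri.fc_matrix(np.stack([np.ones(20), rng.normal(size=20)]))

    def test_relabel_invariance(self, rng):
        tc = rng.normal(size=(5, 80))
        perm = np.array([3, 0, 4, 1, 2])
        z = fmri.fc_matrix(tc).values
        zp = fmri.fc_matrix(tc[perm]).values
        assert np.allclose(zp, z[np.ix_(perm, perm)], atol=1e-12)


class TestVectorize:
    def test_90_rois_give_4005_features(self):
        vec, meta = fmri.vectorize_lower(np.zeros((90, 90)))
        assert vec.size == 4005 and len(meta) == 4005

    def test_two_rois_give_one(self):
        vec, _ = fmri.vectorize_lower(np.arange(4).reshape(2, 2))
        assert np.array_equal(vec, [2])

    def test_round_trip(self, rng):
        m = rng.normal(size=(7, 7))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        vec, _ = fmri.vectorize_lower(m)
        assert np.allclose(fmri.devectorize_lower(vec, 7), m)


class TestPipelineOrder:
    def test_stage_order_is_fixed(self):
        assert fmri.FMRI_PIPELINE_STAGES == (
            "discard", "regress", "bandpass", "reho", "smooth", "equalize",
        )

    def test_planted_fc_pair_attains_largest_z(self):
        """A single strong off-diagonal in the latent ROI covariance must
        surface as the largest |z| among all pairs."""
        from painfusion import synthetic as syn

        hits = 0
        for seed in range(10):
            parc = syn.make_parcellation((6, 6, 6), 5, seed=seed)
            cov = np.eye(5)
            cov[1, 3] = cov[3, 1] = 0.8
            bold = syn.simulate_bold(
                parc, 300, 2.0, cov, local_coherence=0.9, noise_sd=1.0, seed=seed
            )
            z = fmri.fc_matrix(fmri.roi_timecourses(bold, parc)).values
            tri = np.abs(np.tril(z, k=-1))
            assert tri.max() > 0
            if np.unravel_index(tri.argmax(), tri.shape) == (3, 1):
                hits += 1
        assert hits >= 9
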