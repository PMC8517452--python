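import numpy as np
import pytest

from prostacad import (
    direction_offsets_3d,
    glcm_features,
    glcm_matrix,
    glrlm_features,
    glrlm_matrix,
    intensity_statistics,
    roi_volume,
)
from prostacad.preprocess import DiscretizedROI
from prostacad.texture import (
    GLCM_FEATURE_NAMES,
    GLRLM_FEATURE_NAMES,
    glcm_features_from_matrix,
    glrlm_features_from_matrix,
)
from conftest import make_mask, make_volume, random_discrete_roi
import oracles


def roi_from_levels(levels, n_bins):
    levels = np.asarray(levels, dtype=np.int32)
    mask = make_mask((levels > 0).astype(np.uint8))
    return DiscretizedROI(levels=levels, n_bins=n_bins, mask=mask)


class TestDirections:
    def test_thirteen_offsets(self):
        assert len(direction_offsets_3d()) == 13

    def test_no_two_offsets_parallel_or_antiparallel(self):
        offs = direction_offsets_3d()
        for i, a in enumerate(offs):
            for b in offs[i + 1 :]:
                assert a != b and tuple(-c for c in a) != b

    def test_union_with_negations_covers_26_neighbourhood(self):
        offs = direction_offsets_3d()
        full = set(offs) | {tuple(-c for c in o) for o in offs}
        expected = {
            (x, y, z)
            for x in (-1, 0, 1)
            for y in (-1, 0, 1)
            for z in (-1, 0, 1)
            if (x, y, z) != (0, 0, 0)
        }
        assert full == expected


class TestGLCMMatrix:
    def test_hand_enumerated_row(self):
        roi = roi_from_levels(np.array([1, 1, 2, 2]).reshape(1, 1, 4), 2)
        tm = glcm_matrix(roi, (0, 0, 1))
        # ordered pairs (1,1),(1,2),(2,2) counted in both orders -> 6 total
        expected = np.array([[2, 1], [1, 2]]) / 6.0
        assert np.allclose(tm.matrix, expected)
        assert tm.matrix.sum() == pytest.approx(1.0)

    def test_constant_roi_single_cell(self):
        roi = roi_from_levels(np.ones((3, 3, 3), dtype=int), 4)
        tm = glcm_matrix(roi, (1, 0, 0))
        assert tm.matrix[0, 0] == pytest.approx(1.0)
        assert tm.matrix.sum() == pytest.approx(1.0)

    def test_empty_direction_flagged(self):
        roi = roi_from_levels(np.array([[[1]]]), 2)
        tm = glcm_matrix(roi, (1, 0, 0))
        assert tm.empty

    def test_every_nonempty_direction_normalized_and_symmetric(self):
        rng = np.random.default_rng(7)
        roi = random_discrete_roi(rng)
        for off in direction_offsets_3d():
            tm = glcm_matrix(roi, off)
            if not tm.empty:
                assert tm.matrix.sum() == pytest.approx(1.0)
                assert np.allclose(tm.matrix, tm.matrix.T)


class TestGLCMFeatures:
    def test_feature_count_is_25(self):
        rng = np.random.default_rng(8)
        feats = glcm_features(random_discrete_roi(rng))
        assert len(feats) == 25
        assert tuple(feats) == GLCM_FEATURE_NAMES

    def test_constant_roi_degenerate_values(self):
        roi = roi_from_levels(np.ones((3, 3, 3), dtype=int), 4)
        feats = glcm_features(roi)
        assert feats["joint_maximum"] == pytest.approx(1.0)
        assert feats["joint_entropy"] == pytest.approx(0.0)
        assert feats["contrast"] == pytest.approx(0.0)

    def test_matches_bruteforce_on_random_roi(self):
        rng = np.random.default_rng(9)
        levels = rng.integers(0, 5, size=(5, 5, 5)).astype(np.int32)
        roi = roi_from_levels(levels, 4)
        ours = glcm_features(roi)
        brute = oracles.brute_glcm_averaged(levels, 4)
        for name in GLCM_FEATURE_NAMES:
            assert ours[name] == pytest.approx(brute[name], abs=1e-10), name


class TestGLRLM:
    def test_single_run_of_four(self):
        roi = roi_from_levels(np.ones((1, 1, 4), dtype=int), 2)
        tm = glrlm_matrix(roi, (0, 0, 1))
        assert tm.matrix[0, 3] == 1 and tm.matrix.sum() == 1
        feats = glrlm_features_from_matrix(tm.matrix, tm.n_observations)
        assert feats["run_percentage"] == pytest.approx(0.25)
        assert feats["long_run_emphasis"] == pytest.approx(16.0)

    def test_alternating_levels_all_runs_length_one(self):
        roi = roi_from_levels(np.array([1, 2, 1, 2]).reshape(1, 1, 4), 2)
        tm = glrlm_matrix(roi, (0, 0, 1))
        assert tm.matrix.shape[1] == 1 and tm.matrix.sum() == 4
        feats = glrlm_features_from_matrix(tm.matrix, tm.n_observations)
        assert feats["run_percentage"] == pytest.approx(1.0)

    def test_masked_voxel_terminates_run(self):
        roi = roi_from_levels(np.array([1, 1, 0, 1]).reshape(1, 1, 4), 2)
        tm = glrlm_matrix(roi, (0, 0, 1))
        # one run of 2 and one run of 1
        assert tm.matrix[0, 0] == 1 and tm.matrix[0, 1] == 1

    def test_run_counts_conserve_voxels_every_direction(self):
        rng = np.random.default_rng(10)
        roi = random_discrete_roi(rng)
        n_vox = int((roi.levels > 0).sum())
        for off in direction_offsets_3d():
            tm = glrlm_matrix(roi, off)
            lengths = np.arange(1, tm.matrix.shape[1] + 1)
            assert (tm.matrix * lengths).sum() == pytest.approx(n_vox)

    def test_feature_count_is_16(self):
        rng = np.random.default_rng(11)
        feats = glrlm_features(random_discrete_roi(rng))
        assert len(feats) == 16
        assert tuple(feats) == GLRLM_FEATURE_NAMES

    def test_matches_bruteforce_on_random_roi(self):
        rng = np.random.default_rng(12)
        levels = rng.integers(0, 4, size=(6, 5, 4)).astype(np.int32)
        levels[0, 0, 0] = 1
        roi = roi_from_levels(levels, 3)
        ours = glrlm_features(roi)
        brute = oracles.brute_glrlm_averaged(levels, 3)
        for name in GLRLM_FEATURE_NAMES:
            assert ours[name] == pytest.approx(brute[name], abs=1e-10), name


class TestIntensityStatistics:
    def test_small_sample_arithmetic(self):
        data = np.zeros((1, 1, 4))
        data[0, 0, :] = [1, 2, 3, 4]
        mask = make_mask(np.ones((1, 1, 4)))
        # 4 bins so the discretized levels coincide with the raw ranks
        stats = intensity_statistics(make_volume(data), mask, n_bins_intensity=4)
        assert stats["mean"] == pytest.approx(2.5)
        assert stats["p50"] == pytest.approx(2.5)
        assert stats["intensity_variance"] == pytest.approx(1.25)  # population
        assert stats["intensity_hist_mean"] == pytest.approx(2.5)

    def test_constant_roi_conventions(self):
        vol = make_volume(np.full((2, 2, 2), 7.0))
        stats = intensity_statistics(vol, make_mask(np.ones((2, 2, 2))), 64)
        assert stats["skewness"] == 0.0
        assert stats["kurtosis"] == 0.0
        assert stats["intensity_hist_mean"] == pytest.approx(1.0)

    def test_symmetric_distribution_zero_skewness(self):
        data = np.zeros((1, 1, 6))
        data[0, 0, :] = [-3, -1, -2, 2, 1, 3]
        stats = intensity_statistics(make_volume(data), make_mask(np.ones((1, 1, 6))), 64)
        assert abs(stats["skewness"]) < 1e-10


class TestRoiVolume:
    def test_hundred_voxels_half_mm(self):
        mask = np.zeros((10, 10, 2), dtype=np.uint8)
        mask[:, :, 0] = 1
        assert roi_volume(make_mask(mask, spacing=(0.5, 0.5, 0.5))) == pytest.approx(12.5)

    def test_single_anisotropic_voxel(self):
        mask = np.zeros((2, 2, 2), dtype=np.uint8)
        mask[0, 0, 0] = 1
        assert roi_volume(make_mask(mask, spacing=(0.5, 0.5, 3.0))) == pytest.approx(0.75)
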