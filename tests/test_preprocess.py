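import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from prostacad import (
    DegenerateDataError,
    Mask3D,
    denoise_gaussian,
    discretize_fbn,
    resample_isotropic,
    resegment_roi,
)
from prostacad.preprocess import PreprocessConfig
from conftest import make_mask, make_volume


class TestDenoise:
    def test_constant_volume_unchanged(self):
        vol = make_volume(np.full((6, 6, 6), 3.7), spacing=(0.5, 0.5, 2.0))
        out = denoise_gaussian(vol, 1.0)
        assert np.allclose(out.data, 3.7)

    def test_sigma_zero_is_identity(self):
        vol = make_volume(np.random.default_rng(0).normal(size=(5, 5, 5)))
        out = denoise_gaussian(vol, 0.0)
        assert np.array_equal(out.data, vol.data)

    def test_impulse_response_matches_sampled_kernel(self):
        """Unit impulse -> separable product of the sampled normalized
        1D Gaussian (sigma 0.5 voxels, truncation radius 2)."""
        data = np.zeros((9, 9, 9))
        data[4, 4, 4] = 1.0
        out = denoise_gaussian(make_volume(data, spacing=(1, 1, 1)), 0.5)
        i = np.arange(-2, 3, dtype=float)
        k = np.exp(-(i**2) / (2 * 0.25))
        k /= k.sum()
        expected = np.zeros((9, 9, 9))
        for a in range(5):
            for b in range(5):
                for c in range(5):
                    expected[2 + a, 2 + b, 2 + c] = k[a] * k[b] * k[c]
        assert np.allclose(out.data, expected, atol=1e-12)

    def test_physical_sigma_scales_with_spacing(self):
        # same physical sigma on a coarser axis smooths fewer voxels
        rng = np.random.default_rng(1)
        data = rng.normal(size=(16, 16, 16))
        fine = denoise_gaussian(make_volume(data, (0.5, 0.5, 0.5)), 1.0)
        coarse = denoise_gaussian(make_volume(data, (2.0, 2.0, 2.0)), 1.0)
        assert fine.data.std() < coarse.data.std()


class TestResample:
    def test_identity_when_already_isotropic(self):
        vol = make_volume(np.random.default_rng(2).normal(size=(6, 6, 6)), (0.5, 0.5, 0.5))
        out = resample_isotropic(vol, 0.5, "trilinear")
        assert np.array_equal(out.data, vol.data)

    def test_trilinear_reproduces_linear_ramp(self):
        nx = 9
        data = np.broadcast_to(np.arange(nx, dtype=float)[:, None, None], (nx, 4, 4)).copy()
        vol = make_volume(data, spacing=(1.0, 1.0, 1.0))
        out = resample_isotropic(vol, 0.5, "trilinear")
        expected = np.arange(out.shape[0]) * 0.5
        assert np.allclose(out.data[:, 0, 0], expected, atol=1e-12)
        assert out.spacing == (0.5, 0.5, 0.5)

    def test_mask_resampling_binary_and_volume_preserved(self):
        rng = np.random.default_rng(3)
        blob = np.zeros((24, 24, 10))
        x, y, z = np.meshgrid(*[np.arange(n) for n in blob.shape], indexing="ij")
        blob[((x - 12) ** 2 / 81 + (y - 12) ** 2 / 81 + (z - 5) ** 2 / 9) <= 1] = 1
        mask = make_mask(blob, spacing=(0.8, 0.8, 2.4))
        out = resample_isotropic(mask, 0.5)
        assert isinstance(out, Mask3D)
        assert set(np.unique(out.data)) <= {0, 1}
        vol_in = mask.n_voxels * 0.8 * 0.8 * 2.4
        vol_out = out.n_voxels * 0.125
        assert abs(vol_out - vol_in) / vol_in < 0.15

    def test_single_voxel_axis_handled(self):
        vol = make_volume(np.ones((5, 5, 1)), spacing=(1.0, 1.0, 3.0))
        out = resample_isotropic(vol, 0.5, "trilinear")
        assert out.shape[2] == 1
        assert np.allclose(out.data, 1.0)


class TestResegment:
    def test_percentile_window_removes_extremes(self):
        vals = np.arange(1, 101, dtype=float)
        data = np.zeros((10, 10, 2))
        data[:, :, 0] = vals.reshape(10, 10)
        mask = np.zeros((10, 10, 2), dtype=np.uint8)
        mask[:, :, 0] = 1
        out = resegment_roi(make_volume(data), make_mask(mask), 1, 99)
        kept_vals = data[out.as_bool()]
        # linear-interpolation convention: P1 = 1.99, P99 = 99.01
        assert out.n_voxels == 98
        assert 1 not in kept_vals and 100 not in kept_vals

    def test_constant_roi_unchanged(self):
        vol = make_volume(np.full((4, 4, 4), 2.0))
        mask = make_mask(np.ones((4, 4, 4)))
        out = resegment_roi(vol, mask, 1, 99)
        assert np.array_equal(out.data, mask.data)

    def test_full_range_unchanged(self):
        rng = np.random.default_rng(4)
        vol = make_volume(rng.normal(size=(4, 4, 4)))
        mask = make_mask(np.ones((4, 4, 4)))
        out = resegment_roi(vol, mask, 0, 100)
        assert np.array_equal(out.data, mask.data)

    def test_second_pass_is_bounded_and_nested(self):
        """Re-applying the window trims only within the first result (the
        interpolated-percentile convention recomputes bounds on the trimmed
        distribution, so exact idempotence cannot hold in general)."""
        rng = np.random.default_rng(5)
        vol = make_volume(rng.normal(size=(6, 6, 6)))
        mask = make_mask(np.ones((6, 6, 6)))
        once = resegment_roi(vol, mask, 5, 95)
        twice = resegment_roi(vol, once, 5, 95)
        assert np.all(twice.data <= once.data)  # nested
        assert twice.n_voxels >= int(0.9 * once.n_voxels)
        # idempotent for the full-range window
        full = resegment_roi(vol, mask, 0, 100)
        assert np.array_equal(resegment_roi(vol, full, 0, 100).data, full.data)

    def test_empty_mask_is_error(self):
        vol = make_volume(np.zeros((3, 3, 3)))
        with pytest.raises(DegenerateDataError):
            resegment_roi(vol, make_mask(np.zeros((3, 3, 3))), 1, 99)


class TestDiscretize:
    def test_four_values_four_bins(self):
        data = np.zeros((1, 1, 4))
        data[0, 0, :] = [0, 1, 2, 3]
        mask = make_mask(np.ones((1, 1, 4)))
        roi = discretize_fbn(make_volume(data), mask, 4)
        assert roi.levels[0, 0, :].tolist() == [1, 2, 3, 4]

    def test_constant_roi_maps_to_level_one(self):
        roi = discretize_fbn(make_volume(np.full((3, 3, 3), 9.0)), make_mask(np.ones((3, 3, 3))), 32)
        assert set(roi.levels[roi.mask.as_bool()]) == {1}

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(2, 64), st.integers(0, 2**31 - 1))
    def test_extremes_map_to_boundary_levels(self, n_bins, seed):
        rng = np.random.default_rng(seed)
        data = rng.normal(size=(4, 4, 4))
        mask = make_mask((rng.random((4, 4, 4)) > 0.3).astype(np.uint8))
        if mask.n_voxels == 0:
            return
        roi = discretize_fbn(make_volume(data), mask, n_bins)
        inside = roi.levels[mask.as_bool()]
        vals = data[mask.as_bool()]
        assert roi.levels[mask.as_bool()][np.argmin(vals)] == 1
        if vals.max() > vals.min():
            assert inside[np.argmax(vals)] == n_bins
        assert inside.min() >= 1 and inside.max() <= n_bins

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        st.floats(0.1, 100.0), st.floats(-50.0, 50.0), st.integers(0, 2**31 - 1)
    )
    def test_fbn_invariant_to_positive_affine_rescaling(self, a, b, seed):
        rng = np.random.default_rng(seed)
        data = rng.normal(size=(5, 5, 5))
        mask = make_mask(np.ones((5, 5, 5)))
        base = discretize_fbn(make_volume(data), mask, 16)
        scaled = discretize_fbn(make_volume(a * data + b), mask, 16)
        assert np.array_equal(base.levels, scaled.levels)


def test_config_validation():
    with pytest.raises(ValueError):
        PreprocessConfig(reseg_lo_pct=99, reseg_hi_pct=1)
    with pytest.raises(ValueError):
        PreprocessConfig(n_bins_texture=1)
    with pytest.raises(ValueError):
        PreprocessConfig(iso_spacing_mm=0)
    cfg = PreprocessConfig()
    assert PreprocessConfig.from_dict(cfg.to_dict()) == cfg
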