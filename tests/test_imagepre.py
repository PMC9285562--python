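"""Image IO, cropping, resampling, thresholding and contrast metrics."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from poroseg.imagepre import (CoarseRange, RoiBox, VolumetricImage,
                              coarse_threshold, contrast_metrics, crop,
                              read_volume, resample_isotropic, write_volume)


class TestIO:
    @pytest.mark.parametrize("ext", ["nii.gz", "mha", "npy", "npz"])
    def test_write_read_round_trip(self, ramp_image, tmp_path, ext):
        path = tmp_path / f"vol.{ext}"
        write_volume(ramp_image, path)
        back = read_volume(path)
        np.testing.assert_allclose(back.data, ramp_image.data)
        np.testing.assert_allclose(back.spacing, ramp_image.spacing)
        np.testing.assert_allclose(back.origin, ramp_image.origin, atol=1e-6)

    def test_raw_spacing_preserved(self, tmp_path):
        """CA-1-like geometry: 0.5 x 0.5 x 0.4 mm voxels."""
        img = VolumetricImage(np.zeros((4, 4, 4)), (0.5, 0.5, 0.4))
        path = write_volume(img, tmp_path / "v.npy")
        np.testing.assert_array_equal(read_volume(path).spacing, [0.5, 0.5, 0.4])

    def test_missing_file(self):
        with pytest.raises(FileNotFoundError):
            read_volume("/nonexistent/image.nii")

    def test_raw_without_sidecar_rejected(self, tmp_path):
        np.save(tmp_path / "v.npy", np.zeros((3, 3, 3)))
        with pytest.raises(FileNotFoundError, match="sidecar"):
            read_volume(tmp_path / "v.npy")

    def test_dicom_series_round_trip(self, dicom_series_factory):
        d, vol = dicom_series_factory(n_slices=6, dz=0.4)
        img = read_volume(d)
        np.testing.assert_array_equal(img.data, vol)
        np.testing.assert_allclose(img.spacing, [0.5, 0.5, 0.4])

    def test_dicom_missing_slice_rejected(self, dicom_series_factory):
        d, _ = dicom_series_factory(n_slices=6, drop_slice=3)
        with pytest.raises(ValueError, match="slice spacing"):
            read_volume(d)


class TestCrop:
    def test_full_extent_identity(self, ramp_image):
        out = crop(ramp_image, RoiBox((0, 0, 0), ramp_image.shape))
        np.testing.assert_array_equal(out.data, ramp_image.data)
        np.testing.assert_array_equal(out.origin, ramp_image.origin)

    def test_values_match_source(self, ramp_image):
        out = crop(ramp_image, RoiBox((2, 3, 4), (4, 5, 6)))
        np.testing.assert_array_equal(out.data, ramp_image.data[2:4, 3:5, 4:6])

    def test_world_coordinates_preserved(self, ramp_image):
        """Voxel (0,0,0) of the crop sits at origin + spacing*(2,3,4)."""
        def world(img, idx):  # independent bookkeeping
            return np.asarray(img.origin) + np.asarray(img.spacing) * idx

        out = crop(ramp_image, RoiBox((2, 3, 4), (6, 6, 6)))
        np.testing.assert_allclose(world(out, np.zeros(3)),
                                   world(ramp_image, np.array([2, 3, 4])))

    def test_roi_outside_image(self, ramp_image):
        with pytest.raises(ValueError):
            crop(ramp_image, RoiBox((0, 0, 0), (9, 8, 8)))

    @given(st.integers(0, 5), st.integers(0, 5))
    def test_crop_composition(self, a, b):
        """crop(crop(img, A), B') equals crop(img, A intersect B)."""
        img = VolumetricImage(np.arange(512.0).reshape(8, 8, 8), (1, 1, 1))
        box1 = RoiBox((a, 0, 0), (a + 3, 8, 8))
        box2 = RoiBox((b, 0, 0), (b + 3, 8, 8))
        try:
            both = box1.intersect(box2)
        except ValueError:
            return
        inner = RoiBox((max(b - a, 0), 0, 0),
                       (max(b - a, 0) + (both.upper[0] - both.lower[0]), 8, 8))
        once = crop(img, both)
        twice = crop(crop(img, box1), inner)
        np.testing.assert_array_equal(once.data, twice.data)
        np.testing.assert_array_equal(once.origin, twice.origin)


class TestResample:
    def test_constant_preserved(self):
        img = VolumetricImage(np.full((6, 6, 6), 42.0), (0.5, 0.5, 0.4))
        out = resample_isotropic(img, 0.3)
        np.testing.assert_allclose(out.data, 42.0)
        assert out.is_isotropic

    def test_affine_field_exact(self):
        """Trilinear interpolation reproduces affine intensity exactly."""
        sp = np.array([0.5, 0.5, 0.4])
        idx = np.indices((8, 8, 8)).astype(float)
        world = idx * sp.reshape(3, 1, 1, 1)
        a = np.array([2.0, -1.0, 0.5])
        data = (a.reshape(3, 1, 1, 1) * world).sum(axis=0) + 7.0
        out = resample_isotropic(VolumetricImage(data, sp), 0.25)
        idx2 = np.indices(out.shape).astype(float)
        expected = (a.reshape(3, 1, 1, 1) * idx2 * 0.25).sum(axis=0) + 7.0
        np.testing.assert_allclose(out.data, expected, atol=1e-10)

    def test_extent_preserved_paper_target(self):
        """0.5 mm grid resampled to 0.1 mm keeps the extent within a voxel."""
        img = VolumetricImage(np.random.default_rng(0).normal(size=(9, 9, 9)),
                              (0.5, 0.5, 0.5))
        out = resample_isotropic(img, 0.1)
        extent_in = (np.array(img.shape) - 1) * 0.5
        extent_out = (np.array(out.shape) - 1) * 0.1
        assert np.all(np.abs(extent_in - extent_out) <= 0.1 + 1e-12)

    def test_values_stay_within_input_range(self):
        rng = np.random.default_rng(1)
        img = VolumetricImage(rng.normal(size=(7, 7, 7)), (0.4, 0.5, 0.6))
        out = resample_isotropic(img, 0.22)
        assert out.data.min() >= img.data.min() - 1e-12
        assert out.data.max() <= img.data.max() + 1e-12

    def test_target_too_large(self):
        img = VolumetricImage(np.zeros((4, 4, 4)), (0.5, 0.5, 0.5))
        with pytest.raises(ValueError):
            resample_isotropic(img, 10.0)


class TestCoarseThreshold:
    def test_all_inside(self):
        img = VolumetricImage(np.full((3, 3, 3), 10.0), (1, 1, 1))
        assert coarse_threshold(img, CoarseRange(0, 20)).all()

    def test_toy_grid_enumeration(self):
        data = np.array([[40.0, 100.0, 250.0], [50.0, 200.0, 201.0],
                         [49.0, 151.0, 0.0]]).reshape(3, 3, 1)
        img = VolumetricImage(data, (1, 1, 1))
        mask = coarse_threshold(img, CoarseRange(50, 200))
        expected = np.array([[False, True, False], [True, True, False],
                             [False, True, False]]).reshape(3, 3, 1)
        np.testing.assert_array_equal(mask, expected)

    def test_boundaries_closed(self):
        img = VolumetricImage(np.array([50.0, 200.0, 49.999, 200.001]
                                       ).reshape(4, 1, 1), (1, 1, 1))
        mask = coarse_threshold(img, CoarseRange(50, 200))
        np.testing.assert_array_equal(mask.ravel(), [True, True, False, False])

    @given(st.floats(1, 40), st.floats(1, 40))
    def test_monotone_in_range_width(self, lo_shrink, hi_shrink):
        rng = np.random.default_rng(3)
        img = VolumetricImage(rng.uniform(0, 100, (5, 5, 5)), (1, 1, 1))
        wide = coarse_threshold(img, CoarseRange(0.0, 100.0))
        narrow = coarse_threshold(img, CoarseRange(lo_shrink, 100.0 - hi_shrink))
        assert narrow.sum() <= wide.sum()
        assert not np.any(narrow & ~wide)


class TestContrastMetrics:
    def _img(self, values):
        return VolumetricImage(np.asarray(values, float).reshape(-1, 1, 1),
                               (1, 1, 1))

    def test_identical_distributions_zero_cnr(self):
        img = self._img([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        ob = np.zeros((6, 1, 1), bool)
        ob[:3] = True
        rep = contrast_metrics(img, ob, ~ob)
        assert rep.cnr == pytest.approx(0.0)

    def test_hand_computed_moments(self):
        """Object const 100 vs background {0, 2}: CNR = 99."""
        img = self._img([100.0, 100.0, 0.0, 2.0])
        ob = np.array([True, True, False, False]).reshape(-1, 1, 1)
        rep = contrast_metrics(img, ob, ~ob)
        assert rep.mean_object == 100.0
        assert rep.mean_background == 1.0
        assert rep.sd_background == 1.0
        assert rep.cnr == pytest.approx(99.0)

    def test_scale_invariance(self):
        rng = np.random.default_rng(5)
        vals = rng.normal(10, 2, 20)
        ob = np.zeros((20, 1, 1), bool)
        ob[:10] = True
        r1 = contrast_metrics(self._img(vals), ob, ~ob)
        r2 = contrast_metrics(self._img(vals * 3.5), ob, ~ob)
        assert r2.cnr == pytest.approx(r1.cnr)
        assert r2.snr == pytest.approx(r1.snr)
        assert r2.mean_object == pytest.approx(3.5 * r1.mean_object)

    def test_zero_variance_background_flagged(self):
        img = self._img([5.0, 5.0, 1.0, 1.0])
        ob = np.array([True, True, False, False]).reshape(-1, 1, 1)
        rep = contrast_metrics(img, ob, ~ob)
        assert not rep.cnr_defined
        assert np.isnan(rep.cnr)

    def test_overlapping_masks_rejected(self):
        img = self._img([1.0, 2.0, 3.0])
        m = np.ones((3, 1, 1), bool)
        with pytest.raises(ValueError):
            contrast_metrics(img, m, m)
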