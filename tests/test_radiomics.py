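import numpy as np
import pytest

import segqc
from segqc.radiomics import (
    CLASS_FEATURE_NAMES,
    FEATURE_NAMES,
    ExtractionSettings,
    discretize,
    extract_case,
    first_order_features,
    shape_features,
)
from segqc.phantom import PerturbationSpec, PhantomSpec, generate_phantom, perturb_mask

from _oracles import brute_surface
from conftest import block_mask


def volume_from(arr, spacing=(1.0, 1.0, 1.0)):
    return segqc.ImageVolume(np.asarray(arr, dtype=float), spacing)


def roi(values, spacing=(1.0, 1.0, 1.0)):
    """Volume + all-ones mask from a small array."""
    arr = np.asarray(values, dtype=float)
    vol = volume_from(arr, spacing)
    mask = segqc.SegMask(np.ones(arr.shape), spacing)
    return vol, mask


class TestDiscretize:
    def test_constant_roi_single_bin(self):
        vol, mask = roi(np.full((3, 3, 1), 7.0))
        d = discretize(vol, mask, 64)
        assert d.n_bins == 1
        assert set(d.labels[d.mask]) == {1}

    def test_floor_rule_on_exact_multiples(self):
        vol, mask = roi(np.array([0.0, 64.0, 128.0]).reshape(3, 1, 1))
        d = discretize(vol, mask, 64)
        assert d.labels[:, 0, 0].tolist() == [1, 2, 3]

    def test_values_within_one_width_share_bin(self):
        vol, mask = roi(np.array([0.0, 63.9]).reshape(2, 1, 1))
        d = discretize(vol, mask, 64)
        assert d.labels[:, 0, 0].tolist() == [1, 1]

    def test_anchored_at_in_mask_minimum(self):
        vol, mask = roi(np.array([1000.0, 1063.0]).reshape(2, 1, 1))
        d = discretize(vol, mask, 64)
        assert d.labels[:, 0, 0].tolist() == [1, 1]

    def test_empty_mask_rejected(self):
        vol = volume_from(np.zeros((3, 3, 3)))
        empty = segqc.SegMask(np.zeros((3, 3, 3)), (1, 1, 1))
        with pytest.raises(ValueError, match="empty"):
            discretize(vol, empty, 64)


class TestFirstOrder:
    def test_constant_roi_conventions(self):
        vol, mask = roi(np.full((3, 3, 2), 5.0))
        f = first_order_features(vol, mask)
        assert f["Mean"] == 5.0
        assert f["Variance"] == 0.0
        assert f["Skewness"] == 0.0  # zero-variance convention
        assert f["Kurtosis"] == 0.0
        assert f["Entropy"] == 0.0  # single bin
        assert f["Uniformity"] == 1.0

    def test_hand_computed_statistics(self):
        vol, mask = roi(np.array([1.0, 2.0, 3.0, 4.0]).reshape(4, 1, 1))
        f = first_order_features(vol, mask)
        assert f["Mean"] == pytest.approx(2.5)
        assert f["Variance"] == pytest.approx(1.25)  # population variance
        assert f["Energy"] == pytest.approx(1 + 4 + 9 + 16)
        assert f["RootMeanSquared"] == pytest.approx(np.sqrt(30 / 4))
        assert f["Range"] == 3.0
        assert f["MeanAbsoluteDeviation"] == pytest.approx(1.0)

    def test_total_energy_scales_with_voxel_volume(self):
        vol, mask = roi(np.full((2, 2, 2), 3.0), spacing=(1.0, 1.0, 2.0))
        f = first_order_features(vol, mask)
        assert f["TotalEnergy"] == pytest.approx(2.0 * f["Energy"])

    def test_feature_count_is_18(self):
        vol, mask = roi(np.arange(8.0).reshape(2, 2, 2))
        assert len(first_order_features(vol, mask)) == 18


class TestShape:
    def test_cube_voxel_volume(self):
        m = block_mask((14, 14, 14), (slice(2, 12), slice(2, 12), slice(2, 12)))
        f = shape_features(m)
        assert f["VoxelVolume"] == pytest.approx(1000.0)
        assert f["MeshVolume"] == pytest.approx(1000.0, rel=0.05)

    def test_max_3d_diameter_against_surface_oracle(self):
        m = block_mask((14, 14, 14), (slice(2, 12), slice(2, 12), slice(2, 12)))
        f = shape_features(m)
        surf = brute_surface(m.voxels.astype(bool))
        from scipy.spatial.distance import pdist

        centre_diam = pdist(surf).max()  # sqrt(3) * 9 for the 10-voxel cube
        # the isosurface lies outside the voxel centres but marching cubes
        # chamfers the corners, so the mesh diameter sits between the
        # centre-to-centre diagonal and the padded bounding-box diagonal
        assert centre_diam <= f["Maximum3DDiameter"] <= np.sqrt(3 * 10**2)

    def test_sphere_more_spherical_than_elongated_ellipsoid(self):
        _, round_mask = generate_phantom(
            PhantomSpec(ellipsoid_radii=(18.0, 18.0, 18.0))
        )
        _, long_mask = generate_phantom(
            PhantomSpec(ellipsoid_radii=(9.0, 9.0, 30.0))
        )
        assert (
            shape_features(round_mask)["Sphericity"]
            > shape_features(long_mask)["Sphericity"]
        )

    def test_anisotropic_spacing_enters_physical_units(self):
        m1 = block_mask((10, 10, 10), (slice(2, 6), slice(2, 6), slice(2, 6)))
        vox = np.zeros((10, 10, 10))
        vox[2:6, 2:6, 2:6] = 1
        m2 = segqc.SegMask(vox, (1.0, 1.0, 2.0))
        assert shape_features(m2)["VoxelVolume"] == pytest.approx(
            2.0 * shape_features(m1)["VoxelVolume"]
        )

    def test_two_voxel_mask_degenerate_axes(self):
        vox = np.zeros((5, 5, 5))
        vox[2, 2, 2] = vox[2, 2, 3] = 1
        f = shape_features(segqc.SegMask(vox, (1, 1, 1)))
        assert f["MinorAxisLength"] == 0.0
        assert f["LeastAxisLength"] == 0.0
        assert f["Elongation"] == 0.0

    def test_feature_count_is_14(self):
        m = block_mask((8, 8, 8), (slice(2, 6), slice(2, 6), slice(2, 6)))
        assert len(shape_features(m)) == 14


class TestExtractCase:
    def test_cardinalities(self, small_phantom_case):
        img, gold = small_phantom_case
        fv = extract_case(img, gold)
        assert len(fv.values) == 321
        for region in ("whole", "apex", "base"):
            per_region = [n for n in fv.values if n.startswith(region + "_")]
            assert len(per_region) == 107
        expected = {
            "firstorder": 18,
            "shape": 14,
            "glcm": 24,
            "glrlm": 16,
            "glszm": 16,
            "gldm": 14,
            "ngtdm": 5,
        }
        for cls, n in expected.items():
            assert len(CLASS_FEATURE_NAMES[cls]) == n

    def test_all_values_finite(self, small_phantom_case):
        img, gold = small_phantom_case
        assert np.all(np.isfinite(extract_case(img, gold).as_array()))

    def test_whole_mean_equals_direct_mean(self, small_phantom_case):
        img, gold = small_phantom_case
        fv = extract_case(img, gold)
        direct = img.intensities[gold.voxels > 0].mean()
        assert fv.values["whole_firstorder_Mean"] == pytest.approx(direct)

    def test_deterministic(self, small_phantom_case):
        img, gold = small_phantom_case
        a = extract_case(img, gold).as_array()
        b = extract_case(img, gold).as_array()
        assert np.array_equal(a, b)

    def test_intensity_shift_invariance_of_texture(self, small_phantom_case):
        """Fixed-bin-width bins re-anchor at the in-mask minimum, so adding
        a constant leaves texture features unchanged and shifts the mean."""
        img, gold = small_phantom_case
        shifted = segqc.ImageVolume(img.intensities + 500.0, img.spacing)
        a = extract_case(img, gold)
        b = extract_case(shifted, gold)
        for name in FEATURE_NAMES:
            cls = name.split("_")[1]
            if cls in ("glcm", "glrlm", "glszm", "gldm", "ngtdm"):
                assert a.values[name] == pytest.approx(b.values[name]), name
        assert b.values["whole_firstorder_Mean"] == pytest.approx(
            a.values["whole_firstorder_Mean"] + 500.0
        )

    def test_leak_blob_increases_surface_area(self, small_phantom_case):
        img, gold = small_phantom_case
        leaked = perturb_mask(gold, PerturbationSpec("leak_blob", 3, seed=2))
        a = extract_case(img, gold)
        b = extract_case(img, leaked)
        assert b.values["whole_shape_SurfaceArea"] > a.values["whole_shape_SurfaceArea"]

    def test_thin_mask_degenerate_regions_still_321(self):
        """A 2-slice mask has empty apex/base thirds; extraction must not
        crash and still emits the full vector."""
        vox = np.zeros((12, 12, 12))
        vox[4:8, 4:8, 5:7] = 1
        mask = segqc.SegMask(vox, (1, 1, 1))
        rng = np.random.default_rng(0)
        vol = volume_from(rng.normal(100, 20, (12, 12, 12)))
        fv = extract_case(vol, mask)
        assert len(fv.values) == 321
        assert "apex" in fv.degenerate_regions and "base" in fv.degenerate_regions
        assert np.all(np.isfinite(fv.as_array()))

    def test_empty_mask_rejected(self):
        vol = volume_from(np.zeros((6, 6, 6)))
        empty = segqc.SegMask(np.zeros((6, 6, 6)), (1, 1, 1))
        with pytest.raises(ValueError, match="empty"):
            extract_case(vol, empty)

    def test_settings_fingerprint_recorded(self, small_phantom_case):
        img, gold = small_phantom_case
        fv = extract_case(img, gold, ExtractionSettings(bin_width=32))
        assert "binwidth=32" in fv.fingerprint
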