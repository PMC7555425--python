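import numpy as np
import pytest

import segqc
from segqc.metrics import arvd, asd, dice, hd95, metric_panel, surface_voxels
from segqc.phantom import PerturbationSpec, perturb_mask

from _oracles import brute_asd, brute_hd95, brute_surface, random_mask
from conftest import block_mask


def mask_from(vox, spacing=(1.0, 1.0, 1.0)):
    return segqc.SegMask(np.asarray(vox), spacing)


class TestDice:
    def test_identical_masks(self):
        m = block_mask((6, 6, 6), (slice(1, 4), slice(1, 4), slice(1, 4)))
        assert dice(m, m) == 1.0

    def test_shifted_block_half_overlap(self):
        a = block_mask((6, 6, 3), (slice(1, 3), slice(1, 3), slice(1, 2)))
        b = block_mask((6, 6, 3), (slice(2, 4), slice(1, 3), slice(1, 2)))
        assert dice(a, b) == 0.5

    def test_disjoint_masks(self):
        a = block_mask((8, 8, 3), (slice(0, 2), slice(0, 2), slice(0, 1)))
        b = block_mask((8, 8, 3), (slice(5, 7), slice(5, 7), slice(0, 1)))
        assert dice(a, b) == 0.0

    def test_both_empty_defined_as_one(self):
        e = block_mask((4, 4, 4), (slice(0, 0), slice(0, 0), slice(0, 0)))
        assert dice(e, e) == 1.0

    def test_grid_mismatch_raises(self):
        a = block_mask((6, 6, 6), (slice(1, 3), slice(1, 3), slice(1, 3)))
        b = block_mask((5, 5, 5), (slice(1, 3), slice(1, 3), slice(1, 3)))
        with pytest.raises(ValueError, match="grid mismatch"):
            dice(a, b)


class TestArvd:
    def test_exact_arithmetic(self):
        ref = np.zeros((10, 10, 2))
        ref[:10, :10, 0] = 1  # 100 voxels
        auto = np.zeros((10, 10, 2))
        auto[:10, :10, 0] = 1
        auto[:2, :10, 1] = 1  # 120 voxels
        assert arvd(mask_from(auto), mask_from(ref)) == pytest.approx(20.0)

    def test_identical_masks_zero(self):
        m = block_mask((6, 6, 6), (slice(1, 4), slice(1, 4), slice(1, 4)))
        assert arvd(m, m) == 0.0

    def test_empty_automated_is_hundred(self):
        ref = block_mask((6, 6, 6), (slice(1, 4), slice(1, 4), slice(1, 4)))
        empty = block_mask((6, 6, 6), (slice(0, 0), slice(0, 0), slice(0, 0)))
        assert arvd(empty, ref) == 100.0

    def test_empty_reference_rejected(self):
        ref = block_mask((6, 6, 6), (slice(0, 0), slice(0, 0), slice(0, 0)))
        m = block_mask((6, 6, 6), (slice(1, 4), slice(1, 4), slice(1, 4)))
        with pytest.raises(ValueError, match="empty reference"):
            arvd(m, ref)

    def test_asymmetric_in_reference(self):
        big = block_mask((8, 8, 8), (slice(0, 4), slice(0, 4), slice(0, 4)))
        small = block_mask((8, 8, 8), (slice(0, 4), slice(0, 4), slice(0, 2)))
        assert arvd(big, small) != arvd(small, big)


class TestSurface:
    def test_single_voxel(self):
        vox = np.zeros((5, 5, 5))
        vox[2, 2, 2] = 1
        assert surface_voxels(mask_from(vox)).tolist() == [[2, 2, 2]]

    @pytest.mark.parametrize("side,expected", [(3, 26), (5, 98)])
    def test_solid_cube_surface_counts(self, side, expected):
        vox = np.zeros((side + 4,) * 3)
        vox[2 : 2 + side, 2 : 2 + side, 2 : 2 + side] = 1
        assert len(surface_voxels(mask_from(vox))) == expected

    def test_grid_boundary_counts_as_outside(self):
        vox = np.ones((3, 3, 3))
        assert len(surface_voxels(mask_from(vox))) == 26  # only centre interior


class TestDistances:
    def _single_voxel_pair(self, gap, spacing):
        a = np.zeros((10, 5, 5))
        b = np.zeros((10, 5, 5))
        a[2, 2, 2] = 1
        b[2 + gap, 2, 2] = 1
        return mask_from(a, spacing), mask_from(b, spacing)

    def test_identical_masks_zero(self):
        m = block_mask((6, 6, 6), (slice(1, 4), slice(1, 4), slice(1, 4)))
        assert hd95(m, m) == 0.0
        assert asd(m, m) == 0.0

    def test_single_voxels_three_apart(self):
        a, b = self._single_voxel_pair(3, (1.0, 1.0, 1.0))
        assert hd95(a, b) == pytest.approx(3.0)
        assert asd(a, b) == pytest.approx(3.0)

    def test_spacing_scales_distances(self):
        a, b = self._single_voxel_pair(3, (0.5, 1.0, 1.0))
        assert hd95(a, b) == pytest.approx(1.5)
        assert asd(a, b) == pytest.approx(1.5)

    def test_empty_mask_rejected(self):
        m = block_mask((6, 6, 6), (slice(1, 4), slice(1, 4), slice(1, 4)))
        e = block_mask((6, 6, 6), (slice(0, 0), slice(0, 0), slice(0, 0)))
        with pytest.raises(ValueError):
            hd95(m, e)

    def test_cube_vs_dilated_matches_oracle(self):
        from scipy import ndimage

        vox = np.zeros((9, 9, 9))
        vox[3:6, 3:6, 3:6] = 1
        dil = ndimage.binary_dilation(vox.astype(bool))
        a, b = mask_from(vox), mask_from(dil)
        assert asd(a, b) == pytest.approx(brute_asd(vox > 0, dil, (1, 1, 1)), abs=1e-9)
        assert hd95(a, b) == pytest.approx(brute_hd95(vox > 0, dil, (1, 1, 1)), abs=1e-9)

    def test_symmetry(self):
        rng = np.random.default_rng(5)
        a = mask_from(random_mask(rng, (8, 8, 8), 0.4))
        b = mask_from(random_mask(rng, (8, 8, 8), 0.4))
        assert hd95(a, b) == hd95(b, a)
        assert asd(a, b) == asd(b, a)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(6)
        va = random_mask(rng, (8, 8, 8), 0.4)
        vb = random_mask(rng, (8, 8, 8), 0.4)
        a1, b1 = mask_from(va), mask_from(vb)
        c = 2.5
        a2, b2 = mask_from(va, (c, c, c)), mask_from(vb, (c, c, c))
        assert hd95(a2, b2) == pytest.approx(c * hd95(a1, b1))
        assert asd(a2, b2) == pytest.approx(c * asd(a1, b1))
        assert dice(a2, b2) == dice(a1, b1)


class TestSurfaceOracle:
    def test_surface_matches_enumeration_on_random_masks(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            vox = random_mask(rng, (7, 7, 7), 0.35)
            got = {tuple(p) for p in surface_voxels(mask_from(vox))}
            want = {tuple(p) for p in brute_surface(vox)}
            assert got == want


class TestMetricPanel:
    def test_perfect_segmentation(self, phantom_case):
        _, gold = phantom_case
        panel = metric_panel(gold, gold)
        for r in ("whole", "apex", "base"):
            assert panel.values[(r, "DSC")] == 1.0
            assert panel.values[(r, "aRVD")] == 0.0
            assert panel.values[(r, "HD95")] == 0.0
            assert panel.values[(r, "ASD")] == 0.0

    def test_panel_has_exactly_twelve_cells(self, phantom_case):
        _, gold = phantom_case
        panel = metric_panel(gold, gold)
        assert len(panel.values) == 12 and len(panel.valid) == 12

    def test_heavy_erosion_degrades_every_region(self, phantom_case):
        _, gold = phantom_case
        eroded = perturb_mask(gold, PerturbationSpec("erode", 3))
        panel = metric_panel(eroded, gold)
        for r in ("whole", "apex", "base"):
            assert panel.values[(r, "DSC")] < 1.0
            assert panel.values[(r, "aRVD")] > 0.0

    def test_empty_region_flagged_not_fatal(self, phantom_case):
        _, gold = phantom_case
        # drop enough apex slices to empty the reference-frame apex
        hollow = perturb_mask(gold, PerturbationSpec("drop_apex_slices", 20))
        panel = metric_panel(hollow, gold)
        assert not panel.valid[("apex", "HD95")]
        assert panel.values[("apex", "DSC")] == 0.0
        assert panel.values[("apex", "aRVD")] == 100.0
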