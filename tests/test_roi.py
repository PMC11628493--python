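"""Patch masks against a brute-force enumeration oracle, and patch statistics."""

import math

import numpy as np
import pytest

from ctcontrast import (
    GrayVolume,
    PatchAnnotation,
    PatchSample,
    ScanMeta,
    background_mean,
    bilateral_mean,
    circular_patch_mask,
    fallback_region_sample,
    sample_patch,
)
from ctcontrast.roi import patch_radius_voxels

META = ScanMeta("X", "FORMALIN_BLUGOL", 0.0)


def enumerate_disc(cy, cx, r, shape):
    """Independent oracle: per-pixel loop over the slice."""
    mask = np.zeros(shape, dtype=bool)
    for y in range(shape[0]):
        for x in range(shape[1]):
            if (y - cy) ** 2 + (x - cx) ** 2 <= r * r:
                mask[y, x] = True
    return mask


class TestCircularPatchMask:
    def test_paper_scale_patch_matches_enumeration(self):
        # 0.20 mm circumference at 2.1 um pixels -> r = 200/(2*pi)/2.1 voxels
        ann = PatchAnnotation("lamina", "left", 0, (40.0, 40.0), 0.20)
        r = patch_radius_voxels(0.20, 2.1)
        assert r == pytest.approx(200.0 / (2 * math.pi) / 2.1)
        mask = circular_patch_mask(ann, 2.1, (80, 80))
        oracle = enumerate_disc(40.0, 40.0, r, (80, 80))
        assert np.array_equal(mask, oracle)
        assert abs(int(mask.sum()) - 722) <= 3  # digital-circle count near pi*r^2

    def test_radius_one_gives_five_voxel_plus(self):
        # circumference worth exactly 2*pi voxels -> r = 1 voxel
        voxel_um = 10.0
        circ_mm = 2 * math.pi * voxel_um / 1000.0
        ann = PatchAnnotation("x", "midline", 0, (5.0, 5.0), circ_mm)
        mask = circular_patch_mask(ann, voxel_um, (11, 11))
        assert int(mask.sum()) == 5
        ys, xs = np.nonzero(mask)
        assert sorted(zip(ys.tolist(), xs.tolist())) == [
            (4, 5), (5, 4), (5, 5), (5, 6), (6, 5)
        ]

    def test_translation_equivariance_for_integer_offsets(self):
        a = PatchAnnotation("x", "left", 0, (20.0, 20.0), 0.20)
        b = PatchAnnotation("x", "left", 0, (23.0, 25.0), 0.20)
        ma = circular_patch_mask(a, 5.0, (60, 60))
        mb = circular_patch_mask(b, 5.0, (60, 60))
        assert np.array_equal(np.roll(np.roll(ma, 3, axis=0), 5, axis=1), mb)

    def test_subvoxel_radius_is_an_error(self):
        ann = PatchAnnotation("x", "left", 0, (5.0, 5.0), 0.20)
        with pytest.raises(ValueError, match="diameter"):
            circular_patch_mask(ann, 50.0, (11, 11))  # r = 0.64 voxels

    @pytest.mark.parametrize("r", [15.0, 25.0, 40.0])
    def test_mask_area_approaches_pi_r_squared(self, r):
        circ_mm = 2 * math.pi * r * 10.0 / 1000.0  # radius r voxels at 10 um
        ann = PatchAnnotation("x", "left", 0, (60.0, 60.0), circ_mm)
        mask = circular_patch_mask(ann, 10.0, (121, 121))
        assert int(mask.sum()) == pytest.approx(math.pi * r * r, rel=0.02)


class TestSamplePatch:
    def test_uniform_patch_mean_and_zero_sd(self, make_uniform_volume):
        vol = make_uniform_volume(30000)
        ann = PatchAnnotation("x", "left", 1, (15.0, 15.0), 0.20)
        s = sample_patch(vol, ann)
        assert s.mean_gray == 30000 and s.sd_gray == 0.0
        oracle = enumerate_disc(15.0, 15.0, patch_radius_voxels(0.20, 10.0), (32, 32))
        assert s.n_voxels == int(oracle.sum())

    def test_half_and_half_patch_averages_symmetrically(self):
        voxels = np.full((1, 40, 40), 10000, dtype=np.uint16)
        voxels[:, :, 20:] = 20000  # split along the patch's vertical diameter
        vol = GrayVolume(voxels, 10.0, META)
        ann = PatchAnnotation("x", "left", 0, (19.5, 19.5), 0.20)
        s = sample_patch(vol, ann)
        assert s.mean_gray == pytest.approx(15000.0)

    def test_population_sd_convention(self):
        voxels = np.full((1, 20, 20), 1000, dtype=np.uint16)
        voxels[0, 10, 10] = 2000
        vol = GrayVolume(voxels, 10.0, META)
        circ_mm = 2 * math.pi * 1.0 * 10.0 / 1000.0  # r = 1 voxel, 5-voxel plus
        s = sample_patch(vol, PatchAnnotation("x", "left", 0, (10.0, 10.0), circ_mm))
        vals = np.array([2000, 1000, 1000, 1000, 1000], dtype=float)
        assert s.sd_gray == pytest.approx(vals.std(ddof=0))
        assert s.sd_gray != pytest.approx(vals.std(ddof=1))

    def test_boundary_clipped_patch_rejected(self, make_uniform_volume):
        vol = make_uniform_volume(1000)
        ann = PatchAnnotation("x", "left", 0, (1.0, 15.0), 0.20)
        with pytest.raises(ValueError, match="clipped"):
            sample_patch(vol, ann)

    def test_slice_outside_volume_rejected(self, make_uniform_volume):
        vol = make_uniform_volume(1000)
        ann = PatchAnnotation("x", "left", 99, (15.0, 15.0), 0.20)
        with pytest.raises(ValueError, match="slice_index"):
            sample_patch(vol, ann)


class TestAveraging:
    def sample(self, organ, side, mean):
        return PatchSample(organ, side, mean, 0.0, 10, 0)

    def test_bilateral_mean_of_pair(self):
        assert bilateral_mean(
            self.sample("lamina", "left", 10000.0), self.sample("lamina", "right", 20000.0)
        ) == 15000.0

    def test_bilateral_idempotent_and_midline_passthrough(self):
        s = self.sample("lamina", "left", 12345.0)
        assert bilateral_mean(s, s) == s.mean_gray
        assert bilateral_mean(self.sample("ampn", "midline", 12345.0)) == 12345.0

    def test_bilateral_organ_mismatch_rejected(self):
        with pytest.raises(ValueError, match="different organs"):
            bilateral_mean(
                self.sample("lamina", "left", 1.0), self.sample("lobula", "right", 2.0)
            )

    def test_background_mean_is_symmetric_pair_average(self):
        a = self.sample("background", "background", 800.0)
        b = self.sample("background", "background", 1000.0)
        assert background_mean([a, b]) == 900.0
        assert background_mean([b, a]) == 900.0
        assert background_mean([a, a]) == 800.0

    def test_background_count_enforced(self):
        a = self.sample("background", "background", 800.0)
        with pytest.raises(ValueError, match="exactly 2"):
            background_mean([a])
        with pytest.raises(ValueError, match="exactly 2"):
            background_mean([a, a, a])


class TestFallbackRegion:
    def test_six_mm_circumference_radius(self):
        assert patch_radius_voxels(6.00, 10.0) == pytest.approx(6000.0 / (2 * math.pi) / 10.0)

    def test_uniform_fallback_region_mean_and_flag(self):
        voxels = np.full((1, 220, 220), 5000, dtype=np.uint16)
        vol = GrayVolume(voxels, 10.0, META)
        ann = PatchAnnotation("brain_area", "midline", 0, (109.5, 109.5), 6.00)
        s = fallback_region_sample(vol, ann)
        assert s.fallback is True
        assert s.mean_gray == 5000.0
        # ordinary samples are not flagged
        assert sample_patch(vol, ann).fallback is False
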