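"""VOI construction: labelling, bottom-up selection, cortical erosion."""

import numpy as np
import pytest

from vnca_marrow.phantom import build_phantom
from vnca_marrow.segmentation import (
    VOIMask,
    ball_structuring_element,
    erode_cortex,
    extract_voxels,
    label_vertebrae,
    labeled_spine_from_map,
    select_bottom_k,
)
from vnca_marrow.spectral import VNCaVolume


def brute_force_erosion(mask: np.ndarray, radius_mm: float, spacing) -> np.ndarray:
    """Keep a voxel iff every lattice point of the physical ball fits inside."""
    offsets = np.argwhere(ball_structuring_element(radius_mm, spacing))
    offsets -= np.array(ball_structuring_element(radius_mm, spacing).shape) // 2
    out = np.zeros_like(mask)
    for idx in np.argwhere(mask):
        pts = idx + offsets
        if np.any((pts < 0) | (pts >= mask.shape)):
            continue
        if mask[tuple(pts.T)].all():
            out[tuple(idx)] = True
    return out


class TestErosion:
    def test_cube_oracle_isotropic(self):
        """3 mm ball erosion of an 11^3 cube at 1 mm spacing leaves 5^3 voxels."""
        mask = np.zeros((15, 15, 15), dtype=bool)
        mask[2:13, 2:13, 2:13] = True
        out = erode_cortex(VOIMask(mask, (1.0, 1.0, 1.0)), 3.0)
        assert out.mask.sum() == 125
        assert out.mask[5:10, 5:10, 5:10].all()

    def test_radius_zero_is_identity(self):
        mask = np.random.default_rng(0).random((8, 8, 8)) > 0.5
        out = erode_cortex(VOIMask(mask, (1.0, 1.0, 2.0)), 0.0)
        np.testing.assert_array_equal(out.mask, mask)

    def test_anisotropic_matches_brute_force_ball_fit(self, rng):
        spacing = (1.0, 1.0, 2.0)
        mask = np.zeros((14, 12, 10), dtype=bool)
        mask[1:12, 2:11, 1:9] = True
        mask[3:7, 3:7, 0:10] = True  # protrusion
        mask &= rng.random(mask.shape) > 0.05  # pocked surface
        out = erode_cortex(VOIMask(mask, spacing), 3.0)
        np.testing.assert_array_equal(out.mask, brute_force_erosion(mask, 3.0, spacing))

    def test_anisotropic_depths(self):
        # semi-axes (3, 3, 1.5) mm -> 3 voxels in-plane, 1 through-plane
        selem = ball_structuring_element(3.0, (1.0, 1.0, 2.0))
        assert selem.shape == (7, 7, 3)

    def test_result_subset_and_composition_bound(self, rng):
        mask = rng.random((12, 12, 12)) > 0.3
        m = VOIMask(mask, (1.0, 1.0, 1.0))
        once = erode_cortex(m, 2.0)
        assert not (once.mask & ~mask).any()
        twice = erode_cortex(once, 2.0)
        combined = erode_cortex(m, 4.0)
        # erosion by r then r' contains erosion by the (r + r') ball
        assert not (combined.mask & ~twice.mask).any()

    def test_vanishing_mask_warns(self):
        mask = np.zeros((6, 6, 6), dtype=bool)
        mask[2:4, 2:4, 2:4] = True
        with pytest.warns(UserWarning, match="removed the entire VOI"):
            out = erode_cortex(VOIMask(mask, (1.0, 1.0, 1.0)), 5.0)
        assert not out.mask.any()


class TestLabelling:
    def test_phantom_recovers_truth_ordering(self, small_spec):
        spec = small_spec(seed=21, infiltration=0.3)
        vol, truth = build_phantom(spec)
        ls = label_vertebrae(vol.conventional, spec.spacing_mm)
        assert ls.n_vertebrae == spec.n_vertebrae
        # caudal->cranial ordering matches construction order exactly
        for lab in ls.ordering:
            ours = ls.label_map == lab
            theirs = truth.label_map == lab
            dice = 2 * (ours & theirs).sum() / (ours.sum() + theirs.sum())
            assert dice == 1.0

    def test_empty_volume_is_an_error(self):
        with pytest.raises(ValueError, match="no spine"):
            label_vertebrae(np.full((10, 10, 10), -1000.0), (1.0, 1.0, 1.0))

    def test_fused_bodies_split_at_profile_minimum(self):
        conv = np.full((12, 12, 30), -1000.0)
        conv[2:11, 2:11, 2:11] = 300.0
        conv[2:11, 2:11, 14:23] = 300.0
        conv[6, 6, 11:14] = 300.0  # one-voxel bridge
        ls = label_vertebrae(conv, (1.0, 1.0, 1.0), min_body_volume_cm3=0.1)
        assert ls.n_vertebrae == 2

    def test_truth_map_import_drops_lesions(self, small_spec):
        spec = small_spec(seed=3, lesions=(((24.0, 24.0, 16.0), 6.0),))
        _, truth = build_phantom(spec)
        ls = labeled_spine_from_map(truth.label_map, spec.spacing_mm)
        voi = select_bottom_k(ls, spec.n_vertebrae)
        assert not (voi.mask & (truth.label_map == -1)).any()


class TestSelection:
    def make_spine(self, n):
        labels = np.zeros((4, 4, 6 * n), dtype=np.int32)
        for v in range(1, n + 1):
            labels[1:3, 1:3, 6 * (v - 1) : 6 * v - 2] = v
        return labeled_spine_from_map(labels, (1.0, 1.0, 1.0))

    def test_most_cranial_excluded(self):
        ls = self.make_spine(20)
        voi = select_bottom_k(ls, 17)
        kept = set(np.unique(ls.label_map[voi.mask]))
        assert kept == set(range(1, 18))

    def test_exact_count_is_identity(self):
        ls = self.make_spine(17)
        voi = select_bottom_k(ls, 17)
        np.testing.assert_array_equal(voi.mask, ls.label_map > 0)

    def test_too_few_vertebrae_reported(self):
        ls = self.make_spine(16)
        with pytest.raises(ValueError, match="found 16 < 17"):
            select_bottom_k(ls, 17)


class TestExtraction:
    def test_empty_mask(self):
        v = VNCaVolume(np.zeros((4, 4, 4)), (1.0, 1.0, 1.0), 25.0)
        sample, vol = extract_voxels(v, VOIMask(np.zeros((4, 4, 4), bool), (1.0, 1.0, 1.0)))
        assert sample.size == 0 and vol == 0.0

    def test_constant_grid_and_volume(self):
        v = VNCaVolume(np.full((10, 10, 10), -80.0), (2.0, 2.0, 2.0), 25.0)
        mask = np.ones((10, 10, 10), bool)
        sample, vol = extract_voxels(v, VOIMask(mask, (2.0, 2.0, 2.0)))
        assert np.all(sample == -80.0)
        assert vol == pytest.approx(1000 * 8 / 1000.0)  # count x voxel volume

    def test_shape_mismatch(self):
        v = VNCaVolume(np.zeros((4, 4, 4)), (1.0, 1.0, 1.0), 25.0)
        with pytest.raises(ValueError, match="shape mismatch"):
            extract_voxels(v, VOIMask(np.zeros((5, 4, 4), bool), (1.0, 1.0, 1.0)))
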