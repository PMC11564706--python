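import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from breastmorph.labelmap import PhysicalPoint, side_subvolume
from breastmorph.landmarks import build_breast_box
from breastmorph.metrics import (
    EmptyMaskError,
    axis_extents,
    breast_volume,
    connected_components,
    dominant_mass,
    tumor_metrics_report,
    tumor_to_landmark_distance,
    tumor_volume,
)
from oracles import brute_min_corner_distance


class TestConnectedComponents:
    def test_corner_touching_voxels(self):
        m = np.zeros((3, 3, 3), bool)
        m[0, 0, 0] = m[1, 1, 1] = True
        assert connected_components(m, "face")[1] == 2
        assert connected_components(m, "corner")[1] == 1

    def test_empty_mask(self):
        assert connected_components(np.zeros((2, 2, 2), bool))[1] == 0

    def test_ids_in_raster_order(self):
        m = np.zeros((5, 3, 3), bool)
        m[4, 0, 0] = True  # later in raster order
        m[0, 2, 2] = True
        labels, n = connected_components(m)
        assert n == 2
        assert labels[0, 2, 2] == 1 and labels[4, 0, 0] == 2


class TestDominantMass:
    def test_largest_wins(self):
        m = np.zeros((8, 3, 3), bool)
        m[0:5, 0, 0] = True
        m[0:3, 2, 2] = True
        dom = dominant_mass(m)
        assert dom.sum() == 5 and dom[0, 0, 0]

    def test_unifocal_identity(self):
        m = np.zeros((4, 4, 4), bool)
        m[1:3, 1:3, 1:3] = True
        np.testing.assert_array_equal(dominant_mass(m), m)

    def test_tie_goes_to_raster_first(self):
        m = np.zeros((8, 3, 3), bool)
        m[0:4, 0, 0] = True
        m[0:4, 2, 2] = True  # same size, later first voxel in raster order
        dom = dominant_mass(m)
        assert dom[0, 0, 0] and not dom[0, 2, 2]

    def test_empty_raises(self):
        with pytest.raises(EmptyMaskError):
            dominant_mass(np.zeros((2, 2, 2), bool))


class TestExtentsAndVolumes:
    @pytest.mark.parametrize(
        "spacing,expected",
        [((1, 1, 1), (1.0, 1.0, 10.0)), ((0.5, 0.5, 2.0), (0.5, 0.5, 20.0))],
    )
    def test_rod_extents(self, spacing, expected):
        m = np.zeros((3, 3, 12), bool)
        m[1, 1, 1:11] = True
        assert axis_extents(m, spacing) == pytest.approx(expected)

    def test_single_voxel(self):
        m = np.zeros((2, 2, 2), bool)
        m[0, 0, 0] = True
        assert axis_extents(m, (1, 1, 1)) == (1.0, 1.0, 1.0)

    def test_volume_counts_voxels(self):
        m = np.zeros((4, 4, 4), bool)
        m[:2, :2, :2] = True
        assert tumor_volume(m, (0.5, 0.5, 2.0)) == pytest.approx(4.0)
        assert tumor_volume(np.zeros((2, 2, 2), bool), (1, 1, 1)) == 0.0

    def test_bounding_box_at_least_tumor_volume(self, rng):
        m = rng.random((6, 6, 6)) < 0.3
        if not m.any():
            m[0, 0, 0] = True
        ext = axis_extents(m, (1, 1, 1))
        assert np.prod(ext) >= tumor_volume(m, (1, 1, 1))


class TestVertexDistances:
    def test_hand_computed_examples(self):
        a = np.zeros((7, 3, 3), bool)
        b = np.zeros((7, 3, 3), bool)
        a[0, 1, 1] = True
        b[5, 1, 1] = True
        # corners at i=1.0 and i=5.0 -> 4 mm
        assert tumor_to_landmark_distance(a, b, (1, 1, 1)) == pytest.approx(4.0)

    def test_adjacent_voxels_share_corners(self):
        a = np.zeros((3, 3, 3), bool)
        b = np.zeros((3, 3, 3), bool)
        a[0, 0, 0] = True
        b[1, 0, 0] = True
        assert tumor_to_landmark_distance(a, b, (1, 1, 1)) == 0.0

    def test_point_target_uses_nearest_corner(self):
        m = np.zeros((2, 2, 2), bool)
        m[0, 0, 0] = True
        # unit voxel [0,1]^3; nearest corner to (3, .5, .5) is (1, 0 or 1, ...)
        d = tumor_to_landmark_distance(m, PhysicalPoint(3.0, 0.5, 0.5), (1, 1, 1))
        assert d == pytest.approx(np.sqrt(4.0 + 0.25 + 0.25))

    def test_matches_brute_force_exactly(self, rng):
        for _ in range(25):
            a = rng.random((6, 6, 6)) < 0.15
            b = rng.random((6, 6, 6)) < 0.15
            if not a.any() or not b.any():
                continue
            spacing = tuple(rng.choice([0.5, 1.0, 2.0], size=3))
            fast = tumor_to_landmark_distance(a, b, spacing)
            brute = brute_min_corner_distance(a, b, spacing)
            assert fast == pytest.approx(brute, abs=1e-12)

    def test_translation_invariance(self, rng):
        a = rng.random((5, 5, 5)) < 0.3
        b = rng.random((5, 5, 5)) < 0.3
        a[0, 0, 0] = b[4, 4, 4] = True
        big_a = np.zeros((9, 9, 9), bool)
        big_b = np.zeros((9, 9, 9), bool)
        big_a[1:6, 2:7, 3:8] = a
        big_b[1:6, 2:7, 3:8] = b
        shifted_a = np.roll(big_a, (2, 1, 1), axis=(0, 1, 2))
        shifted_b = np.roll(big_b, (2, 1, 1), axis=(0, 1, 2))
        d0 = tumor_to_landmark_distance(big_a, big_b, (1, 1, 1))
        d1 = tumor_to_landmark_distance(shifted_a, shifted_b, (1, 1, 1))
        assert d0 == pytest.approx(d1, abs=1e-12)

    def test_empty_inputs_raise(self):
        m = np.zeros((2, 2, 2), bool)
        with pytest.raises(EmptyMaskError):
            tumor_to_landmark_distance(m, m, (1, 1, 1))


class TestReport:
    def test_unifocal_scopes_identical(self, preset_case):
        lm, gt = preset_case("unifocal_small")
        box = build_breast_box(lm, "left")
        nip = PhysicalPoint(*gt.sides["left"].nipple_ref_mm)
        rep = tumor_metrics_report(lm, "left", nip, box)
        assert rep.n_components == 1
        assert rep.whole_tumor == rep.dominant_mass

    def test_multifocal_dominant_smaller(self, preset_case):
        lm, gt = preset_case("multifocal_far")
        box = build_breast_box(lm, "left")
        nip = PhysicalPoint(*gt.sides["left"].nipple_ref_mm)
        rep = tumor_metrics_report(lm, "left", nip, box)
        assert rep.n_components == 2
        assert (
            rep.dominant_mass.longest_dimension_mm < rep.whole_tumor.longest_dimension_mm
        )
        assert (
            rep.dominant_mass.bounding_box_volume_mm3
            <= rep.whole_tumor.bounding_box_volume_mm3
        )

    def test_ratio_and_breast_volume(self, preset_case):
        lm, gt = preset_case("unifocal_small")
        box = build_breast_box(lm, "left")
        nip = PhysicalPoint(*gt.sides["left"].nipple_ref_mm)
        rep = tumor_metrics_report(lm, "left", nip, box)
        assert 0 < rep.tumor_to_breast_ratio < 1
        # brute-force recount of breast tissue inside the box
        sub = side_subvolume(lm, "left")
        sel = box.contains_centers(sub)
        count = int((sub.breast_tissue_mask() & sel).sum())
        assert rep.breast_volume_mm3 == pytest.approx(count * sub.voxel_volume_mm3)
        assert breast_volume(lm, box) == pytest.approx(rep.breast_volume_mm3)

    def test_distances_within_voxel_diagonal_of_truth(self, preset_case):
        lm, gt = preset_case("unifocal_large")
        diag = float(np.linalg.norm(lm.spacing_mm))
        box = build_breast_box(lm, "left")
        nip = PhysicalPoint(*gt.sides["left"].nipple_ref_mm)
        rep = tumor_metrics_report(lm, "left", nip, box)
        t = gt.tumors[0]
        assert rep.to_skin_mm == pytest.approx(t.to_skin_mm, abs=diag)
        assert rep.to_chest_mm == pytest.approx(t.to_chest_mm, abs=diag)
        assert rep.to_nipple_mm == pytest.approx(t.to_nipple_mm, abs=diag)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(0, 2**24 - 1), st.integers(0, 2**24 - 1))
def test_volume_additive_over_components(bits_a, bits_b):
    """Splitting a mask into components conserves total volume."""
    m = np.zeros((48,), bool)
    m[:24] = [(bits_a >> i) & 1 for i in range(24)]
    m[24:] = [(bits_b >> i) & 1 for i in range(24)]
    m = m.reshape(4, 4, 3)
    labels, n = connected_components(m)
    total = sum(tumor_volume(labels == i, (1, 1, 1)) for i in range(1, n + 1))
    assert total == tumor_volume(m, (1, 1, 1))
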