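import numpy as np
import pytest

from breastmorph._voxels import corner_points_mm
from breastmorph.hulls import (
    MAX_MARGIN_MM,
    build_hull,
    corner_shifted_mask,
    extract_surface,
    multicentric_hulls,
    unicentric_hull,
    voxelize_hull,
)
from breastmorph.labelmap import LabelMap, side_subvolume
from breastmorph.metrics import EmptyMaskError
from breastmorph.evaluation import dice

SPHERE = {}


def sphere_mask(r=10, n=31):
    if (r, n) not in SPHERE:
        c = (np.arange(n) + 0.5) - n / 2
        X, Y, Z = np.meshgrid(c, c, c, indexing="ij")
        SPHERE[(r, n)] = X**2 + Y**2 + Z**2 <= r**2
    return SPHERE[(r, n)]


class TestCornerShift:
    def test_single_voxel_becomes_2x2x2(self):
        m = np.zeros((3, 3, 3), bool)
        m[1, 1, 1] = True
        shifted, dorigin = corner_shifted_mask(m, (1, 1, 1))
        assert shifted.shape == (4, 4, 4)
        assert shifted.sum() == 8
        assert dorigin == (-0.5, -0.5, -0.5)

    def test_rod_becomes_2x2x3(self):
        m = np.zeros((3, 3, 4), bool)
        m[1, 1, 1:3] = True
        shifted, _ = corner_shifted_mask(m, (1, 1, 1))
        assert shifted.sum() == 12  # 2 x 2 x 3 block

    def test_corner_touching_voxels_share_one_corner(self):
        a = np.zeros((3, 3, 3), bool)
        b = np.zeros((3, 3, 3), bool)
        a[0, 0, 0] = True
        b[1, 1, 1] = True
        sa, _ = corner_shifted_mask(a, (1, 1, 1))
        sb, _ = corner_shifted_mask(b, (1, 1, 1))
        assert int((sa & sb).sum()) == 1

    def test_empty_raises(self):
        with pytest.raises(EmptyMaskError):
            corner_shifted_mask(np.zeros((2, 2, 2), bool), (1, 1, 1))


class TestExtractSurface:
    def test_mesh_is_watertight(self):
        mesh = extract_surface(sphere_mask(6, 21), (1, 1, 1))
        assert mesh.is_watertight
        norms = np.linalg.norm(mesh.vertex_normals, axis=1)
        np.testing.assert_allclose(norms, 1.0, atol=1e-6)

    def test_sphere_mesh_volume_within_5pct(self):
        mesh = extract_surface(sphere_mask(10, 31), (1, 1, 1))
        assert mesh.volume_mm3 == pytest.approx(4 / 3 * np.pi * 1000, rel=0.05)

    def test_normals_point_outward(self):
        mesh = extract_surface(sphere_mask(6, 21), (1, 1, 1))
        centroid = mesh.vertices.mean(axis=0)
        outward = ((mesh.vertices - centroid) * mesh.vertex_normals).sum(axis=1)
        assert (outward > 0).mean() > 0.99

    def test_border_touching_mask_stays_watertight(self):
        m = np.ones((4, 4, 4), bool)
        mesh = extract_surface(m, (1, 1, 1))
        assert mesh.is_watertight


class TestBuildHull:
    def test_single_voxel_margin0_volume(self):
        m = np.zeros((3, 3, 3), bool)
        m[1, 1, 1] = True
        h = build_hull(m, (1, 1, 1), 0.0)
        assert h.volume_mm3 == pytest.approx(1.0, rel=0.1)

    def test_cuboid_margin0_contains_all_corners(self):
        m = np.zeros((10, 10, 10), bool)
        m[2:7, 3:8, 1:9] = True
        h = build_hull(m, (1, 1, 1), 0.0)
        pts = corner_points_mm(m, (1, 1, 1))
        assert h.contains(pts).all()

    def test_offset_sphere_volume(self):
        h = build_hull(sphere_mask(10, 31), (1, 1, 1), 10.0)
        assert h.volume_mm3 == pytest.approx(4 / 3 * np.pi * 20**3, rel=0.1)

    def test_margin_out_of_range(self):
        m = np.zeros((3, 3, 3), bool)
        m[1, 1, 1] = True
        with pytest.raises(ValueError):
            build_hull(m, (1, 1, 1), MAX_MARGIN_MM + 1)
        with pytest.raises(ValueError):
            build_hull(m, (1, 1, 1), -1)

    @pytest.mark.parametrize("margin", [0.0, 5.0, 10.0, 20.0])
    def test_containment_and_near_margin_guarantee(self, margin):
        # on spheres and cuboids: corners inside, boundary at least
        # margin minus one voxel diagonal away
        diag = np.sqrt(3.0)
        for mask in (sphere_mask(8, 27), _cuboid()):
            h = build_hull(mask, (1, 1, 1), margin)
            pts = corner_points_mm(mask, (1, 1, 1))
            assert h.contains(pts).all()
            assert h.boundary_distance(pts).min() >= margin - diag


def _cuboid():
    m = np.zeros((14, 14, 14), bool)
    m[3:11, 4:10, 2:12] = True
    return m


class TestUnicentricMulticentric:
    def test_margin_monotonicity(self):
        vols = [
            unicentric_hull(sphere_mask(6, 21), (1, 1, 1), m).volume_mm3
            for m in (0, 2, 5, 10, 20)
        ]
        assert all(a < b for a, b in zip(vols, vols[1:]))

    def test_unifocal_multicentric_equals_unicentric(self):
        m = sphere_mask(5, 17)
        multi = multicentric_hulls(m, (1, 1, 1), 4.0)
        uni = unicentric_hull(m, (1, 1, 1), 4.0)
        assert len(multi) == 1
        assert multi[0].volume_mm3 == pytest.approx(uni.volume_mm3, rel=1e-9)

    def test_far_foci_stay_separate(self, preset_case):
        lm, _ = preset_case("multifocal_far")
        sub = side_subvolume(lm, "left")
        hulls = multicentric_hulls(
            sub.tissue_mask("tumor"), sub.spacing_mm, 1.0, origin_mm=sub.origin_mm
        )
        assert len(hulls) == 2
        assert set(hulls[0].component_ids).isdisjoint(hulls[1].component_ids)

    def test_near_foci_merge_at_5mm(self, preset_case):
        lm, _ = preset_case("multifocal_near")
        sub = side_subvolume(lm, "left")
        hulls = multicentric_hulls(
            sub.tissue_mask("tumor"), sub.spacing_mm, 5.0, origin_mm=sub.origin_mm
        )
        assert len(hulls) == 1
        assert hulls[0].component_ids == (1, 2)

    def test_unicentric_bridges_gap(self, preset_case):
        lm, _ = preset_case("multifocal_far")
        sub = side_subvolume(lm, "left")
        tumor = sub.tissue_mask("tumor")
        uni = unicentric_hull(tumor, sub.spacing_mm, 1.0, sub.origin_mm)
        parts = multicentric_hulls(tumor, sub.spacing_mm, 1.0, origin_mm=sub.origin_mm)
        assert uni.volume_mm3 > sum(h.volume_mm3 for h in parts)

    def test_merge_order_independence(self):
        # three collinear foci where adjacent pairs overlap at the margin
        m = np.zeros((40, 9, 9), bool)
        for c in (6, 18, 30):
            m[c - 3 : c + 3, 2:8, 2:8] = True
        hulls = multicentric_hulls(m, (1, 1, 1), 5.0)
        assert len(hulls) == 1
        assert hulls[0].component_ids == (1, 2, 3)
        # permuting the volume (reversed axis) gives the same merged volume
        hulls_r = multicentric_hulls(m[::-1].copy(), (1, 1, 1), 5.0)
        assert hulls_r[0].volume_mm3 == pytest.approx(hulls[0].volume_mm3, rel=1e-6)


class TestVoxelize:
    def test_round_trip_dice(self, schema):
        # compact fixtures: the convex cover of a blocky lattice adds a
        # sub-voxel shell, so small spheres (r <~ 8) fall below 0.9 by
        # surface-to-volume ratio alone
        for mask in (sphere_mask(10, 31), _cuboid()):
            h = build_hull(mask, (1, 1, 1), 0.0)
            lm = LabelMap(np.zeros(mask.shape, np.int16), (1, 1, 1), schema)
            vox = voxelize_hull(h, lm)
            assert dice(vox, mask) >= 0.9

    def test_hull_covers_mask_voxels(self, schema):
        mask = _cuboid()
        h = build_hull(mask, (1, 1, 1), 0.0)
        lm = LabelMap(np.zeros(mask.shape, np.int16), (1, 1, 1), schema)
        vox = voxelize_hull(h, lm)
        covered = (vox & mask).sum() / mask.sum()
        assert covered >= 0.99
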