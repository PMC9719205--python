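"""Thresholding, mask algebra, apical window, isosurface extraction."""

import numpy as np
import pytest

from molardrift import (
    GroundTruthMotion,
    PhantomSpec,
    VoxelVolume,
    extract_mesh,
    open_apical_window,
    threshold_mask,
    union_masks,
)
from molardrift.phantom import CUSP_PROTRUSION_MM, ArchPhantom, generate_phantom
from molardrift.segmentation import default_thresholds


def make_volume(shape=(20, 20, 20), value=100.0, spacing=0.5, origin=(0, 0, 0)):
    return VoxelVolume(
        np.full(shape, value, dtype=np.float32), (spacing,) * 3, origin
    )


class TestThresholdMask:
    def test_constant_volume_inside_range_is_all_true(self):
        vol = make_volume(value=100.0)
        assert threshold_mask(vol, (99.0, 101.0)).all()

    def test_range_excluding_all_values_warns_and_is_empty(self):
        vol = make_volume(value=100.0)
        with pytest.warns(UserWarning, match="no voxels"):
            mask = threshold_mask(vol, (500.0, 600.0))
        assert not mask.any()

    def test_half_open_interval_partitions_exactly(self):
        vol = make_volume(value=100.0)
        below = threshold_mask(vol, (0.0, 100.0))  # 100 excluded at hi
        above = threshold_mask(vol, (100.0, 200.0))  # included at lo
        assert not below.any() and above.all()

    def test_invalid_range_rejected(self):
        with pytest.raises(ValueError):
            threshold_mask(make_volume(), (5.0, 5.0))

    def test_phantom_class_counts_match_analytic_voxelization(self):
        """Noise-free masks count exactly the voxel centers inside each
        analytic solid (independent re-implementation of the geometry)."""
        spec = PhantomSpec(
            voxel_spacing_mm=(0.5, 0.5, 0.5), noise_sd=0.0, partial_volume=False
        )
        base, _, _ = generate_phantom(spec, GroundTruthMotion.zero(), build_meshes=False)
        vol = base.volume
        cfg = default_thresholds(spec)
        pts = vol.voxel_centers().reshape(-1, 3)

        h = spec.crown_height_mm
        a, b = spec.crown_halfwidth_md_mm, spec.crown_halfwidth_bl_mm

        def superellipsoid(p, cx):
            return (
                np.abs((p[:, 0] - cx) / a) ** 4
                + np.abs(p[:, 1] / b) ** 4
                + np.abs((p[:, 2] - h / 2) / (h / 2)) ** 4
            ) <= 1

        def cusp_spheres(p, cx, layout):
            r = spec.cusp_radius_mm
            cz = h + CUSP_PROTRUSION_MM - r
            hit = np.zeros(len(p), dtype=bool)
            for dx, dy in layout:
                hit |= np.sum((p - [cx + dx, dy, cz]) ** 2, axis=1) <= r**2
            return hit

        four = [(2.4, -2.6), (-2.4, -2.6), (2.4, 2.6), (-2.4, 2.6)]
        crown_oracle = np.zeros(len(pts), dtype=bool)
        for cx in (0.0, spec.tooth_pitch_mm, -spec.tooth_pitch_mm):
            crown_oracle |= superellipsoid(pts, cx) | cusp_spheres(pts, cx, four)

        L = spec.root_length_mm
        root_oracle = np.zeros(len(pts), dtype=bool)
        for cx, r0 in (((2.0, 0.0), 1.8), ((-2.0, 0.0), 1.8)):
            z = pts[:, 2]
            rad = r0 * np.clip(1 + z / L, 0, 1)
            inz = (z <= 0) & (z >= -L)
            root_oracle |= inz & (
                (pts[:, 0] - cx[0]) ** 2 + (pts[:, 1] - cx[1]) ** 2 <= rad**2
            )
        root_oracle &= ~crown_oracle  # crown takes priority at the junction

        crown_count = int(threshold_mask(vol, cfg.crown_range).sum())
        root_count = int(threshold_mask(vol, cfg.root_range).sum())
        assert crown_count == int(crown_oracle.sum())
        assert root_count == int(root_oracle.sum())


class TestUnionMasks:
    def test_mask_and_complement_cover_everything(self, rng):
        a = rng.random((8, 8, 8)) > 0.5
        assert union_masks([a, ~a]).all()

    def test_idempotent(self, rng):
        a = rng.random((8, 8, 8)) > 0.5
        assert np.array_equal(union_masks([a, a]), a)

    def test_matches_elementwise_or_oracle(self, rng):
        masks = [rng.random((6, 7, 8)) > 0.4 for _ in range(4)]
        expect = masks[0] | masks[1] | masks[2] | masks[3]
        assert np.array_equal(union_masks(masks), expect)

    def test_monotone_never_removes_voxels(self, rng):
        a = rng.random((8, 8, 8)) > 0.5
        b = rng.random((8, 8, 8)) > 0.5
        u = union_masks([a, b])
        assert u.sum() >= max(a.sum(), b.sum())
        assert (u & a).sum() == a.sum()

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            union_masks([np.ones((3, 3, 3), bool), np.ones((4, 3, 3), bool)])


class TestApicalWindow:
    def test_zero_radius_is_noop(self):
        vol = make_volume()
        mask = np.ones(vol.shape, dtype=bool)
        assert np.array_equal(open_apical_window(mask, vol, (5, 5, 5), 0.0), mask)

    def test_cleared_count_matches_sphere_voxelization_oracle(self):
        vol = make_volume(shape=(40, 40, 40), spacing=0.25)
        mask = np.ones(vol.shape, dtype=bool)
        center, radius = np.array([5.0, 5.0, 5.0]), 2.0
        out = open_apical_window(mask, vol, center, radius)
        pts = vol.voxel_centers().reshape(-1, 3)
        inside = np.sum((pts - center) ** 2, axis=1) <= radius**2
        assert int(mask.sum() - out.sum()) == int(inside.sum())

    def test_window_far_from_mask_warns_and_is_noop(self):
        vol = make_volume()
        mask = np.ones(vol.shape, dtype=bool)
        with pytest.warns(UserWarning):
            out = open_apical_window(mask, vol, (500.0, 500.0, 500.0), 2.0)
        assert np.array_equal(out, mask)


class TestExtractMesh:
    def test_cube_surface_area(self):
        vol = make_volume(shape=(40, 40, 40), spacing=0.25)
        pts = vol.voxel_centers()
        s = 6.0
        mask = np.all((pts >= 1.0) & (pts <= 1.0 + s), axis=-1)
        mesh = extract_mesh(mask, vol).as_trimesh()
        # iso-level 0.5 places faces half a voxel outside the border centers
        s_eff = s + 0.25
        assert mesh.area == pytest.approx(6 * s_eff**2, rel=0.05)

    def test_sphere_enclosed_volume_and_voxel_consistency(self):
        vol = make_volume(shape=(50, 50, 50), spacing=0.25)
        pts = vol.voxel_centers()
        center, r = np.array([6.0, 6.0, 6.0]), 4.0
        mask = np.sum((pts - center) ** 2, axis=-1) <= r**2
        tm = extract_mesh(mask, vol).as_trimesh()
        analytic = 4.0 / 3.0 * np.pi * r**3
        assert tm.volume == pytest.approx(analytic, rel=0.05)
        voxel_volume = mask.sum() * 0.25**3
        assert tm.volume == pytest.approx(voxel_volume, rel=0.05)

    def test_vertices_confined_to_dilated_solid(self):
        """Crown-mask mesh vertices stay within one voxel diagonal of the
        analytic crown solid."""
        spec = PhantomSpec(voxel_spacing_mm=(0.4, 0.4, 0.4), noise_sd=0.0)
        base, _, _ = generate_phantom(spec, GroundTruthMotion.zero(), build_meshes=False)
        cfg = default_thresholds(spec)
        mask = threshold_mask(base.volume, cfg.crown_range)
        mesh = extract_mesh(mask, base.volume)
        phantom = ArchPhantom(spec)
        diag = float(np.linalg.norm(spec.voxel_spacing_mm))
        tissue = phantom.tissue_at(mesh.vertices, dilate=diag)
        assert (tissue == 1).all()  # all vertices within dilated crown class

    def test_empty_mask_rejected(self):
        vol = make_volume()
        with pytest.raises(ValueError, match="empty"):
            extract_mesh(np.zeros(vol.shape, dtype=bool), vol)
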