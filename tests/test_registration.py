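"""Masked alignment-area selection, Kabsch/ICP, transform utilities."""

import dataclasses

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from molardrift import (
    AlignmentMask,
    RigidTransform,
    SurfaceModel,
    apply_transform,
    icp_align,
    kabsch,
    select_alignment_points,
)
from molardrift.core import Tissue

from _oracles import rot_z


def labeled_model(n_target_crown=200, n_neighbor_crown=300, n_bone=400,
                  n_crest=50, n_window=60, seed=0):
    """Synthetic labeled point soup (faces unused by selection)."""
    rng = np.random.default_rng(seed)
    counts = [n_target_crown, n_neighbor_crown, n_bone, n_crest, n_window]
    verts = rng.normal(size=(sum(counts), 3)) * 10
    tissue = np.concatenate([
        np.full(n_target_crown, Tissue.CROWN),
        np.full(n_neighbor_crown, Tissue.CROWN),
        np.full(n_bone + n_crest + n_window, Tissue.BONE),
    ])
    is_target = np.zeros(len(verts), bool)
    is_target[:n_target_crown] = True
    crest = np.zeros(len(verts), bool)
    crest[n_target_crown + n_neighbor_crown + n_bone:
          n_target_crown + n_neighbor_crown + n_bone + n_crest] = True
    window = np.zeros(len(verts), bool)
    window[-n_window:] = True
    return SurfaceModel(verts, np.zeros((1, 3), int), tissue, is_target, crest, window)


class TestAlignmentSelection:
    def test_label_bookkeeping(self):
        model = labeled_model()
        pts = select_alignment_points(model, AlignmentMask())
        # neighbor crowns + bone, minus crest and window zones
        assert len(pts) == 300 + 400

    def test_target_crown_never_included(self):
        model = labeled_model()
        pts = select_alignment_points(
            model, AlignmentMask(include_stable_bone=False)
        )
        assert len(pts) == 300
        target = model.vertices[model.is_target]
        assert not any((pts == t).all(axis=1).any() for t in target)

    def test_zone_flags_control_bone_subset(self):
        model = labeled_model()
        pts = select_alignment_points(
            model,
            AlignmentMask(include_crowns_except_target=False,
                          exclude_crest_zone=False, exclude_window_zone=False),
        )
        assert len(pts) == 400 + 50 + 60

    def test_all_exclude_mask_rejected(self):
        with pytest.raises(ValueError, match="include"):
            AlignmentMask(include_crowns_except_target=False, include_stable_bone=False)

    def test_underconstrained_selection_rejected(self):
        model = labeled_model(n_neighbor_crown=10, n_bone=5, n_crest=0, n_window=0)
        with pytest.raises(ValueError, match="under-constrained"):
            select_alignment_points(model, AlignmentMask())


class TestKabsch:
    def test_matches_scipy_alignment_oracle(self, rng):
        P = rng.normal(size=(60, 3))
        true = RigidTransform.from_axis_angle([1, -2, 0.5], 17.0).compose(
            RigidTransform.from_translation([0.3, -4.0, 1.2])
        )
        Q = true.apply(P)
        est = kabsch(P, Q)
        rot, rssd = Rotation.align_vectors(
            Q - Q.mean(axis=0), P - P.mean(axis=0)
        )
        assert np.allclose(est.rotation, rot.as_matrix(), atol=1e-8)
        assert np.abs(est.apply(P) - Q).max() < 1e-9


class TestICP:
    def _cloud(self, rng, n=500):
        # a non-degenerate cloud with structure in all directions
        pts = rng.normal(size=(n, 3)) * [10, 6, 3]
        pts[:, 2] += 0.5 * np.sin(pts[:, 0])
        return pts

    def test_identical_sets_give_identity(self, rng):
        pts = self._cloud(rng)
        res = icp_align(pts, pts)
        assert res.converged
        assert res.final_rms < 1e-9
        assert res.transform.rotation_angle_deg() < 1e-6
        assert np.linalg.norm(res.transform.translation) < 1e-6

    def test_known_transform_recovery(self, rng):
        fixed = self._cloud(rng, n=2000)
        true = RigidTransform.from_axis_angle([0.2, 1, 0.1], 5.0).compose(
            RigidTransform.from_translation([0.6, -0.5, 0.6])
        )
        moving = true.inverse().apply(fixed)
        res = icp_align(moving, fixed)
        err = res.transform.compose(true.inverse())
        assert err.rotation_angle_deg() < 0.01
        assert np.linalg.norm(err.translation) < 0.01

    def test_noisy_recovery_within_tolerance(self):
        rng = np.random.default_rng(11)
        fixed = self._cloud(rng, n=3000)
        true = RigidTransform.from_axis_angle([0, 0, 1], 4.0).compose(
            RigidTransform.from_translation([0.8, 0.3, -0.4])
        )
        moving = true.inverse().apply(fixed)
        idx = rng.choice(len(moving), size=len(moving) // 10, replace=False)
        moving[idx] += rng.normal(0, 0.05, size=(len(idx), 3))
        res = icp_align(moving, fixed)
        err = res.transform.compose(true.inverse())
        assert err.rotation_angle_deg() < 0.1
        assert np.linalg.norm(err.translation) < 0.05

    def test_rms_history_monotone_nonincreasing(self, rng):
        fixed = self._cloud(rng, n=1500)
        true = RigidTransform.from_axis_angle([1, 1, 0], 6.0).compose(
            RigidTransform.from_translation([1.0, 0.5, 0.2])
        )
        res = icp_align(true.inverse().apply(fixed), fixed)
        hist = np.array(res.rms_history)
        assert np.all(np.diff(hist) <= 1e-9)

    def test_nonconvergence_flagged_not_raised(self, rng):
        fixed = self._cloud(rng, n=800)
        moving = RigidTransform.from_axis_angle([0, 0, 1], 8.0).apply(fixed)
        res = icp_align(moving, fixed, max_iter=2)
        assert not res.converged
        assert res.n_iterations == 2

    def test_small_point_sets_rejected(self, rng):
        pts = rng.normal(size=(50, 3))
        with pytest.raises(ValueError, match="100"):
            icp_align(pts, pts)

    def test_returned_transform_is_rigid(self, rng):
        fixed = self._cloud(rng, n=600)
        moving = RigidTransform.from_axis_angle([1, 0, 0], 3.0).apply(fixed)
        R = icp_align(moving, fixed).transform.rotation
        assert np.allclose(R.T @ R, np.eye(3), atol=1e-9)
        assert np.isclose(np.linalg.det(R), 1.0, atol=1e-9)


class TestApplyTransform:
    def test_identity_unchanged(self, rng):
        pts = rng.normal(size=(20, 3))
        assert np.array_equal(apply_transform(pts, RigidTransform.identity()), pts)

    def test_inverse_round_trip(self, rng):
        t = RigidTransform.from_axis_angle([3, 1, 2], 33.0).compose(
            RigidTransform.from_translation([5, -2, 7])
        )
        pts = rng.normal(size=(30, 3))
        back = apply_transform(apply_transform(pts, t), t.inverse())
        assert np.abs(back - pts).max() < 1e-9

    def test_distances_preserved(self, rng):
        t = RigidTransform.from_axis_angle([1, 4, -1], 51.0, center=[1, 2, 3])
        pts = rng.normal(size=(40, 3))
        out = apply_transform(pts, t)
        d0 = np.linalg.norm(pts[:, None] - pts[None], axis=-1)
        d1 = np.linalg.norm(out[:, None] - out[None], axis=-1)
        assert np.abs(d1 - d0).max() < 1e-9

    def test_known_rotation_matches_matrix_oracle(self):
        t = RigidTransform.from_axis_angle([0, 0, 1], 30.0)
        v = np.array([1.0, 0.0, 0.0])
        assert np.allclose(t.apply(v), rot_z(30.0) @ v, atol=1e-12)
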