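"""Rigid transforms, coarse principal-axes alignment, trimmed ICP."""

import numpy as np
import pytest

import cartoplan as cp
from cartoplan.phantom import epicardial_surface_points, generate_ra_cloud
from cartoplan.registration import (RigidTransform, apply_transform, coarse_align,
                                    icp_refine, register_two_stage)


@pytest.fixture(scope="module")
def epi_cloud(noiseless_phantom):
    _, _, truth = noiseless_phantom
    return truth, epicardial_surface_points(truth)


class TestRigidTransform:
    def test_compose_inverse_round_trip(self):
        tf = RigidTransform.from_axis_angle([1, 2, 3], 25.0, translation=[4, -1, 7])
        pts = np.random.default_rng(0).normal(size=(50, 3))
        back = tf.inverse().apply(tf.apply(pts))
        assert np.allclose(back, pts, atol=1e-9)

    def test_identity_apply_is_noop(self):
        pts = np.random.default_rng(1).normal(size=(20, 3))
        assert np.array_equal(RigidTransform.identity().apply(pts), pts)

    def test_improper_rotation_rejected(self):
        with pytest.raises(ValueError, match="proper|orthonormal"):
            RigidTransform(rotation=np.diag([1.0, 1.0, -1.0]))

    def test_isometry_preserves_pairwise_distances(self):
        tf = RigidTransform.from_axis_angle([0, 1, 0], 40.0, translation=[1, 2, 3])
        pts = np.random.default_rng(2).normal(size=(30, 3))
        moved = tf.apply(pts)
        d0 = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        d1 = np.linalg.norm(moved[:, None] - moved[None, :], axis=-1)
        assert np.allclose(d0, d1, atol=1e-9)


class TestCoarseAlign:
    def test_pure_translation_recovered(self, epi_cloud):
        _, src = epi_cloud
        tf = coarse_align(src, src + np.array([5.0, -3.0, 2.0]))
        assert np.allclose(tf.rotation, np.eye(3), atol=1e-6)
        assert np.allclose(tf.translation, [5.0, -3.0, 2.0], atol=1e-6)

    def test_identical_clouds_identity(self, epi_cloud):
        _, src = epi_cloud
        tf = coarse_align(src, src)
        assert np.allclose(tf.rotation, np.eye(3), atol=1e-6)
        assert np.allclose(tf.translation, 0.0, atol=1e-6)

    def test_30_degree_rotation_recovered(self, epi_cloud):
        _, src = epi_cloud
        truth_tf = RigidTransform.from_axis_angle([0, 0, 1], 30.0)
        tf = coarse_align(src, truth_tf.apply(src))
        err = tf.compose(truth_tf.inverse())
        assert err.rotation_angle_deg() < 0.5

    def test_degenerate_cloud_centroid_only(self):
        rng = np.random.default_rng(3)
        planar = np.column_stack([rng.normal(size=(50, 2)), np.zeros(50)])
        tf = coarse_align(planar, planar + [0, 0, 4.0])
        assert np.allclose(tf.rotation, np.eye(3))
        assert np.allclose(tf.translation, [0, 0, 4.0], atol=1e-9)


class TestICP:
    def test_identical_clouds_zero_rms(self, epi_cloud):
        _, src = epi_cloud
        res = icp_refine(src, src)
        assert res.rms == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(res.transform.rotation, np.eye(3), atol=1e-9)

    def test_known_transform_recovered_noiseless(self, epi_cloud):
        _, src = epi_cloud
        tf = RigidTransform.from_axis_angle([0, 0, 1], 10.0, translation=[5, -3, 2])
        res = icp_refine(src, tf.apply(src), init=coarse_align(src, tf.apply(src)),
                         trim_fraction=0.0)
        err = res.transform.compose(tf.inverse())
        assert err.rotation_angle_deg() < 0.1
        assert np.linalg.norm(res.transform.translation - tf.translation) < 0.05

    def test_rms_history_non_increasing(self, epi_cloud):
        truth, src = epi_cloud
        tf = RigidTransform.from_axis_angle([0.2, 0.1, 1], 12.0, translation=[4, 2, -3])
        cloud, _ = generate_ra_cloud(truth, tf, noise_sd=0.5, keep_fraction=0.7, seed=5)
        res = icp_refine(src, cloud, init=coarse_align(src, cloud))
        hist = np.asarray(res.rms_history)
        assert np.all(np.diff(hist) <= 1e-9)

    def test_non_finite_rejected(self, epi_cloud):
        _, src = epi_cloud
        bad = src.copy()
        bad[0, 0] = np.nan
        with pytest.raises(ValueError, match="finite"):
            icp_refine(bad, src)

    def test_two_stage_noisy_partial_recovery_20_seeds(self, epi_cloud):
        """Noise 0.5 mm, 70% coverage: < 2 deg / < 1 mm error on every seed."""
        truth, src = epi_cloud
        tf = RigidTransform.from_axis_angle([0.2, 0.1, 1], 10.0, translation=[5, -3, 2])
        rot_errs, tr_errs, pt95 = [], [], []
        for seed in range(20):
            cloud, _ = generate_ra_cloud(truth, tf, noise_sd=0.5, keep_fraction=0.7,
                                         seed=seed)
            res = register_two_stage(src, cloud)
            err = res.transform.compose(tf.inverse())
            rot_errs.append(err.rotation_angle_deg())
            tr_errs.append(np.linalg.norm(res.transform.translation - tf.translation))
            e = np.linalg.norm(res.transform.apply(src) - tf.apply(src), axis=1)
            pt95.append(np.percentile(e, 95))
        assert max(rot_errs) < 2.0
        assert max(tr_errs) < 1.0
        assert max(pt95) < 1.5


class TestApplyTransform:
    def test_identity_leaves_plan_bitwise(self, default_plan):
        plan = default_plan["plan"]
        moved = apply_transform(plan, RigidTransform.identity())
        assert np.array_equal(moved.positions(), plan.positions())

    def test_round_trip_and_isometry_on_plan(self, default_plan):
        plan = default_plan["plan"]
        tf = RigidTransform.from_axis_angle([1, 1, 0], 33.0, translation=[9, -2, 4])
        moved = apply_transform(plan, tf)
        back = apply_transform(moved, tf.inverse())
        assert np.allclose(back.positions(), plan.positions(), atol=1e-9)
        p0, p1 = plan.positions(), moved.positions()
        d0 = np.linalg.norm(p0[:, None] - p0[None, :], axis=-1)
        d1 = np.linalg.norm(p1[:, None] - p1[None, :], axis=-1)
        assert np.allclose(d0, d1, atol=1e-9)
        # scalars untouched
        assert [t.needle_depth for t in moved.targets] == \
            [t.needle_depth for t in plan.targets]

    def test_map_scalars_preserved(self, default_phantom):
        emap = default_phantom["emap"]
        tf = RigidTransform.from_axis_angle([0, 0, 1], 15.0)
        moved = apply_transform(emap, tf)
        assert np.array_equal(moved.transmurality, emap.transmurality)
        assert np.allclose(moved.vertices, tf.apply(emap.vertices))
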