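"""Skeleton extraction, rigid-transform algebra and ICP registration properties."""

import numpy as np
import pytest

import marrowdose as md
from marrowdose.registration import fit_rigid
from marrowdose.synthetic import rotation_about_axis

from conftest import random_rigid, rms


class TestExtractSkeleton:
    def test_cube_above_threshold_yields_its_voxel_centers(self):
        hu = np.zeros((6, 6, 6))
        hu[2:4, 2:4, 2:4] = 1000.0
        ct = md.CTVolume(values=hu, spacing=[2, 2, 2], origin=[10, 0, -4])
        skel = md.extract_skeleton(ct, 200)
        assert len(skel) == 8
        expected = {
            (10 + 2 * i, 2 * j, -4 + 2 * k)
            for i in (2, 3) for j in (2, 3) for k in (2, 3)
        }
        assert {tuple(p) for p in skel.points} == expected

    def test_threshold_above_max_rejected(self):
        ct = md.CTVolume(values=np.zeros((3, 3, 3)), spacing=[1, 1, 1], origin=[0, 0, 0])
        with pytest.raises(ValueError, match="threshold"):
            md.extract_skeleton(ct, 200)

    def test_zero_threshold_returns_every_positive_voxel(self):
        ct = md.CTVolume(values=np.ones((3, 4, 5)), spacing=[1, 1, 1], origin=[0, 0, 0])
        assert len(md.extract_skeleton(ct, 0)) == 3 * 4 * 5


class TestPhantomSkeleton:
    def test_counts_and_partition(self, mini_phantom, mini_skeleton):
        n_bone = int((mini_phantom.label_volume > 0).sum())
        assert len(mini_skeleton) == n_bone
        by_tissue = [
            int(((mini_phantom.label_volume > 0) & (mini_phantom.tissue_volume == t)).sum())
            for t in (1, 2, 3)
        ]
        assert sum(by_tissue) == n_bone

    def test_points_inside_bounding_box(self, mini_phantom, mini_skeleton):
        low = mini_phantom.origin
        high = mini_phantom.origin + (np.array(mini_phantom.shape) - 1) * mini_phantom.spacing
        assert np.all(mini_skeleton.points >= low - 1e-9)
        assert np.all(mini_skeleton.points <= high + 1e-9)

    def test_boneless_phantom_rejected(self, mini_phantom):
        import dataclasses
        empty = dataclasses.replace(
            mini_phantom,
            label_volume=np.zeros_like(mini_phantom.label_volume),
            tissue_volume=np.zeros_like(mini_phantom.tissue_volume),
            site_names={},
        )
        with pytest.raises(ValueError, match="no bone"):
            md.phantom_skeleton_points(empty)


class TestTransformAlgebra:
    def test_identity_leaves_points_unchanged(self):
        pts = np.arange(12.0).reshape(4, 3)
        np.testing.assert_array_equal(md.RigidTransform.identity().apply(pts), pts)

    def test_pure_translation(self):
        t = md.RigidTransform(translation=[1, 2, 3])
        np.testing.assert_allclose(t.apply([[0, 0, 0]]), [[1, 2, 3]])

    def test_compose_with_inverse_is_identity(self):
        rng = np.random.default_rng(2)
        t = md.RigidTransform(
            rotation=rotation_about_axis(rng.normal(size=3), 0.7),
            translation=rng.uniform(-50, 50, 3),
        )
        pts = rng.uniform(-100, 100, (50, 3))
        round_trip = t.compose(t.inverse()).apply(pts)
        np.testing.assert_allclose(round_trip, pts, atol=1e-12)
        np.testing.assert_allclose(t.inverse().apply(t.apply(pts)), pts, atol=1e-12)

    def test_non_orthonormal_rotation_rejected(self):
        with pytest.raises(ValueError, match="orthonormal"):
            md.RigidTransform(rotation=np.eye(3) * 2.0)

    def test_reflection_rejected(self):
        with pytest.raises(ValueError, match="proper"):
            md.RigidTransform(rotation=np.diag([1.0, 1.0, -1.0]))


class TestInitialAlign:
    def test_identical_clouds_give_identity(self, mini_skeleton):
        t = md.initial_align(mini_skeleton, mini_skeleton)
        np.testing.assert_allclose(t.rotation, np.eye(3))
        np.testing.assert_allclose(t.translation, 0.0, atol=1e-9)

    def test_translation_recovered_from_centroids(self, mini_skeleton):
        shifted = md.SkeletonPointSet(mini_skeleton.points + [10, 0, 0], frame="patient")
        t = md.initial_align(mini_skeleton, shifted)
        np.testing.assert_allclose(t.translation, [10, 0, 0], atol=1e-9)
        np.testing.assert_allclose(t.rotation, np.eye(3))

    def test_rotation_is_left_to_icp(self, mini_skeleton, mini_centroid):
        rot = md.RigidTransform.about_point(
            rotation_about_axis([0, 0, 1], 0.5), [0, 0, 0], mini_centroid)
        target = md.SkeletonPointSet(rot.apply(mini_skeleton.points), frame="patient")
        t = md.initial_align(mini_skeleton, target)
        np.testing.assert_allclose(t.rotation, np.eye(3))


class TestICP:
    def test_recovers_known_transform(self, mini_skeleton, mini_centroid):
        truth = md.RigidTransform.about_point(
            rotation_about_axis([0, 0, 1], np.deg2rad(30)), [5, -3, 2], mini_centroid)
        target = md.SkeletonPointSet(truth.apply(mini_skeleton.points), frame="patient")
        res = md.icp_register(mini_skeleton, target,
                              md.ICPConfig(convergence_tol=1e-6, max_iterations=200))
        assert rms(res.transform.apply(mini_skeleton.points), target.points) < 1e-6

    def test_identical_clouds_converge_immediately(self, mini_skeleton):
        res = md.icp_register(mini_skeleton, mini_skeleton)
        assert res.converged
        assert len(res.history) <= 2
        np.testing.assert_allclose(res.transform.rotation, np.eye(3), atol=1e-9)
        np.testing.assert_allclose(res.transform.translation, 0.0, atol=1e-9)

    def test_jittered_target_registers_within_noise(self, mini_skeleton, mini_centroid):
        rng = np.random.default_rng(17)
        sigma = 0.5
        truth = random_rigid(rng, mini_centroid)
        jittered = truth.apply(mini_skeleton.points) + rng.normal(0, sigma, mini_skeleton.points.shape)
        target = md.SkeletonPointSet(jittered, frame="patient")
        res = md.icp_register(mini_skeleton, target,
                              md.ICPConfig(convergence_tol=1e-4, max_iterations=200))
        assert rms(res.transform.apply(mini_skeleton.points), jittered) <= 2 * sigma

    def test_history_is_monotone_non_increasing(self, mini_skeleton, mini_centroid):
        rng = np.random.default_rng(23)
        for _ in range(3):
            truth = random_rigid(rng, mini_centroid)
            target = md.SkeletonPointSet(
                truth.apply(mini_skeleton.points) + rng.normal(0, 1.0, mini_skeleton.points.shape),
                frame="patient")
            res = md.icp_register(mini_skeleton, target)
            diffs = np.diff(res.history)
            assert np.all(diffs <= 1e-9)

    def test_equivariance_to_source_prerotation(self, mini_skeleton, mini_centroid):
        rng = np.random.default_rng(29)
        truth = random_rigid(rng, mini_centroid, max_angle_deg=25)
        target = md.SkeletonPointSet(truth.apply(mini_skeleton.points), frame="patient")
        pre = md.RigidTransform.about_point(
            rotation_about_axis([1, 1, 0], np.deg2rad(15)), [20, 0, -10], mini_centroid)
        rotated_source = md.SkeletonPointSet(pre.apply(mini_skeleton.points), frame="phantom")
        cfg = md.ICPConfig(convergence_tol=1e-6, max_iterations=300)
        direct = md.icp_register(mini_skeleton, target, cfg)
        via_pre = md.icp_register(rotated_source, target, cfg)
        aligned_a = direct.transform.apply(mini_skeleton.points)
        aligned_b = via_pre.transform.apply(rotated_source.points)
        assert rms(aligned_a, aligned_b) < 1e-3

    def test_scale_is_exactly_one_when_disabled(self, mini_skeleton, mini_centroid):
        truth = random_rigid(np.random.default_rng(31), mini_centroid)
        target = md.SkeletonPointSet(truth.apply(mini_skeleton.points), frame="patient")
        res = md.icp_register(mini_skeleton, target, md.ICPConfig(allow_scale=False))
        assert res.transform.scale == 1.0

    def test_similarity_mode_recovers_isotropic_scale(self, mini_skeleton, mini_centroid):
        truth = md.RigidTransform.about_point(
            rotation_about_axis([0, 1, 0], np.deg2rad(10)), [4, 4, -6], mini_centroid,
            scale=1.07)
        target = md.SkeletonPointSet(truth.apply(mini_skeleton.points), frame="patient")
        res = md.icp_register(mini_skeleton, target,
                              md.ICPConfig(allow_scale=True, convergence_tol=1e-6,
                                           max_iterations=300))
        assert res.transform.scale == pytest.approx(1.07, abs=1e-3)

    def test_degenerate_collinear_geometry_rejected(self):
        line = np.column_stack([np.arange(10.0), np.zeros(10), np.zeros(10)])
        with pytest.raises(ValueError, match="degenerate"):
            fit_rigid(line, line + [1.0, 0, 0])

    def test_too_few_points_rejected(self):
        a = md.SkeletonPointSet(np.zeros((2, 3)) + [[0, 0, 0], [1, 1, 1]], frame="phantom")
        with pytest.raises(ValueError, match="at least 3"):
            md.icp_register(a, a)
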