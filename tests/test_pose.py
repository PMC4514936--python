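"""Pose differences: translation, Kabsch rotation, Euler angle extraction."""

import numpy as np
import pytest

from splintacc.geometry import (
    FiducialTriad,
    LabelMismatchError,
    Region,
    Timepoint,
    vector_triad,
)
from splintacc.pose import (
    AngleConvention,
    RegionMismatchError,
    RotationEstimate,
    estimate_rotation,
    euler_to_matrix,
    matrix_to_euler,
    pose_difference,
    rotation_angles,
    translation_difference,
)

from conftest import random_rotation_matrix, random_triad_coords
from oracles import brute_force_rotation

COORDS = np.array([(0.0, 0.0, 0.0), (30.0, 0.0, 0.0), (0.0, 40.0, 10.0)])


def pair(post_coords, plan_coords=COORDS, region=Region.MAXILLA):
    plan = FiducialTriad.from_coords(region, Timepoint.PLANNED, plan_coords)
    post = FiducialTriad.from_coords(region, Timepoint.POSTOP, post_coords)
    return plan, post


class TestTranslationDifference:
    def test_identity_is_zero(self):
        t = translation_difference(*pair(COORDS))
        assert t.magnitude == pytest.approx(0.0, abs=1e-12)

    def test_planned_advancement_recovered(self):
        # a pure 5 mm shift of every screw moves the barycenter by 5 mm
        t = translation_difference(*pair(COORDS + [5.0, 0.0, 0.0]))
        assert (t.dx, t.magnitude) == (pytest.approx(5.0), pytest.approx(5.0))

    def test_1_2_2_norm(self):
        t = translation_difference(*pair(COORDS + [1.0, 2.0, 2.0]))
        assert t.magnitude == pytest.approx(3.0, abs=1e-12)

    def test_region_mismatch_rejected(self):
        plan = FiducialTriad.from_coords(Region.SKULL, Timepoint.PLANNED, COORDS)
        post = FiducialTriad.from_coords(Region.MAXILLA, Timepoint.POSTOP, COORDS)
        with pytest.raises(RegionMismatchError):
            translation_difference(plan, post)

    def test_timepoint_order_enforced(self):
        plan, post = pair(COORDS)
        with pytest.raises(ValueError, match="planned, postop"):
            translation_difference(post, plan)

    def test_label_mismatch_rejected(self):
        plan = FiducialTriad.from_coords(
            Region.MAXILLA, Timepoint.PLANNED, COORDS, labels=(1, 2, 3)
        )
        post = FiducialTriad.from_coords(
            Region.MAXILLA, Timepoint.POSTOP, COORDS, labels=(1, 2, 4)
        )
        with pytest.raises(LabelMismatchError):
            translation_difference(plan, post)


class TestEstimateRotation:
    def test_identity(self):
        plan, post = pair(COORDS)
        est = estimate_rotation(vector_triad(plan), vector_triad(post))
        np.testing.assert_allclose(est.matrix, np.eye(3), atol=1e-12)
        assert est.residual_rmse == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(est.transformed_y_axis, [0, 1, 0], atol=1e-12)

    def test_known_rotation_recovered_exactly(self):
        R = euler_to_matrix(0.0, 0.0, 10.0)
        plan, post = pair(COORDS @ R.T)
        est = estimate_rotation(vector_triad(plan), vector_triad(post))
        np.testing.assert_allclose(est.matrix, R, atol=1e-9)
        assert est.residual_rmse < 1e-9

    def test_always_proper_orthonormal(self, rng):
        for _ in range(20):
            coords = random_triad_coords(rng)
            noisy = coords @ random_rotation_matrix(rng).T + rng.normal(0, 0.5, (3, 3))
            plan, post = pair(noisy, plan_coords=coords)
            est = estimate_rotation(vector_triad(plan), vector_triad(post))
            np.testing.assert_allclose(est.matrix.T @ est.matrix, np.eye(3), atol=1e-9)
            assert np.linalg.det(est.matrix) == pytest.approx(1.0, abs=1e-9)

    def test_equivariance_under_global_rotation(self, rng):
        coords = random_triad_coords(rng)
        R0 = random_rotation_matrix(rng)
        noisy = coords @ R0.T + rng.normal(0, 0.2, (3, 3))
        plan, post = pair(noisy, plan_coords=coords)
        est = estimate_rotation(vector_triad(plan), vector_triad(post))
        G = random_rotation_matrix(rng, max_deg=170.0)
        plan_g, post_g = pair(noisy @ G.T, plan_coords=coords @ G.T)
        est_g = estimate_rotation(vector_triad(plan_g), vector_triad(post_g))
        np.testing.assert_allclose(est_g.matrix, G @ est.matrix @ G.T, atol=1e-9)
        assert est_g.residual_rmse == pytest.approx(est.residual_rmse, abs=1e-9)

    def test_agrees_with_brute_force_oracle_under_noise(self, rng):
        # a handful here; the 20-instance sweep lives in the acceptance suite
        for _ in range(3):
            coords = random_triad_coords(rng)
            R = random_rotation_matrix(rng, max_deg=12.0)
            noisy = coords @ R.T + rng.normal(0, 0.1, (3, 3))
            plan, post = pair(noisy, plan_coords=coords)
            vp, vq = vector_triad(plan), vector_triad(post)
            est = estimate_rotation(vp, vq)
            oracle_angles, oracle_fit = brute_force_rotation(vp.vectors, vq.vectors)
            kabsch_angles = np.array(matrix_to_euler(est.matrix))
            np.testing.assert_allclose(kabsch_angles, oracle_angles, atol=0.1)
            kabsch_fit = float(np.sum((vp.vectors @ est.matrix.T - vq.vectors) ** 2))
            assert kabsch_fit <= oracle_fit + 1e-9
            assert est.residual_rmse > 0

    def test_improper_matrix_rejected(self):
        reflection = np.diag([1.0, 1.0, -1.0])
        with pytest.raises(ValueError, match="proper"):
            RotationEstimate(Region.SKULL, reflection, np.array([0.0, 1.0, 0.0]), 0.0)


class TestRotationAngles:
    def make_est(self, R):
        return RotationEstimate(
            Region.MAXILLA, R, R @ np.array([0.0, 1.0, 0.0]), 0.0
        )

    def test_identity_standard_is_zero(self):
        ang = rotation_angles(self.make_est(np.eye(3)))
        np.testing.assert_allclose(ang.angles, 0.0, atol=1e-12)
        assert not ang.gimbal_lock

    def test_single_axis_pitch(self):
        ang = rotation_angles(self.make_est(euler_to_matrix(5.0, 0.0, 0.0)))
        np.testing.assert_allclose(ang.angles, [5.0, 0.0, 0.0], atol=1e-9)

    def test_paper_literal_identity_yaw_degenerates_to_90(self):
        # the printed yaw formula atan2(y, x) evaluates to 90 deg at identity
        ang = rotation_angles(self.make_est(np.eye(3)), "paper_literal")
        assert (ang.pitch, ang.roll, ang.yaw) == (0.0, 0.0, pytest.approx(90.0))

    @pytest.mark.parametrize("deg", [-12.0, -3.0, 4.0, 15.0])
    def test_paper_literal_pitch_matches_standard_for_x_rotations(self, deg):
        est = self.make_est(euler_to_matrix(deg, 0.0, 0.0))
        lit = rotation_angles(est, "paper_literal")
        std = rotation_angles(est, "standard")
        assert lit.pitch == pytest.approx(std.pitch, abs=1e-9)

    @pytest.mark.parametrize("deg", [-12.0, -3.0, 4.0, 15.0])
    def test_paper_literal_roll_is_negated_standard_yaw_for_z_rotations(self, deg):
        est = self.make_est(euler_to_matrix(0.0, 0.0, deg))
        lit = rotation_angles(est, "paper_literal")
        std = rotation_angles(est, "standard")
        assert lit.roll == pytest.approx(-std.yaw, abs=1e-9)

    def test_gimbal_lock_flagged_not_fatal(self):
        ang = rotation_angles(self.make_est(euler_to_matrix(0.0, 90.0, 0.0)))
        assert ang.gimbal_lock
        assert ang.roll == pytest.approx(90.0, abs=1e-6)


class TestPoseDifference:
    def test_identity(self):
        pd_ = pose_difference(*pair(COORDS))
        assert pd_.translation.magnitude == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(pd_.rotation.angles, 0.0, atol=1e-9)

    def test_constructed_shift_plus_pitch(self):
        R = euler_to_matrix(3.0, 0.0, 0.0)
        b = COORDS.mean(axis=0)
        post = (COORDS - b) @ R.T + b + [5.0, 0.0, 0.0]
        pd_ = pose_difference(*pair(post))
        assert pd_.translation.magnitude == pytest.approx(5.0, abs=1e-9)
        assert pd_.rotation.pitch == pytest.approx(3.0, abs=1e-9)

    def test_noise_free_rigid_round_trip(self, rng):
        # any proper rigid motion is recovered exactly from the triad pair
        for _ in range(10):
            coords = random_triad_coords(rng)
            angles = rng.uniform(-20, 20, 3)
            R = euler_to_matrix(*angles)
            t = rng.uniform(-10, 10, 3)
            b = coords.mean(axis=0)
            post = (coords - b) @ R.T + b + t
            pd_ = pose_difference(*pair(post, plan_coords=coords))
            np.testing.assert_allclose(pd_.translation.components, t, atol=1e-9)
            np.testing.assert_allclose(pd_.rotation.angles, angles, atol=1e-9)

    def test_mismatched_regions_rejected(self):
        plan = FiducialTriad.from_coords(Region.SKULL, Timepoint.PLANNED, COORDS)
        post = FiducialTriad.from_coords(Region.MANDIBLE, Timepoint.POSTOP, COORDS)
        with pytest.raises(RegionMismatchError):
            pose_difference(plan, post)

    def test_convention_passthrough(self):
        pd_ = pose_difference(*pair(COORDS), convention="paper_literal")
        assert pd_.rotation.convention is AngleConvention.PAPER_LITERAL
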