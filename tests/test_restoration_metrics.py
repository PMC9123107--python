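"""Restoration of the distal fibula and pose-error decomposition."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fibrestore import (
    FibulaErrorReport,
    RigidTransform,
    SegmentName,
    decompose_error,
    generate_bone_pair,
    inject_deformity,
    reference_pose,
    restore_distal_fibula,
)
from fibrestore.anatomy import AnatomicalFrame
from fibrestore.pipeline import _distal_fibula_indices, evaluate_pair
from fibrestore.registration import transform_difference
from fibrestore.restoration_metrics import swing_twist_angle_deg
from fibrestore.synthetic_cohort import MIRROR_AXIS
from fibrestore.mesh_core import mirror_mesh, TriMesh
from fibrestore.anatomy import build_anatomical_frame


@pytest.fixture(scope="module")
def frame():
    return AnatomicalFrame(
        origin=np.zeros(3), x_axis=[1, 0, 0], y_axis=[0, 1, 0], z_axis=[0, 0, 1]
    )


REF_POINT = np.array([12.0, -170.0, 16.0])


class TestDecomposeError:
    def test_equal_poses_give_zero(self, frame):
        t = RigidTransform.from_rotvec((3.0, 5.0, -2.0), (1.0, 2.0, 3.0))
        rep = decompose_error(t, t, frame, REF_POINT, segment=SegmentName.TIBIA_25)
        assert rep.translation_error == pytest.approx(0.0, abs=1e-9)
        assert rep.rotation_error == pytest.approx(0.0, abs=1e-9)
        assert rep.euclidean_distance == pytest.approx(0.0, abs=1e-9)
        assert rep.euler_angle == pytest.approx(0.0, abs=1e-9)

    def test_pure_distal_translation_is_positive_lengthening(self, frame):
        t = RigidTransform(np.eye(3), (0.0, -2.0, 0.0))
        rep = decompose_error(t, RigidTransform.identity(), frame, REF_POINT,
                              segment=SegmentName.TIBIA_25)
        assert rep.translation_error == pytest.approx(2.0, abs=1e-9)
        assert rep.euclidean_distance == pytest.approx(2.0, abs=1e-9)
        assert rep.rotation_error == pytest.approx(0.0, abs=1e-9)
        assert rep.euler_angle == pytest.approx(0.0, abs=1e-9)

    def test_pure_axial_rotation(self, frame):
        t = RigidTransform.from_rotvec((0.0, 5.0, 0.0), center=REF_POINT)
        rep = decompose_error(t, RigidTransform.identity(), frame, REF_POINT,
                              segment=SegmentName.TIBIA_25)
        assert rep.rotation_error == pytest.approx(5.0, abs=1e-9)
        assert rep.euler_angle == pytest.approx(5.0, abs=1e-9)
        assert rep.translation_error == pytest.approx(0.0, abs=1e-9)
        assert rep.euclidean_distance == pytest.approx(0.0, abs=1e-9)

    def test_off_axis_rotation_has_no_twist(self, frame):
        t = RigidTransform.from_rotvec((8.0, 0.0, 0.0), center=REF_POINT)
        rep = decompose_error(t, RigidTransform.identity(), frame, REF_POINT,
                              segment=SegmentName.TIBIA_25)
        assert rep.euler_angle == pytest.approx(8.0, abs=1e-9)
        assert rep.rotation_error == pytest.approx(0.0, abs=1e-9)

    def test_report_invariants_enforced(self):
        with pytest.raises(ValueError):
            FibulaErrorReport(SegmentName.TIBIA_25, translation_error=3.0,
                              rotation_error=0.0, euclidean_distance=1.0,
                              euler_angle=0.0)
        with pytest.raises(ValueError):
            FibulaErrorReport(SegmentName.TIBIA_25, translation_error=0.0,
                              rotation_error=4.0, euclidean_distance=0.0,
                              euler_angle=1.0)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000), st.floats(0.5, 179.5))
    def test_euler_angle_equals_axis_angle_magnitude(self, seed, angle):
        rng = np.random.default_rng(seed)
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        frame = AnatomicalFrame(origin=np.zeros(3), x_axis=[1, 0, 0],
                                y_axis=[0, 1, 0], z_axis=[0, 0, 1])
        t = RigidTransform.from_rotvec(axis * angle, center=REF_POINT)
        rep = decompose_error(t, RigidTransform.identity(), frame, REF_POINT,
                              segment=SegmentName.TIBIA_25)
        assert rep.euler_angle == pytest.approx(angle, abs=1e-7)
        # swing-twist about y never exceeds the geodesic angle
        assert abs(rep.rotation_error) <= rep.euler_angle + 1e-9

    def test_swing_twist_projection_oracle(self):
        """Twist about y matches the quaternion-projection closed form for a
        composed swing+twist rotation."""
        from scipy.spatial.transform import Rotation

        twist = Rotation.from_euler("y", 9.0, degrees=True)
        swing = Rotation.from_euler("x", 14.0, degrees=True)
        r = (swing * twist).as_matrix()  # twist applied first
        assert swing_twist_angle_deg(r, [0.0, 1.0, 0.0]) == pytest.approx(9.0, abs=1e-9)


class TestReferencePose:
    def test_identical_regions_give_identity(self, zero_noise_pair):
        frame = build_anatomical_frame(zero_noise_pair.ipsi_tibia,
                                       zero_noise_pair.ipsi_fibula)
        idx = _distal_fibula_indices(zero_noise_pair.ipsi_fibula, frame)
        pts = zero_noise_pair.ipsi_fibula.vertices[idx]
        t = reference_pose(pts, pts, correspondence=True)
        assert np.abs(t.rotation - np.eye(3)).max() < 1e-9
        assert np.abs(t.translation).max() < 1e-9

    def test_recovers_injected_pose(self, zero_noise_pair):
        inj = inject_deformity(zero_noise_pair, translation_y=-2.0, rotation_y=5.0)
        frame = build_anatomical_frame(inj.ipsi_tibia, inj.ipsi_fibula)
        idx = _distal_fibula_indices(inj.ipsi_fibula, frame)
        mc = mirror_mesh(inj.contra_fibula, MIRROR_AXIS)
        t_ref = reference_pose(inj.ipsi_fibula.vertices[idx], mc.vertices[idx],
                               correspondence=True)
        # the reference corrects the injected displacement: +2 mm along y,
        # -5 deg about y (about the fragment centroid)
        truth = RigidTransform.from_rotvec(
            (0.0, -5.0, 0.0), (0.0, 2.0, 0.0),
            center=mc.vertices[idx].mean(axis=0),
        )
        ang, shift = transform_difference(t_ref, truth, inj.ipsi_fibula.vertices[idx].mean(axis=0))
        assert ang < 0.2
        assert shift < 0.2

    def test_role_swap_inverts(self, default_pair):
        frame = build_anatomical_frame(default_pair.ipsi_tibia, default_pair.ipsi_fibula)
        idx = _distal_fibula_indices(default_pair.ipsi_fibula, frame)
        ipsi = default_pair.ipsi_fibula.vertices[idx]
        mc = mirror_mesh(default_pair.contra_fibula, MIRROR_AXIS).vertices[idx]
        fwd = reference_pose(ipsi, mc)
        rev = reference_pose(mc, ipsi)
        ang, shift = transform_difference(fwd, rev.inverse(), ipsi.mean(axis=0))
        assert ang < 0.1
        assert shift < 0.1


class TestRestoreDistalFibula:
    def test_perfect_symmetry_restores_exactly(self, zero_noise_pair):
        """With an exactly mirror-symmetric pair the restored distal fibula
        coincides with the true (mirrored) location for every segment."""
        for seg in (SegmentName.TIBIA_25, SegmentName.TIBIA_50,
                    SegmentName.FIBULA_75, SegmentName.FIBULA_75_PLUS_TIBIA):
            res = restore_distal_fibula(
                zero_noise_pair.ipsi_tibia, zero_noise_pair.ipsi_fibula,
                zero_noise_pair.contra_tibia, zero_noise_pair.contra_fibula, seg,
            )
            # ground-truth pose of the mirrored distal fibula is the identity
            before = res.transform.inverse().apply(res.restored_distal_fibula)
            rms = np.sqrt(np.mean(np.sum(
                (res.restored_distal_fibula - before) ** 2, axis=1)))
            assert rms < 0.05, seg

    def test_tibia_segment_ignores_fibular_perturbation(self, zero_noise_pair):
        base = restore_distal_fibula(
            zero_noise_pair.ipsi_tibia, zero_noise_pair.ipsi_fibula,
            zero_noise_pair.contra_tibia, zero_noise_pair.contra_fibula,
            SegmentName.TIBIA_25,
        )
        inj = inject_deformity(zero_noise_pair, translation_y=-3.0, rotation_y=8.0)
        perturbed = restore_distal_fibula(
            inj.ipsi_tibia, inj.ipsi_fibula, inj.contra_tibia, inj.contra_fibula,
            SegmentName.TIBIA_25,
        )
        ang, shift = transform_difference(
            base.transform, perturbed.transform,
            zero_noise_pair.ipsi_fibula.vertices.mean(axis=0))
        assert ang < 0.1
        assert shift < 0.1

    def test_fibula_segment_feels_fibular_perturbation(self, zero_noise_pair):
        """The deformity's blend tail reaches into the proximal-75%-fibula
        region, so an *untrimmed* fibular registration is pulled by a strong
        injected displacement while the tibial one is not.  (Default
        trimming discards those correspondences, which is the point of it.)
        """
        from fibrestore import ICPParams

        inj = inject_deformity(zero_noise_pair, translation_y=-8.0, rotation_y=18.0)
        no_trim = ICPParams(trim_fraction=0.0)
        tib = restore_distal_fibula(
            inj.ipsi_tibia, inj.ipsi_fibula, inj.contra_tibia, inj.contra_fibula,
            SegmentName.TIBIA_25, icp_params=no_trim)
        fib = restore_distal_fibula(
            inj.ipsi_tibia, inj.ipsi_fibula, inj.contra_tibia, inj.contra_fibula,
            SegmentName.FIBULA_75, icp_params=no_trim)
        ang, shift = transform_difference(
            tib.transform, fib.transform, inj.ipsi_fibula.vertices.mean(axis=0))
        assert ang > 0.2 or shift > 0.2

    def test_evaluation_region_not_registrable(self, zero_noise_pair):
        with pytest.raises(ValueError):
            restore_distal_fibula(
                zero_noise_pair.ipsi_tibia, zero_noise_pair.ipsi_fibula,
                zero_noise_pair.contra_tibia, zero_noise_pair.contra_fibula,
                SegmentName.FIBULA_DISTAL_25,
            )


class TestMetricInvariance:
    def test_metrics_invariant_under_common_rigid_motion(self, zero_noise_pair):
        """Moving the whole ipsilateral pair rigidly must not change any
        metric: the anatomical frame moves with it."""
        from conftest import random_rotation

        inj = inject_deformity(zero_noise_pair, translation_y=-1.5, rotation_y=4.0)
        base = evaluate_pair(inj, segments=(SegmentName.TIBIA_25,))[SegmentName.TIBIA_25]

        rng = np.random.default_rng(21)
        r = random_rotation(rng)
        t = np.array([30.0, -12.0, 60.0])
        moved = type(inj)(
            ipsi_tibia=TriMesh(inj.ipsi_tibia.vertices @ r.T + t, inj.ipsi_tibia.faces),
            ipsi_fibula=TriMesh(inj.ipsi_fibula.vertices @ r.T + t, inj.ipsi_fibula.faces),
            contra_tibia=inj.contra_tibia,
            contra_fibula=inj.contra_fibula,
            truth=inj.truth,
            side=inj.side,
        )
        rep = evaluate_pair(moved, segments=(SegmentName.TIBIA_25,))[SegmentName.TIBIA_25]
        assert rep.translation_error == pytest.approx(base.translation_error, abs=0.05)
        assert rep.rotation_error == pytest.approx(base.rotation_error, abs=0.05)
        assert rep.euclidean_distance == pytest.approx(base.euclidean_distance, abs=0.05)
        assert rep.euler_angle == pytest.approx(base.euler_angle, abs=0.05)
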