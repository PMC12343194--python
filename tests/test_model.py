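"""Whole-body model assembly, constraints and initial guessing."""

import numpy as np
import pytest

from confkin.model import (
    ModelDefinition,
    build_model_from_static,
    default_static_pose,
    default_topology,
    initial_guess,
)
from confkin.natural_coords import rigid_body_constraints, transform_coordinates
from conftest import random_rotation


def perturbed_feasible_q(body, rng, scale=0.3):
    """Feasible non-static pose: rigidly transform the whole static pose."""
    R = random_rotation(rng)
    t = rng.uniform(-scale, scale, 3)
    Q = body.static_whole_q().copy()
    for i in range(body.n_segments):
        Q[body.seg_slice(i)] = transform_coordinates(Q[body.seg_slice(i)], R, t)
    return Q


class TestBuildFromStatic:
    def test_static_points_reproduced(self, body, static_pose):
        Q0 = body.static_whole_q()
        for name in body.point_names:
            assert np.linalg.norm(body.point_position(Q0, name) - static_pose[name]) <= 1e-10

    def test_constraints_vanish_at_static_pose(self, body):
        h = body.assemble_constraints(body.static_whole_q())
        assert np.max(np.abs(h)) <= 1e-10

    def test_segment_length_matches_anchor_distance(self, body, static_pose):
        thigh = body.templates[body.segment_index("thigh_r")]
        assert thigh.length == pytest.approx(
            np.linalg.norm(static_pose["hip_r"] - static_pose["knee_r"])
        )

    def test_rotated_static_pose_gives_same_calibration(self, static_pose, rng):
        R = random_rotation(rng)
        t = rng.uniform(-1, 1, 3)
        rotated = {k: R @ v + t for k, v in static_pose.items()}
        a = build_model_from_static(static_pose)
        b = build_model_from_static(rotated)
        for ta, tb in zip(a.templates, b.templates):
            assert ta.length == pytest.approx(tb.length, abs=1e-12)
            # orthonormal construction: dots vanish in both builds
            for d in (tb.dot_uv, tb.dot_uw, tb.dot_vw):
                assert abs(d) < 1e-12

    def test_missing_keypoint_reported_by_name(self, static_pose):
        broken = dict(static_pose)
        del broken["knee_l"]
        with pytest.raises(ValueError, match="knee_l"):
            build_model_from_static(broken)

    def test_zero_length_segment_rejected(self, static_pose):
        broken = dict(static_pose)
        broken["elbow_r"] = broken["shoulder_r"]
        with pytest.raises(ValueError, match="zero-length"):
            build_model_from_static(broken)


class TestConstraintStack:
    def test_row_count_matches_topology(self, body):
        # 12 segments, 6 spherical, 4 hinges, 1 free 6-DOF joint
        assert body.n_constraints == 12 * 6 + 6 * 3 + 4 * 5

    def test_rigid_blocks_equal_per_segment_residuals(self, body, rng):
        Q = body.static_whole_q() + 0.05 * rng.standard_normal(body.nq)
        h = body.assemble_constraints(Q)
        for i, tpl in enumerate(body.templates):
            block = rigid_body_constraints(Q[body.seg_slice(i)], tpl)
            assert np.allclose(h[6 * i : 6 * i + 6], block, atol=1e-12)

    def test_spherical_residual_equals_attachment_difference(self, body, rng):
        Q = body.static_whole_q().copy()
        j = body.joint_by_name("hip_r")
        # translate the thigh: residual = parent-side minus child-side center
        Q[body.seg_slice(j.child)][3:9:3] += 0.0  # no-op slice sanity
        Q[body.seg_slice(j.child)] = transform_coordinates(
            Q[body.seg_slice(j.child)], np.eye(3), np.array([0.01, 0.0, 0.0])
        )
        h = body.assemble_constraints(Q)
        r = 6 * body.n_segments
        for jj in body.joints:
            if jj.name == "hip_r":
                res = h[r : r + 3]
                break
            r += {"spherical": 3, "hinge": 5, "free6dof": 0}[jj.jtype]
        assert np.allclose(res, [-0.01, 0.0, 0.0], atol=1e-12)
        assert np.linalg.norm(res) == pytest.approx(0.01)

    def test_hinge_invariant_under_rotation_about_axis(self, body):
        from confkin.synth import _rot_about_point

        j = body.joint_by_name("knee_r")
        qp = body.static_q[j.parent]
        anchor = j.Np @ qp
        axis = j.Na @ qp
        Q = body.static_whole_q().copy()
        R, t = _rot_about_point(anchor, axis, np.radians(35.0))
        # rotate shank and foot together about the calibrated hinge axis
        for seg in ("shank_r", "foot_r"):
            i = body.segment_index(seg)
            Q[body.seg_slice(i)] = transform_coordinates(Q[body.seg_slice(i)], R, t)
        assert np.max(np.abs(body.assemble_constraints(Q))) <= 1e-10

    def test_off_axis_tilt_violates_hinge_rows(self, body):
        from confkin.synth import _rot_about_point

        j = body.joint_by_name("knee_r")
        qp = body.static_q[j.parent]
        anchor = j.Np @ qp
        Q = body.static_whole_q().copy()
        # tilt about the anterior axis instead of the hinge axis
        R, t = _rot_about_point(anchor, np.array([1.0, 0.0, 0.0]), np.radians(5.0))
        for seg in ("shank_r", "foot_r"):
            i = body.segment_index(seg)
            Q[body.seg_slice(i)] = transform_coordinates(Q[body.seg_slice(i)], R, t)
        h = body.assemble_constraints(Q)
        assert np.max(np.abs(h)) > 1e-4

    def test_jacobian_rank_constant_across_feasible_poses(self, body, rng):
        ranks = set()
        for _ in range(5):
            Q = perturbed_feasible_q(body, rng)
            ranks.add(np.linalg.matrix_rank(body.constraint_jacobian(Q)))
        assert ranks == {body.n_constraints}

    def test_mobility_matches_topology(self, body):
        # 6 (pelvis) + 6 (free torso) + 2*(3 hip + 1 knee + 3 ankle)
        # + 2*(3 shoulder + 1 elbow) = 34
        J = body.constraint_jacobian(body.static_whole_q())
        assert body.nq - np.linalg.matrix_rank(J) == 34


class TestInitialGuess:
    def test_static_points_give_static_anchors(self, body, static_pose):
        Q = initial_guess(static_pose, body)
        assert np.allclose(Q, body.static_whole_q(), atol=1e-12)

    def test_translation_equivariance(self, body, static_pose):
        t = np.array([0.3, -0.2, 0.1])
        Q = initial_guess({k: v + t for k, v in static_pose.items()}, body)
        Q0 = body.static_whole_q()
        for i in range(body.n_segments):
            s, s0 = Q[body.seg_slice(i)], Q0[body.seg_slice(i)]
            assert np.allclose(s[3:6], s0[3:6] + t, atol=1e-12)
            assert np.allclose(s[0:3], s0[0:3], atol=1e-12)

    def test_perturbed_points_give_small_residual(self, body, static_pose, rng):
        noisy = {k: v + rng.normal(0, 0.01, 3) for k, v in static_pose.items()}
        Q = initial_guess(noisy, body)
        h = body.assemble_constraints(Q)
        assert 0 < np.linalg.norm(h) < 0.1

    def test_missing_segment_falls_back_to_parent_attachment(self, body, static_pose):
        partial = {k: v for k, v in static_pose.items() if not k.endswith("_l") or "hip" in k}
        Q = initial_guess(partial, body)
        # left forearm was unresolvable: it must still be a valid 12-vector
        # rigidly consistent with its static shape
        i = body.segment_index("forearm_l")
        tpl = body.templates[i]
        assert np.max(np.abs(rigid_body_constraints(Q[body.seg_slice(i)], tpl))) < 1e-8

    def test_totally_empty_input_rejected(self, body):
        with pytest.raises(ValueError):
            initial_guess({}, body)


class TestSerialization:
    def test_json_round_trip(self, body, tmp_path, rng):
        path = tmp_path / "model.json"
        body.to_json(path)
        loaded = ModelDefinition.from_json(path)
        assert loaded.segment_names == body.segment_names
        assert loaded.n_constraints == body.n_constraints
        Q = perturbed_feasible_q(body, rng)
        assert np.allclose(
            loaded.assemble_constraints(Q), body.assemble_constraints(Q), atol=1e-12
        )
        assert np.allclose(loaded.point_positions(Q), body.point_positions(Q), atol=1e-12)

    def test_schema_version_checked(self, body):
        doc = body.to_json()
        doc["schema_version"] = 99
        with pytest.raises(ValueError):
            ModelDefinition.from_json(doc)


def test_custom_reduced_topology_constraint_count():
    """A one-leg chain: pelvis + thigh + shank, spherical hip, hinge knee."""
    from confkin.model import JointSpec, SegmentSpec, Topology

    topo = Topology(
        segments=[
            SegmentSpec("pelvis", "hip_r", "hip_l", ("hip_r", "hip_l")),
            SegmentSpec("thigh_r", "hip_r", "knee_r", ("knee_r",), parent="pelvis"),
            SegmentSpec("shank_r", "knee_r", "ankle_r", ("ankle_r",), parent="thigh_r"),
        ],
        joints=[
            JointSpec("hip_r", "spherical", "pelvis", "thigh_r", "hip_r"),
            JointSpec("knee_r", "hinge", "thigh_r", "shank_r", "knee_r"),
        ],
    )
    model = build_model_from_static(default_static_pose(), topo)
    assert model.n_constraints == 3 * 6 + 3 + 5
    assert model.nq == 36
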