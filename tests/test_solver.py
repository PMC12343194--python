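"""MKO objectives, per-frame solving and the preprocessing chain."""

import numpy as np
import pytest

from confkin.camera import project
from confkin.heatmap import GaussianModel, gaussian_confidence
from confkin.model import initial_guess
from confkin.solver import (
    ObjectiveSpec,
    SolverOptions,
    confidence_objective,
    distance_objective,
    preprocess_keypoints,
    solve_frame,
    solve_sequence,
)


class TestDistanceObjective:
    def test_zero_at_matching_points(self, body):
        Q = body.static_whole_q()
        spec = ObjectiveSpec(
            mode="distance",
            points={n: body.point_position(Q, n) for n in body.point_names},
        )
        assert distance_objective(Q, spec, body) == pytest.approx(0.0, abs=1e-20)

    def test_single_offset_point(self, body):
        Q = body.static_whole_q()
        pts = {n: body.point_position(Q, n) for n in body.point_names}
        pts["wrist_r"] = pts["wrist_r"] + np.array([0.1, 0.0, 0.0])
        spec = ObjectiveSpec(mode="distance", points=pts)
        assert distance_objective(Q, spec, body) == pytest.approx(0.01)

    def test_matches_term_by_term_oracle(self, body, rng):
        Q = body.static_whole_q() + 0.02 * rng.standard_normal(body.nq)
        pts = {n: rng.uniform(-1, 1, 3) for n in body.point_names[::2]}
        spec = ObjectiveSpec(mode="distance", points=pts)
        expected = sum(
            np.sum((pts[n] - body.point_position(Q, n)) ** 2) for n in pts
        )
        assert distance_objective(Q, spec, body) == pytest.approx(expected)


class TestConfidenceObjective:
    def build_perfect_spec(self, body, cams, A=1.0):
        Q = body.static_whole_q()
        gmap = {}
        for k, cam in enumerate(cams):
            for n in body.point_names:
                px = project(body.point_position(Q, n), cam)
                gmap[(n, k)] = GaussianModel(px, A, 6.0)
        return ObjectiveSpec(mode="confidence", gaussians=gmap, cameras=list(cams))

    def test_perfect_projection_value(self, body, rig):
        spec = self.build_perfect_spec(body, rig, A=1.0)
        val = confidence_objective(body.static_whole_q(), spec, body)
        mn = len(body.point_names) * len(rig)
        assert val == pytest.approx(mn / (1 + 1e-6))

    def test_term_count_drops_with_missing_camera(self, body, rig):
        spec = self.build_perfect_spec(body, rig)
        only0 = {k: g for k, g in spec.gaussians.items() if k[1] == 0}
        spec0 = ObjectiveSpec(mode="confidence", gaussians=only0, cameras=list(rig))
        val = confidence_objective(body.static_whole_q(), spec0, body)
        assert val == pytest.approx(len(body.point_names) / (1 + 1e-6))

    def test_matches_brute_force_composition(self, body, rig, rng):
        spec = self.build_perfect_spec(body, rig, A=0.8)
        Q = body.static_whole_q() + 0.01 * rng.standard_normal(body.nq)
        expected = 0.0
        for (n, k), g in spec.gaussians.items():
            c = gaussian_confidence(g, project(body.point_position(Q, n), rig[k]))
            expected += 1.0 / (c + 1e-6)
        assert confidence_objective(Q, spec, body) == pytest.approx(expected, rel=1e-9)

    def test_neg_sum_variant(self, body, rig):
        spec = self.build_perfect_spec(body, rig, A=0.8)
        opts = SolverOptions(objective_form="neg-sum")
        val = confidence_objective(body.static_whole_q(), spec, body, opts)
        assert val == pytest.approx(-0.8 * len(spec.gaussians))

    def test_gradient_matches_finite_differences(self, body, rig, rng):
        from confkin.solver import _confidence_value_grad

        spec = self.build_perfect_spec(body, rig, A=0.9)
        opts = SolverOptions()
        Q = body.static_whole_q() + 0.01 * rng.standard_normal(body.nq)
        f, g = _confidence_value_grad(Q, spec, body, opts)
        idx = rng.choice(body.nq, size=12, replace=False)
        for i in idx:
            dq = np.zeros(body.nq)
            dq[i] = 1e-6
            fd = (
                _confidence_value_grad(Q + dq, spec, body, opts)[0]
                - _confidence_value_grad(Q - dq, spec, body, opts)[0]
            ) / 2e-6
            assert g[i] == pytest.approx(fd, rel=1e-4, abs=1e-5)

    def test_no_terms_rejected(self, body, rig):
        spec = ObjectiveSpec(mode="confidence", gaussians={}, cameras=list(rig))
        with pytest.raises(ValueError):
            confidence_objective(body.static_whole_q(), spec, body)


class TestSolveFrame:
    def test_distance_recovery_from_feasible_pose(self, small_scene):
        body = small_scene.model
        Qt = small_scene.Q[3]
        spec = ObjectiveSpec(
            mode="distance",
            points={n: body.point_position(Qt, n) for n in body.point_names},
        )
        sol = solve_frame(spec, small_scene.Q[2], body, SolverOptions(ftol=1e-13))
        assert sol.converged
        assert sol.max_violation <= 1e-6
        err = np.max(
            np.linalg.norm(body.point_positions(sol.Q) - body.point_positions(Qt).reshape(-1, 3), axis=1)
        )
        assert err < 1e-4

    def test_feasibility_beats_contradictory_data(self, body):
        # exact points violating rigidity: solver must stay feasible with
        # a nonzero objective rather than tear the model apart
        Q = body.static_whole_q()
        pts = {n: body.point_position(Q, n) for n in body.point_names}
        pts["knee_r"] = pts["knee_r"] + np.array([0.0, 0.0, 0.15])  # stretch the thigh
        spec = ObjectiveSpec(mode="distance", points=pts)
        sol = solve_frame(spec, Q, body)
        assert sol.converged
        assert sol.max_violation <= 1e-6
        assert sol.objective > 1e-4

    def test_failure_reported_not_raised(self, body):
        spec = ObjectiveSpec(
            mode="distance",
            points={n: body.point_position(body.static_whole_q(), n) for n in body.point_names},
        )
        sol = solve_frame(spec, body.static_whole_q(), body, SolverOptions(max_iter=1))
        assert sol.status in ("failed", "converged")  # never an exception
        if sol.status == "failed":
            assert sol.message


class TestSolveSequence:
    def test_all_visible_sequence_fully_converges(self, small_scene, small_scene_solutions):
        assert all(s.converged for s in small_scene_solutions)
        for f, s in enumerate(small_scene_solutions):
            err = np.max(
                np.linalg.norm(
                    small_scene.model.point_positions(s.Q) - small_scene.truth_points[f], axis=1
                )
            )
            assert err < 5e-3

    def test_single_frame_equals_solve_frame(self, small_scene):
        spec = small_scene.confidence_specs()[0]
        seq = solve_sequence([spec], small_scene.model)
        from confkin.solver import _first_guess

        one = solve_frame(spec, _first_guess(spec, small_scene.model), small_scene.model)
        assert len(seq) == 1
        assert seq[0].status == one.status
        assert np.allclose(seq[0].Q, one.Q, atol=1e-9)

    def test_distance_mode_skips_frames_with_missing_points(self, small_scene):
        specs = small_scene.distance_specs()
        specs[2].points["neck"] = None
        sols = solve_sequence(specs, small_scene.model)
        assert sols[2].status == "skipped_missing_data"
        assert "neck" in sols[2].message
        assert sols[1].converged and sols[3].converged

    def test_objective_signs(self, small_scene, small_scene_solutions):
        dsols = solve_sequence(small_scene.distance_specs(), small_scene.model)
        for s in dsols:
            if s.converged:
                assert s.objective >= 0.0
        for s in small_scene_solutions:
            assert s.objective > 0.0

    def test_converged_frames_satisfy_constraints_and_direct_frames(
        self, small_scene, small_scene_solutions
    ):
        body = small_scene.model
        bounds = body.determinant_bounds()
        for s in small_scene_solutions:
            assert np.max(np.abs(body.assemble_constraints(s.Q))) <= 1e-6
            assert np.all(body.frame_determinants(s.Q) >= bounds)


class TestPreprocess:
    def make_series(self, F=30):
        xs = np.arange(F, dtype=float)
        series = np.stack([100 + xs, 200 + 2 * xs, np.full(F, 0.9)], axis=1)
        return series

    def test_short_gap_linearly_filled(self):
        s = self.make_series()
        s[5:8, 2] = 0.0
        filled, valid = preprocess_keypoints(s)
        assert valid[5:8].all()
        assert np.allclose(filled[5:8, 0], [105, 106, 107])
        assert np.allclose(filled[5:8, 1], [210, 212, 214])
        assert np.allclose(filled[5:8, 2], 0.9)

    def test_long_gap_stays_invalid(self):
        s = self.make_series()
        s[5:17, 2] = 0.0  # 12 frames >= the 10-frame limit
        filled, valid = preprocess_keypoints(s)
        assert not valid[5:17].any()
        assert valid[:5].all() and valid[17:].all()

    def test_exactly_ten_frames_stays_invalid(self):
        s = self.make_series()
        s[5:15, 2] = 0.0
        _, valid = preprocess_keypoints(s)
        assert not valid[5:15].any()

    def test_boundary_gaps_stay_invalid(self):
        s = self.make_series()
        s[:3, 2] = 0.0
        s[-2:, 2] = 0.0
        _, valid = preprocess_keypoints(s)
        assert not valid[:3].any()
        assert not valid[-2:].any()

    def test_low_confidence_invalidated_at_threshold(self):
        s = self.make_series()
        s[10, 2] = 0.05  # at the threshold: invalid (strictly greater required)
        s[11, 2] = 0.051
        s[20:23, 2] = 0.02
        filled, valid = preprocess_keypoints(s)
        assert valid[11]
        # frame 10 was refilled by interpolation (gap of 1); its confidence
        # is the mean of the flanking confidences
        assert valid[10] and filled[10, 2] == pytest.approx(0.5 * (0.9 + 0.051))
        assert valid[20:23].all()  # gap of 3, refilled

    def test_multi_keypoint_array_shape(self):
        F, m = 25, 4
        series = np.zeros((F, m, 3))
        series[:, :, 2] = 0.8
        series[3:6, 1, 2] = 0.0
        filled, valid = preprocess_keypoints(series)
        assert filled.shape == (F, m, 3)
        assert valid.shape == (F, m)
        assert valid[3:6, 1].all()
        assert valid.all()


def test_initial_guess_feeds_solver(small_scene):
    body = small_scene.model
    spec = small_scene.distance_specs()[0]
    pts = {k: v for k, v in spec.points.items() if v is not None}
    Q = initial_guess(pts, body)
    assert Q.shape == (body.nq,)
    # near-feasible: small but generally nonzero residual
    assert np.linalg.norm(body.assemble_constraints(Q)) < 0.1
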