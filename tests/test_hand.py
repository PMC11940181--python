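"""Hand skeleton assembly, kinematics, spring-damper dynamics, clinical
scoring and grasp force distribution."""

import numpy as np
import pytest

from rebiom.fixtures import gen_skeleton
from rebiom.hand import (
    NMM_PER_GMM2,
    PoseTrajectory,
    build_skeleton,
    default_fma_templates,
    distribute_grip_forces,
    enumerate_dof,
    fma_pose_battery,
    forward_kinematics,
    grasp_contact_forces,
    kapandji_score,
    kapandji_targets,
    scale_skeleton,
    simulate_pose,
    spring_energy,
)


class TestAssembly:
    def test_census(self, skeleton):
        assert len(skeleton.bones) == 27
        groups = {}
        for b in skeleton.bones.values():
            groups[b.group] = groups.get(b.group, 0) + 1
        assert groups == {
            "carpal": 8, "metacarpal": 5, "proximal": 5, "middle": 4, "distal": 5,
        }
        kinds = [j.kind for j in skeleton.joints]
        assert kinds.count("revolute") == 9
        assert kinds.count("universal") == 6
        assert len(skeleton.joints) == 15

    def test_numbering_unique_and_grouped(self, skeleton):
        numbers = sorted(b.number for b in skeleton.bones.values())
        assert numbers == list(range(1, 28))
        carpals = sorted(
            b.number for b in skeleton.bones.values() if b.group == "carpal"
        )
        metacarpals = sorted(
            b.number for b in skeleton.bones.values() if b.group == "metacarpal"
        )
        assert carpals == list(range(1, 9))
        assert metacarpals == list(range(9, 14))

    def test_missing_bone_raises(self):
        fx = gen_skeleton(seed=0)
        fx.bones = [b for b in fx.bones if b.name != "distal_small"]
        with pytest.raises(ValueError):
            build_skeleton(fx)

    def test_duplicate_number_raises(self):
        fx = gen_skeleton(seed=0)
        fx.bones[3].number = fx.bones[2].number
        with pytest.raises(ValueError, match="duplicate"):
            build_skeleton(fx)

    def test_dof_counts(self, skeleton):
        assert enumerate_dof(skeleton, "model") == 21
        assert enumerate_dof(mode="anatomical") == 27

    def test_dof_recount_without_thumb(self, skeleton):
        thumb_dof = sum(j.dof for j in skeleton.joints if "thumb" in j.name)
        rest = sum(j.dof for j in skeleton.joints if "thumb" not in j.name)
        assert thumb_dof == 5
        assert rest == 21 - thumb_dof


class TestScaling:
    def test_volume_mass_inertia_laws(self, skeleton):
        big = scale_skeleton(skeleton, 2.0)
        for name in ("metacarpal_index", "distal_thumb"):
            v0 = skeleton.bones[name].mesh.trimesh.volume
            v1 = big.bones[name].mesh.trimesh.volume
            assert v1 == pytest.approx(8 * v0, rel=1e-9)
            assert big.bones[name].mass == pytest.approx(
                8 * skeleton.bones[name].mass, rel=1e-9
            )
            np.testing.assert_allclose(
                big.bones[name].inertia, 32 * skeleton.bones[name].inertia, rtol=1e-9
            )

    def test_round_trip_identity(self, skeleton):
        back = scale_skeleton(scale_skeleton(skeleton, 2.0), 0.5)
        for name, b in skeleton.bones.items():
            np.testing.assert_allclose(
                back.bones[name].mesh.vertices, b.mesh.vertices, atol=1e-9
            )

    def test_fingertip_span_scales(self, skeleton):
        q = np.zeros(skeleton.n_axes)
        _, tips0 = forward_kinematics(skeleton, q)
        _, tips1 = forward_kinematics(scale_skeleton(skeleton, 2.0), q)
        span0 = np.linalg.norm(tips0["thumb"] - tips0["small"])
        span1 = np.linalg.norm(tips1["thumb"] - tips1["small"])
        assert span1 == pytest.approx(2 * span0, rel=1e-9)

    def test_bad_factor(self, skeleton):
        with pytest.raises(ValueError):
            scale_skeleton(skeleton, 0.0)


class TestKinematics:
    def test_rest_pose_identity(self, skeleton):
        T, _ = forward_kinematics(skeleton, np.zeros(skeleton.n_axes))
        for name, M in T.items():
            np.testing.assert_allclose(M, np.eye(4), atol=1e-12)

    def test_single_dip_moves_only_distal(self, skeleton):
        q = np.zeros(skeleton.n_axes)
        idx = skeleton.axis_index("dip_index")
        q[idx] = 0.6
        T, _ = forward_kinematics(skeleton, q)
        for name, M in T.items():
            if name == "distal_index":
                assert not np.allclose(M, np.eye(4))
                j = skeleton.joint("dip_index")
                # rotation magnitude about the DIP axis equals the angle
                tr = np.trace(M[:3, :3])
                assert np.arccos((tr - 1) / 2) == pytest.approx(0.6, abs=1e-9)
                # the COR stays fixed
                np.testing.assert_allclose(
                    M[:3, :3] @ j.cor + M[:3, 3], j.cor, atol=1e-9
                )
            else:
                np.testing.assert_allclose(M, np.eye(4), atol=1e-12)

    def test_chain_composition_matrix_oracle(self, skeleton):
        from rebiom.hand import _joint_transform

        q = np.zeros(skeleton.n_axes)
        angles = {"mcp_index": np.array([0.5, 0.1]), "pip_index": np.array([0.7]),
                  "dip_index": np.array([0.3])}
        for jname, val in angles.items():
            j = skeleton.joint(jname)
            q[skeleton.axis_index(jname)] = val[0]
            if j.dof == 2:
                q[skeleton.axis_index(jname, "abd")] = val[1]
        T, _ = forward_kinematics(skeleton, q)
        # brute-force product of per-joint matrices down the chain
        M = np.eye(4)
        for jname in ("mcp_index", "pip_index", "dip_index"):
            M = M @ _joint_transform(skeleton.joint(jname), angles[jname])
        np.testing.assert_allclose(T["distal_index"], M, atol=1e-12)

    def test_out_of_limit_raises(self, skeleton):
        q = np.zeros(skeleton.n_axes)
        q[skeleton.axis_index("dip_index")] = 3.0
        with pytest.raises(ValueError, match="dip_index"):
            forward_kinematics(skeleton, q)


class TestDynamics:
    def test_equilibrium_stays(self, skeleton):
        traj = simulate_pose(skeleton, np.zeros(skeleton.n_axes), 0.2, 1e-3)
        np.testing.assert_allclose(traj.angles, 0.0, atol=1e-12)

    def test_steady_state_torque_over_stiffness(self, skeleton):
        tau = np.zeros(skeleton.n_axes)
        tau[0] = 10.0
        traj = simulate_pose(skeleton, tau, 2.0, 1e-3, sample_every=20)
        expected = 10.0 / skeleton.joints[0].stiffness
        assert traj.angles[-1, 0] == pytest.approx(expected, rel=1e-3)

    def test_step_response_matches_damped_oscillator(self):
        """Closed-form underdamped oscillator oracle, error < 1e-4 rad."""
        skel = build_skeleton(gen_skeleton(seed=0), stiffness=50.0, damping=0.05)
        tau = np.zeros(skel.n_axes)
        tau[0] = 10.0
        traj = simulate_pose(skel, tau, 1.0, 1e-4)
        j = skel.joints[0]
        I = j.inertia[0] / NMM_PER_GMM2
        k, c = j.stiffness, j.damping
        wn = np.sqrt(k / I)
        zeta = c / (2 * np.sqrt(k * I))
        wd = wn * np.sqrt(1 - zeta**2)
        t = traj.times
        analytic = (10.0 / k) * (
            1 - np.exp(-zeta * wn * t)
            * (np.cos(wd * t) + zeta * wn / wd * np.sin(wd * t))
        )
        assert np.abs(traj.angles[:, 0] - analytic).max() < 1e-4

    def test_energy_nonincreasing_with_zero_torque(self, skeleton):
        q0 = skeleton.rest_vector().copy()
        q0[0] += 0.5
        q0[3] += 0.3
        traj = simulate_pose(
            skeleton, np.zeros(skeleton.n_axes), 1.0, 1e-3, q0=q0, sample_every=5
        )
        E = spring_energy(skeleton, traj)
        assert np.all(np.diff(E) <= 1e-9 * max(E[0], 1.0))

    def test_limits_respected_within_penalty_layer(self, skeleton):
        """Large torque pushes into the limit but the penalty keeps the
        excursion under 0.5 degrees."""
        tau = np.zeros(skeleton.n_axes)
        idx = skeleton.axis_index("dip_index")
        tau[idx] = 200.0  # would give 4 rad unconstrained
        traj = simulate_pose(skeleton, tau, 0.5, 2e-5, sample_every=100)
        hi = skeleton.joint("dip_index").limits[0, 1]
        assert traj.angles[:, idx].max() <= hi + np.deg2rad(0.5)

    def test_divergence_detected(self, skeleton):
        q0 = skeleton.rest_vector().copy()
        q0[0] += 0.5  # perturbed start at a grossly unstable step size
        with pytest.raises(RuntimeError, match="dt"):
            simulate_pose(skeleton, np.zeros(skeleton.n_axes), 0.5, 0.5, q0=q0)

    def test_bad_dt(self, skeleton):
        with pytest.raises(ValueError):
            simulate_pose(skeleton, np.zeros(skeleton.n_axes), 1.0, 0.0)


class TestKapandji:
    def test_rest_trajectory_scores_zero(self, skeleton):
        rest = PoseTrajectory(
            times=np.array([0.0, 1.0]),
            angles=np.zeros((2, skeleton.n_axes)),
            axis_names=skeleton.axis_names,
        )
        score, flags = kapandji_score(skeleton, rest)
        assert score == 0
        assert not any(flags)

    def test_reference_bundle_scores_ten(self, skeleton, bundle):
        score, flags = kapandji_score(skeleton, bundle.kapandji)
        assert score == 10
        assert all(flags)

    def test_partial_trajectory_scores_partial(self, skeleton, bundle):
        """A trajectory reaching only targets 1-4 scores exactly 4."""
        frames = [np.zeros(skeleton.n_axes)] + bundle.kapandji_poses[:4]
        traj = PoseTrajectory(
            times=np.arange(len(frames), dtype=float),
            angles=np.asarray(frames),
            axis_names=skeleton.axis_names,
        )
        score, flags = kapandji_score(skeleton, traj)
        assert score == 4

    def test_monotone_under_target_removal(self, skeleton, bundle):
        """Dropping reached positions from the trajectory never raises the
        score."""
        full, _ = kapandji_score(skeleton, bundle.kapandji)
        for skip in (9, 5, 2):
            frames = [np.zeros(skeleton.n_axes)] + [
                p for i, p in enumerate(bundle.kapandji_poses) if i != skip - 1
            ]
            traj = PoseTrajectory(
                times=np.arange(len(frames), dtype=float),
                angles=np.asarray(frames),
                axis_names=skeleton.axis_names,
            )
            score, flags = kapandji_score(skeleton, traj)
            assert score <= full
            assert score == skip - 1

    def test_targets_count(self, skeleton):
        assert len(kapandji_targets(skeleton)) == 10


class TestFMA:
    def test_reference_poses_pass_all(self, skeleton, bundle):
        results = fma_pose_battery(skeleton, bundle.fma_poses)
        assert sum(results.values()) == 7

    def test_zero_pose_only_full_extension(self, skeleton):
        zero = np.zeros(skeleton.n_axes)
        poses = {name: zero for name in default_fma_templates()}
        results = fma_pose_battery(skeleton, poses)
        assert results["full_extension"]
        assert sum(results.values()) == 1

    def test_band_violation_fails(self, skeleton, bundle):
        pose = bundle.fma_poses["cylindrical_grip"].copy()
        idx = skeleton.axis_index("mcp_index")
        lo, hi = default_fma_templates()["cylindrical_grip"][("mcp_index", "flex")]
        pose[idx] = lo - 2 * (hi - lo)
        results = fma_pose_battery(skeleton, {"cylindrical_grip": pose})
        assert not results["cylindrical_grip"]

    def test_unknown_position_raises(self, skeleton):
        with pytest.raises(KeyError, match="unknown"):
            fma_pose_battery(skeleton, {"fist_bump": np.zeros(skeleton.n_axes)})


class TestGraspForces:
    def _symmetric_contacts(self, n=5, lat=0.6):
        ang = np.linspace(0, 2 * np.pi, n, endpoint=False)
        pts = np.column_stack(
            [np.cos(lat) * np.cos(ang), np.cos(lat) * np.sin(ang),
             np.full(n, np.sin(lat))]
        )
        return pts, -pts

    def test_symmetric_five_contacts_equal_forces(self):
        pts, normals = self._symmetric_contacts()
        f, _ = distribute_grip_forces(pts, normals, 475.0)
        np.testing.assert_allclose(f, 95.0, atol=1e-6)

    def test_total_conserved(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(6, 3))
        normals = -pts
        f, _ = distribute_grip_forces(pts, normals, 321.0)
        assert f.sum() == pytest.approx(321.0, abs=1e-6)
        assert np.all(f >= 0)

    def test_scale_consistency(self):
        rng = np.random.default_rng(5)
        pts = rng.normal(size=(4, 3))
        normals = -pts / np.linalg.norm(pts, axis=1, keepdims=True)
        f1, _ = distribute_grip_forces(pts, normals, 100.0)
        f2, _ = distribute_grip_forces(pts, normals, 200.0)
        np.testing.assert_allclose(f2, 2 * f1, atol=1e-4)

    def test_residual_matches_grid_search_oracle(self):
        """The SLSQP optimum matches a brute-force simplex grid search."""
        rng = np.random.default_rng(8)
        pts = rng.normal(size=(4, 3))
        normals = -pts / np.linalg.norm(pts, axis=1, keepdims=True)
        total = 10.0
        _, residual = distribute_grip_forces(pts, normals, total)
        center = pts.mean(axis=0)
        lever = np.linalg.norm(pts - center, axis=1).mean()
        W = np.vstack([normals.T, (np.cross(pts - center, normals) / lever).T])
        best = np.inf
        n_grid = 20
        for i in range(n_grid + 1):
            for j in range(n_grid + 1 - i):
                for k in range(n_grid + 1 - i - j):
                    w = np.array([i, j, k, n_grid - i - j - k]) / n_grid
                    best = min(best, np.linalg.norm(W @ (w * total)))
        assert residual <= best + 1e-6 * total

    def test_too_few_contacts(self):
        with pytest.raises(ValueError, match="3 contacts"):
            distribute_grip_forces(np.zeros((2, 3)), np.ones((2, 3)), 10.0)

    def test_grasp_from_pose(self, skeleton, bundle):
        forces = grasp_contact_forces(
            skeleton, bundle.grasp_pose, *bundle.grasp_sphere, total=475.0
        )
        assert len(forces.contacts) >= 3
        total = sum(c[3] for c in forces.contacts)
        assert total == pytest.approx(475.0, abs=1e-6)
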