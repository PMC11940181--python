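"""Reference pose trajectories for the hand model.

Builds joint-angle trajectories that realise named postures within the
joint limits: the Kapandji opposition ladder (thumb tip brought to each
of the ten targets by bounded inverse kinematics over the thumb chain
and the target finger), the seven FMA positions (template band centres),
per-finger pinches, gesture poses, and a spherical grasp.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .hand import (
    HandSkeleton,
    PoseTrajectory,
    default_fma_templates,
    forward_kinematics,
    kapandji_targets,
    split_angles,
)


@dataclass
class TrajectoryBundle:
    kapandji: PoseTrajectory
    fma_poses: dict[str, np.ndarray]
    pinch: dict[str, np.ndarray]
    gestures: dict[str, np.ndarray]
    grasp_pose: np.ndarray
    grasp_sphere: tuple[np.ndarray, float]  # center, diameter
    kapandji_poses: list[np.ndarray] = field(default_factory=list)


def _axis_columns(skel: HandSkeleton, joints: list[str]) -> list[int]:
    cols = []
    for jname in joints:
        j = skel.joint(jname)
        cols.append(skel.axis_index(jname, "flex"))
        if j.dof == 2:
            cols.append(skel.axis_index(jname, "abd"))
    return cols


_THUMB_JOINTS = ["cmc_thumb", "mcp_thumb", "ip_thumb"]
_FINGER_JOINTS = {
    d: [f"mcp_{d}", f"pip_{d}", f"dip_{d}"]
    for d in ("index", "middle", "ring", "small")
}


def _solve_reach(
    skel: HandSkeleton,
    target_bone: str,
    target_point: np.ndarray,
    free_joints: list[str],
    q_init: np.ndarray,
    tol: float,
    seeds: int = 6,
) -> np.ndarray:
    """Bounded IK: bring the thumb tip onto a bone-attached target point."""
    cols = _axis_columns(skel, free_joints)
    limits = skel.limits_vector()
    lo, hi = limits[cols, 0], limits[cols, 1]
    thumb = skel.bones["distal_thumb"]

    def residual(x):
        q = q_init.copy()
        q[cols] = x
        transforms, _ = forward_kinematics(skel, q, check_limits=False)
        Tt = transforms["distal_thumb"]
        tip = Tt[:3, :3] @ thumb.tip_point + Tt[:3, 3]
        Tb = transforms[target_bone]
        tgt = Tb[:3, :3] @ target_point + Tb[:3, 3]
        return tip - tgt

    rng = np.random.default_rng(1234)
    best = None
    best_cost = np.inf
    starts = [0.35 * (lo + hi)]
    for _ in range(seeds - 1):
        starts.append(lo + rng.random(len(cols)) * (hi - lo))
    for x0 in starts:
        sol = least_squares(residual, np.clip(x0, lo, hi), bounds=(lo, hi),
                            xtol=1e-10, ftol=1e-12, gtol=1e-12)
        if sol.cost < best_cost:
            best_cost = sol.cost
            best = sol.x
        if np.linalg.norm(residual(best)) <= 0.25 * tol:
            break
    q = q_init.copy()
    q[cols] = best
    miss = np.linalg.norm(residual(best))
    if miss > tol:
        raise ValueError(
            f"target on {target_bone} unreachable: closest approach {miss:.2f} mm"
        )
    return q


def _smooth_segments(poses: list[np.ndarray], steps: int = 8) -> np.ndarray:
    """Concatenate poses with smoothstep interpolation between them."""
    frames = [poses[0]]
    for a, b in zip(poses[:-1], poses[1:]):
        for s in np.linspace(0, 1, steps + 1)[1:]:
            w = s * s * (3 - 2 * s)
            frames.append((1 - w) * a + w * b)
    return np.asarray(frames)


def _clip_to_limits(skel: HandSkeleton, q: np.ndarray) -> np.ndarray:
    lim = skel.limits_vector()
    return np.clip(q, lim[:, 0], lim[:, 1])


def _pose_from_bands(skel: HandSkeleton, bands: dict) -> np.ndarray:
    q = skel.rest_vector().copy()
    for (joint, axis), (lo, hi) in bands.items():
        q[skel.axis_index(joint, axis)] = 0.5 * (lo + hi)
    return _clip_to_limits(skel, q)


def gen_trajectories(
    skel: HandSkeleton, kapandji_tolerance: float = 5.0
) -> TrajectoryBundle:
    """Reference trajectory bundle: Kapandji ladder, FMA poses, pinches,
    gesture poses and a spherical grasp, all within joint limits.

    The Kapandji trajectory is constructed to touch every target: for each
    position the thumb chain (and, for finger-mounted targets, that
    finger's joints) is solved by bounded least-squares IK; failure to
    close within the tolerance raises with the offending position.
    """
    rest = skel.rest_vector().copy()
    targets = kapandji_targets(skel)
    target_fingers = [
        "index", "index", "index", "middle", "ring",
        "small", "small", "small", "small", "small",
    ]
    poses = [rest]
    kap_poses = []
    for (bone_name, point), finger in zip(targets, target_fingers):
        free = _THUMB_JOINTS + _FINGER_JOINTS[finger]
        q = _solve_reach(
            skel, bone_name, point, free, rest, tol=0.8 * kapandji_tolerance
        )
        kap_poses.append(q)
        poses.append(q)
        poses.append(rest)
    frames = _smooth_segments(poses, steps=6)
    frames = np.array([_clip_to_limits(skel, f) for f in frames])
    times = np.arange(len(frames)) * 0.05
    kapandji = PoseTrajectory(
        times=times, angles=frames, axis_names=skel.axis_names
    )

    templates = default_fma_templates()
    fma_poses = {
        name: _pose_from_bands(skel, bands) for name, bands in templates.items()
    }

    pinch = {}
    for finger in ("index", "middle", "ring", "small"):
        tip_bone = f"distal_{finger}"
        tip_point = skel.bones[tip_bone].tip_point
        pinch[finger] = _solve_reach(
            skel, tip_bone, tip_point,
            _THUMB_JOINTS + _FINGER_JOINTS[finger], rest, tol=kapandji_tolerance,
        )

    gestures = {}
    flexed = {"mcp": 1.35, "pip": 1.7, "dip": 1.2}

    def gesture(flex_map):
        q = rest.copy()
        for d in ("index", "middle", "ring", "small"):
            for j, val in flexed.items():
                if d in flex_map:
                    continue
                q[skel.axis_index(f"{j}_{d}", "flex")] = val
        q[skel.axis_index("cmc_thumb", "flex")] = 0.9
        q[skel.axis_index("ip_thumb", "flex")] = 0.8
        return _clip_to_limits(skel, q)

    gestures["peace"] = gesture({"index", "middle"})
    gestures["rock"] = gesture({"index", "small"})
    gestures["three"] = gesture({"index", "middle", "ring"})

    grasp_pose = fma_poses["spherical_grip"]
    _, tips = forward_kinematics(skel, grasp_pose, check_limits=False)
    pts = np.stack(list(tips.values()))
    # the grasped ball is the sphere best fitting the five fingertips
    from .rge import fit_cor

    est = fit_cor(pts, model="sphere")
    center, diameter = est.center, 2.0 * est.radius
    return TrajectoryBundle(
        kapandji=kapandji,
        fma_poses=fma_poses,
        pinch=pinch,
        gestures=gestures,
        grasp_pose=grasp_pose,
        grasp_sphere=(center, diameter),
        kapandji_poses=kap_poses,
    )
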