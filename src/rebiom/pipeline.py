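"""End-to-end pipeline orchestration.

A single configured run goes from synthetic fixture generation (or user
files) through scan emulation, cloud cleaning/merging, curvature
classification and cusp segmentation, RGE/COR extraction, B-spline
surface fitting, skeleton assembly, spring-damper simulation, and the
clinical scoring batteries, producing a machine-readable report.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

STAGES = (
    "fixtures",
    "scan",
    "tooth",
    "rge",
    "surface",
    "skeleton",
    "simulate",
    "kapandji",
    "fma",
    "grasp",
)

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "stages": list(STAGES),
    "fixtures": {"hand_length_mm": 180.0, "crown_diameter_mm": 10.0},
    "scan": {"sigma_mm": 0.05, "n_views": 4, "points_per_view": 8000,
             "voxel_mm": 0.4, "k_neighbors": 16, "sigma_mult": 2.5},
    "tooth": {"noise_sigma_mm": 0.0, "smooth_iterations": 80, "ring": 3,
              "min_vertices": 20},
    "rge": {"n_stations": 60},
    "surface": {"net": [8, 8], "smoothing": 1e-3},
    "simulate": {"duration_s": 1.5, "dt_s": 1e-3, "torque_nmm": 10.0},
    "kapandji": {"tolerance_mm": 5.0},
    "grasp": {"total_n": 475.0},
}


class ConfigError(ValueError):
    """Invalid pipeline configuration (unknown stage or malformed value)."""


@dataclass
class PipelineConfig:
    raw: dict = field(default_factory=lambda: copy.deepcopy(DEFAULT_CONFIG))

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        cfg = copy.deepcopy(DEFAULT_CONFIG)
        for key, val in d.items():
            if key == "stages":
                unknown = set(val) - set(STAGES)
                if unknown:
                    raise ConfigError(f"unknown stages: {sorted(unknown)}")
                cfg["stages"] = list(val)
            elif key == "seed":
                cfg["seed"] = int(val)
            elif key in STAGES:
                if not isinstance(val, dict):
                    raise ConfigError(f"stage {key!r} config must be a mapping")
                cfg[key].update(val)
            else:
                raise ConfigError(f"unknown config key {key!r}")
        return cls(raw=cfg)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def __getitem__(self, key):
        return self.raw[key]


def run_pipeline(config: PipelineConfig | dict | None = None, out_dir=None) -> dict:
    """Execute the configured stages in order and return the run report.

    A stage failure marks the report and halts downstream stages.  With a
    fixed seed the report metrics are identical across invocations.
    """
    if config is None:
        config = PipelineConfig()
    elif isinstance(config, dict):
        config = PipelineConfig.from_dict(config)
    seed = config["seed"]
    enabled = config["stages"]
    report: dict = {"seed": seed, "stages": {}, "ok": True}
    ctx: dict = {}

    def record(stage, **metrics):
        report["stages"][stage] = {"status": "ok", **metrics}

    for stage in STAGES:
        if stage not in enabled:
            continue
        try:
            _STAGE_FUNCS[stage](config, seed, ctx, record)
        except Exception as exc:  # noqa: BLE001 - report and halt
            report["stages"][stage] = {"status": "failed", "error": str(exc)}
            report["ok"] = False
            break
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, default=_jsonable)
    return report


def _jsonable(x):
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    raise TypeError(f"not JSON serialisable: {type(x)}")


# --- stage implementations -------------------------------------------------


def _stage_fixtures(config, seed, ctx, record):
    from .fixtures import BoneSpec, gen_bone, gen_occlusal, gen_skeleton

    fx = config["fixtures"]
    ctx["bone"], ctx["bone_truth"] = gen_bone(BoneSpec(seed=seed))
    ctx["molar"], ctx["molar_truth"] = gen_occlusal(
        "molar", crown_diameter=fx["crown_diameter_mm"],
        noise_sigma=config["tooth"]["noise_sigma_mm"], seed=seed,
    )
    ctx["skeleton_fixture"] = gen_skeleton(fx["hand_length_mm"], seed=seed)
    record("fixtures", bone_vertices=len(ctx["bone"].vertices),
           molar_vertices=len(ctx["molar"].vertices),
           skeleton_bones=len(ctx["skeleton_fixture"].bones))


def _stage_scan(config, seed, ctx, record):
    from .fixtures import ScanSpec, emulate_scan
    from .geometry import clean_cloud, deviation_map, merge_clouds

    sc = config["scan"]
    clouds, _, _ = emulate_scan(
        ctx["bone"],
        ScanSpec(sigma=sc["sigma_mm"], n_views=sc["n_views"],
                 points_per_view=sc["points_per_view"], seed=seed),
    )
    cleaned = [clean_cloud(c, sc["k_neighbors"], sc["sigma_mult"]) for c in clouds]
    merged = merge_clouds(cleaned, voxel=sc["voxel_mm"])
    dev = deviation_map(ctx["bone"], merged)
    ctx["merged_cloud"] = merged
    record("scan", views=len(clouds), merged_points=len(merged),
           deviation_max_mm=dev.max, deviation_mean_mm=dev.mean)


def extract_tooth_cusps(
    mesh, smooth_iterations: int = 0, ring: int = 2, min_vertices: int = 20
):
    """Cusp extraction pipeline for an occlusal surface.

    For noisy scanned crowns use the cleaning configuration
    (``smooth_iterations=80, ring=3``); noise-free analytic crowns work
    with no smoothing and the default ring.
    """
    from .curvature import estimate_principal_curvatures
    from .geometry import smooth_mesh
    from .segmentation import extract_cusps, segment_regions

    work = smooth_mesh(mesh, smooth_iterations) if smooth_iterations else mesh
    f = estimate_principal_curvatures(work, ring=ring)
    labeling = segment_regions(work, f, scheme="hk", min_vertices=min_vertices)
    return extract_cusps(work, labeling), labeling, work


def _stage_tooth(config, seed, ctx, record):
    tc = config["tooth"]
    noisy = tc["noise_sigma_mm"] > 0
    cusps, labeling, work = extract_tooth_cusps(
        ctx["molar"],
        smooth_iterations=tc["smooth_iterations"] if noisy else 0,
        ring=tc["ring"] if noisy else 2,
        min_vertices=tc["min_vertices"],
    )
    ctx["cusps"], ctx["tooth_labeling"], ctx["tooth_mesh"] = cusps, labeling, work
    record("tooth", cusp_count=len(cusps),
           true_cusp_count=ctx["molar_truth"].n_cusps,
           region_count=len(labeling.regions))


def _stage_rge(config, seed, ctx, record):
    from .curvature import CONVEX_LABELS, classify_field, estimate_principal_curvatures
    from .rge import fit_cor, rge_frame
    from .segmentation import partition_bone_features

    bone, truth = ctx["bone"], ctx["bone_truth"]
    frame = rge_frame(bone)
    part = partition_bone_features(bone, frame, config["rge"]["n_stations"])
    f = estimate_principal_curvatures(bone)
    lab = classify_field(f, "hk")
    convex = np.array([l in CONVEX_LABELS for l in lab])
    sel = (part.labels == "head") & convex
    est = fit_cor(bone.vertices[sel], model="sphere")
    ctx["bone_frame"], ctx["bone_partition"] = frame, part
    record(
        "rge",
        cog_error_pct_length=float(
            np.linalg.norm(frame.centroid - truth.cog) / truth.spec.length * 100
        ),
        cor_error_mm=float(np.linalg.norm(est.center - truth.cor_center)),
        cor_error_pct_head_radius=float(
            np.linalg.norm(est.center - truth.cor_center) / truth.cor_radius * 100
        ),
        cor_radius_mm=est.radius,
    )


def _stage_surface(config, seed, ctx, record):
    from .surface import fit_surface

    cusps = ctx["cusps"]
    labeling = ctx["tooth_labeling"]
    mesh = ctx["tooth_mesh"]
    if not cusps:
        raise RuntimeError("no cusps to fit")
    biggest = max(cusps, key=lambda c: c.area)
    pts = mesh.vertices[labeling.vertex_region == biggest.region_id]
    net = tuple(config["surface"]["net"])
    surf, rep = fit_surface(pts, net=net, smoothing=config["surface"]["smoothing"])
    record("surface", fit_max_mm=rep.max_deviation, fit_mean_mm=rep.mean_deviation,
           control_points=rep.control_point_count)


def _stage_skeleton(config, seed, ctx, record):
    from .hand import build_skeleton, enumerate_dof

    skel = build_skeleton(ctx["skeleton_fixture"])
    ctx["skel"] = skel
    record("skeleton", bones=len(skel.bones), joints=len(skel.joints),
           model_dof=enumerate_dof(skel), anatomical_dof=enumerate_dof(mode="anatomical"))


def _stage_simulate(config, seed, ctx, record):
    from .hand import simulate_pose

    skel = ctx["skel"]
    sc = config["simulate"]
    tau = np.zeros(skel.n_axes)
    tau[0] = sc["torque_nmm"]
    traj = simulate_pose(skel, tau, sc["duration_s"], sc["dt_s"], sample_every=10)
    steady = traj.angles[-1, 0]
    expected = sc["torque_nmm"] / skel.joints[0].stiffness
    record("simulate", steady_state_rad=float(steady),
           steady_state_error=float(abs(steady - expected)),
           samples=len(traj.times))


def _stage_kapandji(config, seed, ctx, record):
    from .hand import kapandji_score
    from .trajectories import gen_trajectories

    bundle = gen_trajectories(ctx["skel"],
                              kapandji_tolerance=config["kapandji"]["tolerance_mm"])
    ctx["bundle"] = bundle
    score, flags = kapandji_score(
        ctx["skel"], bundle.kapandji, config["kapandji"]["tolerance_mm"]
    )
    record("kapandji", score=score, reached=[bool(f) for f in flags])


def _stage_fma(config, seed, ctx, record):
    from .hand import fma_pose_battery

    results = fma_pose_battery(ctx["skel"], ctx["bundle"].fma_poses)
    record("fma", passed=sum(results.values()), total=len(results),
           results={k: bool(v) for k, v in results.items()})


def _stage_grasp(config, seed, ctx, record):
    from .hand import grasp_contact_forces

    bundle = ctx["bundle"]
    forces = grasp_contact_forces(
        ctx["skel"], bundle.grasp_pose, *bundle.grasp_sphere,
        total=config["grasp"]["total_n"],
    )
    record("grasp", contacts=len(forces.contacts),
           total_n=forces.total,
           magnitudes_n=[round(c[3], 3) for c in forces.contacts],
           residual=forces.residual,
           sphere_diameter_mm=float(bundle.grasp_sphere[1]))


_STAGE_FUNCS = {
    "fixtures": _stage_fixtures,
    "scan": _stage_scan,
    "tooth": _stage_tooth,
    "rge": _stage_rge,
    "surface": _stage_surface,
    "skeleton": _stage_skeleton,
    "simulate": _stage_simulate,
    "kapandji": _stage_kapandji,
    "fma": _stage_fma,
    "grasp": _stage_grasp,
}
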