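"""Synthetic anatomical fixtures with known ground truth.

Every input the pipeline consumes can be generated here: parametric long
bones (necked shafts with spherical articular heads), multi-cusp occlusal
crown surfaces, a 27-bone hand skeleton, and a structured-light scanner
emulator (Gaussian noise, dropout, per-view rigid jitter).  Each
generator is a pure function of its spec and seed and returns the ground
truth needed for parameter-recovery tests: centre of gravity, neck
stations, condylar centres (CORs), cusp apexes, view transforms.

The fixtures are parametric idealisations, not anatomical replicas:
realism targets the geometric features the pipeline measures (necks,
condyles, cusps, joint placement), not bone-by-bone shape fidelity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.special import gamma

from .geometry import PointCloud, TriangleMesh

DEFAULT_SCAN_SIGMA = 0.05  # mm, structured-light class accuracy


@dataclass
class BoneSpec:
    """Parametric long bone: necked shaft with spherical head and base.

    Lengths/radii in mm; ``neck_stations`` are fractions of length where
    the cross-section area profile dips (the anatomical necks).  The head
    (distal, +y) is an exact sphere whose centre is the ground-truth COR.
    """

    group: str = "phalanx"
    length: float = 40.0
    head_radius: float = 5.5
    base_radius: float = 4.8
    shaft_radius: float = 3.2
    neck_stations: tuple[float, float] = (0.18, 0.82)
    neck_radius_frac: float = 0.78  # neck radius / shaft radius
    superellipse_exponent: float = 2.4
    n_axial: int = 100
    n_circ: int = 44
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.neck_stations[0] < self.neck_stations[1] < 1):
            raise ValueError("neck stations must satisfy 0 < s1 < s2 < 1")
        if min(self.head_radius, self.base_radius, self.shaft_radius) <= 0:
            raise ValueError("radii must be > 0")
        if self.length <= 2 * (self.head_radius + self.base_radius):
            raise ValueError("length too short for the requested head/base radii")


@dataclass
class ScanSpec:
    """Scanner emulation: noise, dropout and per-view rigid jitter."""

    sigma: float = DEFAULT_SCAN_SIGMA
    dropout: float = 0.0
    n_views: int = 2
    jitter_rot: float = 0.0  # rad, per view
    jitter_trans: float = 0.0  # mm, per view
    points_per_view: int = 20000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0 or not (0 <= self.dropout < 1):
            raise ValueError("need sigma >= 0 and 0 <= dropout < 1")


@dataclass
class BoneTruth:
    spec: BoneSpec
    cog: np.ndarray  # analytic solid-of-revolution centroid
    volume: float
    cor_center: np.ndarray  # head sphere centre
    cor_radius: float
    neck_stations_mm: tuple[float, float]  # axial positions of the necks
    axis: np.ndarray = field(default_factory=lambda: np.array([0.0, 1.0, 0.0]))


def _superellipse_area_factor(p: float) -> float:
    # area of |x|^p + |z|^p <= 1 (unit superellipse)
    return 4.0 * gamma(1 + 1 / p) ** 2 / gamma(1 + 2 / p)


def _bone_profile(spec: BoneSpec):
    """Radius profile r(y) and superellipse exponent p(y) for y in [0, L].

    Exact sphere arcs at both ends (circular cross-sections there), a
    monotone-cubic blend through the neck minima along the shaft.
    """
    L = spec.length
    rh, rb, rs = spec.head_radius, spec.base_radius, spec.shaft_radius
    y_head_c = L - rh  # head sphere centre height
    y_base_c = rb
    # sphere arcs end at the equator-ish join heights
    y_join_b = rb * 1.55
    y_join_h = L - rh * 1.55
    # necks cannot sit inside the articular sphere caps; clamp towards mid
    n1 = max(spec.neck_stations[0] * L, y_join_b + 0.06 * L)
    n2 = min(spec.neck_stations[1] * L, y_join_h - 0.06 * L)
    if not n1 < n2:
        raise ValueError("neck stations collapse inside the articular caps")
    rn = spec.neck_radius_frac * rs
    # control points for the mid profile (strict minima at the necks)
    ys = [y_join_b, n1, 0.5 * (n1 + n2), n2, y_join_h]
    rs_ctrl = [
        float(np.sqrt(max(rb**2 - (y_join_b - y_base_c) ** 2, 1e-9))),
        rn,
        rs,
        rn,
        float(np.sqrt(max(rh**2 - (y_join_h - y_head_c) ** 2, 1e-9))),
    ]
    mid = PchipInterpolator(ys, rs_ctrl)

    def r_of_y(y):
        y = np.asarray(y, dtype=float)
        out = np.empty_like(y)
        low = y <= y_join_b
        high = y >= y_join_h
        m = ~(low | high)
        out[low] = np.sqrt(np.maximum(rb**2 - (y[low] - y_base_c) ** 2, 0.0))
        out[high] = np.sqrt(np.maximum(rh**2 - (y[high] - y_head_c) ** 2, 0.0))
        out[m] = mid(y[m])
        return out

    def p_of_y(y):
        # circular at the articular ends, superellipse along the shaft
        y = np.asarray(y, dtype=float)
        t = np.clip((y - y_join_b) / max(n1 - y_join_b, 1e-9), 0, 1) * np.clip(
            (y_join_h - y) / max(y_join_h - n2, 1e-9), 0, 1
        )
        blend = 0.5 - 0.5 * np.cos(np.pi * np.clip(t, 0, 1))
        return 2.0 + (spec.superellipse_exponent - 2.0) * blend

    return r_of_y, p_of_y, (n1, n2)


def _analytic_cog(spec: BoneSpec):
    """Solid-of-revolution centroid by quadrature of the area profile."""
    r_of_y, p_of_y, _ = _bone_profile(spec)
    y = np.linspace(0.0, spec.length, 4001)
    area = _superellipse_area_factor(p_of_y(y)) * r_of_y(y) ** 2
    vol = np.trapezoid(area, y)
    ybar = np.trapezoid(area * y, y) / vol
    return np.array([0.0, ybar, 0.0]), float(vol)


def gen_bone(spec: BoneSpec) -> tuple[TriangleMesh, BoneTruth]:
    """Watertight long-bone mesh plus its analytic ground truth.

    The bone axis is +y with the base at y=0 and the spherical head at the
    distal end; cross-sections are superellipses along the shaft and exact
    circles over the articular spheres.
    """
    r_of_y, p_of_y, necks = _bone_profile(spec)
    L = spec.length
    # place axial stations at equal arc length along the profile curve so
    # the sphere caps and necks are resolved as finely as they bend
    yf = np.linspace(0.0, L, 4001)
    rf = r_of_y(yf)
    arc = np.r_[0.0, np.cumsum(np.hypot(np.diff(yf), np.diff(rf)))]
    targets = np.linspace(0.0, arc[-1], spec.n_axial)
    y = np.interp(targets, arc, yf)[1:-1]  # poles handled separately
    theta = np.linspace(0, 2 * np.pi, spec.n_circ, endpoint=False)
    ct, st = np.cos(theta), np.sin(theta)
    verts = [np.array([0.0, 0.0, 0.0])]  # base pole
    for yi in y:
        r = float(r_of_y(np.array([yi]))[0])
        p = float(p_of_y(np.array([yi]))[0])
        x = r * np.sign(ct) * np.abs(ct) ** (2.0 / p)
        z = r * np.sign(st) * np.abs(st) ** (2.0 / p)
        verts.append(np.column_stack([x, np.full_like(x, yi), z]))
    verts.append(np.array([0.0, L, 0.0]))  # head pole
    V = np.vstack([v if v.ndim == 2 else v[None] for v in verts])
    nc = spec.n_circ
    faces = []
    # base fan (outward normals point -y at the base)
    for j in range(nc):
        faces.append([0, 1 + j, 1 + (j + 1) % nc])
    rows = len(y)
    for i in range(rows - 1):
        a0 = 1 + i * nc
        b0 = 1 + (i + 1) * nc
        for j in range(nc):
            j1 = (j + 1) % nc
            faces.append([a0 + j, b0 + j, b0 + j1])
            faces.append([a0 + j, b0 + j1, a0 + j1])
    top = 1 + rows * nc
    last = 1 + (rows - 1) * nc
    for j in range(nc):
        faces.append([top, last + (j + 1) % nc, last + j])
    mesh = TriangleMesh(V, np.asarray(faces))
    if mesh.trimesh.volume < 0:  # safety net; winding is outward by construction
        mesh = TriangleMesh(V, np.asarray(faces)[:, ::-1])
    cog, vol = _analytic_cog(spec)
    truth = BoneTruth(
        spec=spec,
        cog=cog,
        volume=vol,
        cor_center=np.array([0.0, L - spec.head_radius, 0.0]),
        cor_radius=spec.head_radius,
        neck_stations_mm=necks,
    )
    return mesh, truth


@dataclass
class OcclusalTruth:
    n_cusps: int
    apexes: np.ndarray  # (n, 3)
    crown_diameter: float


_OCCLUSAL_PRESETS = {"molar": 8, "premolar": 6, "incisor": 3}


def gen_occlusal(
    preset: str | None = "molar",
    n_cusps: int | None = None,
    crown_diameter: float = 10.0,
    cusp_height: float = 1.3,
    cusp_sigma_frac: float = 0.07,
    noise_sigma: float = 0.0,
    grid_n: int = 64,
    seed: int = 0,
) -> tuple[TriangleMesh, OcclusalTruth]:
    """Multi-cusp occlusal crown as a height field over a disk.

    The crown is a shallow central basin plus ``n_cusps`` radially placed
    smooth bumps with seeded, slightly irregular heights and angular
    positions (the apex ground truth records the realised positions).
    ``noise_sigma`` adds per-vertex Gaussian measurement noise.  The
    occlusal direction is +z.
    """
    if n_cusps is None:
        if preset not in _OCCLUSAL_PRESETS:
            raise ValueError(f"unknown preset {preset!r}")
        n_cusps = _OCCLUSAL_PRESETS[preset]
    if n_cusps < 1:
        raise ValueError("n_cusps must be >= 1")
    rng = np.random.default_rng(seed)
    R = crown_diameter / 2.0
    sig = cusp_sigma_frac * crown_diameter
    ring_r = 0.64 * R
    base_ang = np.linspace(0, 2 * np.pi, n_cusps, endpoint=False)
    ang = base_ang + rng.uniform(-0.12, 0.12, n_cusps) * (2 * np.pi / max(n_cusps, 1))
    heights = cusp_height * (1.0 + rng.uniform(-0.08, 0.08, n_cusps))
    cx = ring_r * np.cos(ang)
    cy = ring_r * np.sin(ang)

    lin = np.linspace(-R, R, grid_n)
    gx, gy = np.meshgrid(lin, lin, indexing="ij")
    keep = gx**2 + gy**2 <= R**2

    def height(px, py):
        z = -0.45 * cusp_height * np.exp(-(px**2 + py**2) / (2 * (0.33 * R) ** 2))
        z = z - 0.15 * cusp_height * ((px**2 + py**2) / R**2)  # rim roll-off
        for k in range(n_cusps):
            d2 = (px - cx[k]) ** 2 + (py - cy[k]) ** 2
            z = z + heights[k] * np.exp(-d2 / (2 * sig**2))
        return z

    gz = height(gx, gy)
    index = -np.ones((grid_n, grid_n), dtype=int)
    index[keep] = np.arange(keep.sum())
    V = np.column_stack([gx[keep], gy[keep], gz[keep]])
    faces = []
    for i in range(grid_n - 1):
        for j in range(grid_n - 1):
            a, b = index[i, j], index[i + 1, j]
            c, d = index[i + 1, j + 1], index[i, j + 1]
            if a >= 0 and b >= 0 and c >= 0:
                faces.append([a, c, b])
            if a >= 0 and c >= 0 and d >= 0:
                faces.append([a, d, c])
    if noise_sigma > 0:
        V = V + rng.normal(0.0, noise_sigma, V.shape)
    mesh = TriangleMesh(V, np.asarray(faces))
    # orient normals towards +z (occlusal)
    if mesh.trimesh.face_normals[:, 2].mean() < 0:
        mesh = TriangleMesh(V, np.asarray(faces)[:, ::-1])
    apex_z = height(cx, cy)
    truth = OcclusalTruth(
        n_cusps=n_cusps,
        apexes=np.column_stack([cx, cy, apex_z]),
        crown_diameter=crown_diameter,
    )
    return mesh, truth


def emulate_scan(
    mesh: TriangleMesh, spec: ScanSpec
) -> tuple[list[PointCloud], PointCloud, list[np.ndarray]]:
    """Emulate a multi-view surface scan of a mesh.

    Each view samples the surface uniformly by area, keeps points whose
    outward normal faces the view direction (visibility), adds Gaussian
    noise along the normal plus isotropic jitter, drops points with the
    dropout probability, and applies a per-view rigid offset.  Returns the
    per-view clouds, the noise-free true merge, and the ground-truth 4x4
    view transforms.
    """
    rng = np.random.default_rng(spec.seed)
    tm = mesh.trimesh
    dirs = _view_directions(spec.n_views)
    clouds: list[PointCloud] = []
    true_points = []
    transforms = []
    for v in range(spec.n_views):
        pts, face_idx = tm.sample(spec.points_per_view, return_index=True, seed=int(rng.integers(2**31)))
        normals = np.asarray(tm.face_normals)[face_idx]
        visible = normals @ dirs[v] > 0.05
        pts, normals = pts[visible], normals[visible]
        if spec.dropout > 0:
            keepmask = rng.random(len(pts)) > spec.dropout
            pts, normals = pts[keepmask], normals[keepmask]
        true_points.append(pts.copy())
        noisy = pts + spec.sigma * rng.normal(size=(len(pts), 1)) * normals
        # jitter variates are drawn unconditionally so the sample stream is
        # identical across jitter settings at a fixed seed
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        angle = rng.normal(0.0, 1.0) * spec.jitter_rot
        trans = rng.normal(0.0, 1.0, 3) * spec.jitter_trans
        T = np.eye(4)
        if spec.jitter_rot > 0 or spec.jitter_trans > 0:
            T[:3, :3] = _rotation_matrix(axis, angle)
            T[:3, 3] = trans
        moved = noisy @ T[:3, :3].T + T[:3, 3]
        clouds.append(
            PointCloud(moved, view_id=np.full(len(moved), v, dtype=int))
        )
        transforms.append(T)
    merged_true = PointCloud(np.vstack(true_points)) if true_points else PointCloud(np.empty((0, 3)))
    return clouds, merged_true, transforms


def _view_directions(n: int) -> np.ndarray:
    golden = np.pi * (3 - np.sqrt(5))
    k = np.arange(n)
    z = 1 - 2 * (k + 0.5) / n
    r = np.sqrt(1 - z * z)
    return np.column_stack([r * np.cos(golden * k), r * np.sin(golden * k), z])


def _rotation_matrix(axis: np.ndarray, angle: float) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    K = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)


# ---------------------------------------------------------------------------
# 27-bone hand skeleton
# ---------------------------------------------------------------------------

DIGITS = ("thumb", "index", "middle", "ring", "small")
CARPAL_NAMES = (
    "scaphoid", "lunate", "triquetrum", "pisiform",
    "trapezium", "trapezoid", "capitate", "hamate",
)

# per-digit segment lengths as fractions of hand length (wrist->middle tip)
_DIGIT_SCALE = {"thumb": None, "index": 0.95, "middle": 1.0, "ring": 0.93, "small": 0.80}
_DIGIT_X = {"thumb": 30.0, "index": 18.0, "middle": 6.0, "ring": -6.0, "small": -18.0}


@dataclass
class BonePlacement:
    name: str
    number: int
    group: str  # carpal | metacarpal | proximal | middle | distal
    digit: str | None
    mesh: TriangleMesh
    base_point: np.ndarray
    tip_point: np.ndarray
    direction: np.ndarray
    truth: BoneTruth | None = None
    cor_world: np.ndarray | None = None  # head sphere centre in world
    cor_radius: float = 0.0


@dataclass
class JointSpec:
    name: str
    kind: str  # revolute | universal
    parent: str
    child: str
    cor: np.ndarray
    axes: np.ndarray  # (1 or 2, 3)
    limits: np.ndarray  # (n_axes, 2)


@dataclass
class SkeletonFixture:
    bones: list[BonePlacement]
    joints: list[JointSpec]
    fixed_attachments: list[tuple[str, str]]  # (parent, child) welds
    hand_length: float
    seed: int

    def bone(self, name: str) -> BonePlacement:
        for b in self.bones:
            if b.name == name:
                return b
        raise KeyError(name)


def _frame_for_direction(d: np.ndarray) -> np.ndarray:
    """Rotation taking +y to direction d (columns are image of x, y, z)."""
    d = d / np.linalg.norm(d)
    ref = np.array([0.0, 0.0, 1.0]) if abs(d[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    x = np.cross(ref, d)
    x /= np.linalg.norm(x)
    z = np.cross(x, d)
    return np.column_stack([x, d, z])


def _posed_bone(spec: BoneSpec, base: np.ndarray, direction: np.ndarray):
    mesh, truth = gen_bone(spec)
    R = _frame_for_direction(direction)
    V = mesh.vertices @ R.T + base
    posed = TriangleMesh(V, mesh.faces)
    cor = R @ truth.cor_center + base
    tip = R @ np.array([0.0, spec.length, 0.0]) + base
    return posed, truth, cor, tip


def _carpal_blob(center: np.ndarray, radii: np.ndarray, seed: int) -> TriangleMesh:
    rng = np.random.default_rng(seed)
    import trimesh

    ico = trimesh.creation.icosphere(subdivisions=2, radius=1.0)
    V = np.asarray(ico.vertices).copy()
    # mild seeded lumpiness so carpals are compact but not perfect ellipsoids
    bump = 1.0 + 0.08 * np.sin(3 * V[:, 0] + rng.uniform(0, 2 * np.pi))
    V = V * bump[:, None] * radii + center
    return TriangleMesh(V, np.asarray(ico.faces))


def gen_skeleton(hand_length: float = 180.0, seed: int = 0) -> SkeletonFixture:
    """Generate the 27-bone hand: 8 carpals, 5 metacarpals, 14 phalanges.

    Coordinates: +x radial (thumb side), +y distal, +z dorsal; the wrist
    sits at the origin.  Finger chains run distally with ~1.6 mm joint
    gaps; the thumb column is abducted radially and rotated volar so its
    flexion sweep opposes the finger pads.  Bone numbering: carpals 1-8,
    metacarpals 9-13 (9 = thumb), proximal phalanges 14-18, middle
    phalanges 19-22 (no thumb middle), distal phalanges 23-27.
    """
    if hand_length <= 0:
        raise ValueError("hand_length must be > 0")
    s = hand_length / 180.0
    gap = 1.6 * s
    bones: list[BonePlacement] = []
    joints: list[JointSpec] = []
    welds: list[tuple[str, str]] = []

    # --- carpals: two rows of compact blobs around the wrist
    row_y = (8.0 * s, 22.0 * s)
    xs = (16.5, 5.5, -5.5, -16.5)
    num = 1
    for row, ylev in enumerate(row_y):
        for col, xo in enumerate(xs):
            name = CARPAL_NAMES[row * 4 + col]
            center = np.array([xo * s, ylev, 0.0])
            radii = np.array([4.6, 5.4, 4.2]) * s
            mesh = _carpal_blob(center, radii, seed * 101 + num)
            bones.append(
                BonePlacement(
                    name=name, number=num, group="carpal", digit=None, mesh=mesh,
                    base_point=center, tip_point=center,
                    direction=np.array([0.0, 1.0, 0.0]),
                )
            )
            num += 1

    # --- digit columns
    finger_lengths = {  # (metacarpal, proximal, middle, distal) for middle digit
        "metacarpal": 62.0, "proximal": 42.0, "middle": 26.0, "distal": 20.0,
    }
    radii_by_group = {"metacarpal": 4.4, "proximal": 3.9, "middle": 3.2, "distal": 2.7}
    thumb_lengths = {"metacarpal": 44.0, "proximal": 31.0, "distal": 24.0}
    thumb_dir = np.array([0.72, 0.62, -0.32])
    thumb_dir /= np.linalg.norm(thumb_dir)

    placements: dict[str, dict[str, BonePlacement]] = {}
    group_numbers = {"metacarpal": 9, "proximal": 14, "middle": 19, "distal": 23}
    for digit in DIGITS:
        placements[digit] = {}
        if digit == "thumb":
            chain = ("metacarpal", "proximal", "distal")
            lengths = {g: thumb_lengths[g] * s for g in chain}
            base = np.array([_DIGIT_X[digit] * s, 24.0 * s, -6.0 * s])
            direction = thumb_dir
        else:
            chain = ("metacarpal", "proximal", "middle", "distal")
            fs = _DIGIT_SCALE[digit]
            lengths = {g: finger_lengths[g] * fs * s for g in chain}
            base = np.array([_DIGIT_X[digit] * s, 30.0 * s, 0.0])
            direction = np.array([0.0, 1.0, 0.0])
        cursor = base
        for g in chain:
            L = lengths[g]
            r = radii_by_group[g] * (0.9 if digit == "small" else 1.0) * s
            spec = BoneSpec(
                group=g,
                length=L,
                head_radius=min(1.28 * r, 0.22 * L),
                base_radius=min(1.15 * r, 0.2 * L),
                shaft_radius=r * 0.78,
                seed=seed,
            )
            mesh, truth, cor, tip = _posed_bone(spec, cursor, direction)
            name = f"{g}_{digit}"
            bones.append(
                BonePlacement(
                    name=name, number=0, group=g, digit=digit, mesh=mesh,
                    base_point=cursor.copy(), tip_point=tip, direction=direction,
                    truth=truth, cor_world=cor, cor_radius=spec.head_radius,
                )
            )
            placements[digit][g] = bones[-1]
            cursor = tip + gap * direction

    # deterministic numbering: within each group, thumb..small order
    for g, start in group_numbers.items():
        n = start
        for digit in DIGITS:
            if g in placements[digit]:
                placements[digit][g].number = n
                n += 1

    # --- joints
    def flexion_axis(direction, palmar):
        f = np.cross(direction, palmar)
        return f / np.linalg.norm(f)

    for digit in DIGITS:
        mc = placements[digit]["metacarpal"]
        pp = placements[digit]["proximal"]
        dp = placements[digit]["distal"]
        if digit == "thumb":
            palmar = np.array([-0.55, 0.0, -0.84])
            palmar /= np.linalg.norm(palmar)
            fax = flexion_axis(mc.direction, palmar)
            abax = np.cross(fax, mc.direction)
            # CMC universal at the metacarpal base (trapezium side)
            joints.append(JointSpec(
                name="cmc_thumb", kind="universal", parent="trapezium",
                child="metacarpal_thumb", cor=mc.base_point,
                axes=np.stack([fax, abax]),
                limits=np.array([[-0.4, 2.1], [-1.3, 1.3]]),
            ))
            joints.append(JointSpec(
                name="mcp_thumb", kind="universal", parent="metacarpal_thumb",
                child="proximal_thumb", cor=mc.cor_world,
                axes=np.stack([fax, abax]),
                limits=np.array([[-0.2, 1.4], [-0.6, 0.6]]),
            ))
            joints.append(JointSpec(
                name="ip_thumb", kind="revolute", parent="proximal_thumb",
                child="distal_thumb", cor=pp.cor_world,
                axes=fax[None], limits=np.array([[-0.3, 1.8]]),
            ))
        else:
            mp = placements[digit]["middle"]
            palmar = np.array([0.0, 0.0, -1.0])
            fax = flexion_axis(mc.direction, palmar)
            abax = np.cross(fax, mc.direction)
            joints.append(JointSpec(
                name=f"mcp_{digit}", kind="universal", parent=mc.name,
                child=pp.name, cor=mc.cor_world,
                axes=np.stack([fax, abax]),
                limits=np.array([[-0.35, 1.65], [-0.40, 0.40]]),
            ))
            joints.append(JointSpec(
                name=f"pip_{digit}", kind="revolute", parent=pp.name,
                child=mp.name, cor=pp.cor_world,
                axes=fax[None], limits=np.array([[-0.1, 1.95]]),
            ))
            joints.append(JointSpec(
                name=f"dip_{digit}", kind="revolute", parent=mp.name,
                child=dp.name, cor=mp.cor_world,
                axes=fax[None], limits=np.array([[-0.1, 1.45]]),
            ))
            welds.append(("capitate", mc.name))

    # carpals welded into one fixed block rooted at the scaphoid
    root = "scaphoid"
    for c in CARPAL_NAMES:
        if c != root:
            welds.append((root, c))

    return SkeletonFixture(
        bones=bones, joints=joints, fixed_attachments=welds,
        hand_length=hand_length, seed=seed,
    )
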