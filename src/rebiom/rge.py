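"""Referential geometric entities (RGEs).

An RGE frame — centroid, ordered principal axes and the three principal
planes through the centroid — orients a bone for sectioning, feature
partitioning and registration.  This module also provides 3-landmark
rigid alignment to a canonical frame, transverse cross-sections, and
least-squares sphere / circle fitting of articular heads to estimate
joint centres of rotation (CORs).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .geometry import PointCloud, TriangleMesh, mass_properties


@dataclass
class RGEFrame:
    """Centroid (mm) and right-handed orthonormal principal axes.

    ``axes[0]`` is the primary axis (largest spatial extent), ``axes[2]``
    completes the right-handed triple.  The three principal planes pass
    through the centroid with the axes as normals.  ``degenerate`` is set
    when the shape is spherically symmetric within tolerance and the axis
    choice is arbitrary-but-orthonormal.
    """

    centroid: np.ndarray
    axes: np.ndarray  # (3, 3), rows are axes
    extents: np.ndarray  # spatial extent along each axis (mm)
    degenerate: bool = False

    def plane(self, k: int):
        """Principal plane k as (point, normal)."""
        return self.centroid, self.axes[k]

    def transformed(self, matrix: np.ndarray) -> "RGEFrame":
        R = np.asarray(matrix)[:3, :3]
        t = np.asarray(matrix)[:3, 3]
        return RGEFrame(
            centroid=R @ self.centroid + t,
            axes=self.axes @ R.T,
            extents=self.extents.copy(),
            degenerate=self.degenerate,
        )


@dataclass
class LandmarkSet:
    """Named anatomical points, e.g. basion/nasion/sella or generic L1-L3."""

    points: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        self.points = {k: np.asarray(v, dtype=float) for k, v in self.points.items()}

    def ordered(self, labels) -> np.ndarray:
        missing = [lab for lab in labels if lab not in self.points]
        if missing:
            raise KeyError(f"landmarks missing: {missing}")
        return np.stack([self.points[lab] for lab in labels])


@dataclass
class CrossSection:
    station: float
    polylines: list[np.ndarray]  # closed planar loops (n, 3)
    area: float
    perimeter: float


@dataclass
class CrossSectionSet:
    stations: list[float]
    sections: list[CrossSection]
    skipped: list[float] = field(default_factory=list)


@dataclass
class CorEstimate:
    """Joint centre-of-rotation estimate from a sphere or in-plane circle fit."""

    center: np.ndarray
    radius: float
    rms_residual: float
    model: str  # 'sphere' or 'circle'
    plane_normal: np.ndarray | None = None


def rge_frame(mesh: TriangleMesh) -> RGEFrame:
    """Centroid and principal axes of a bone.

    The centroid and inertia tensor are solid (divergence-theorem) mass
    properties; for open meshes the vertex mean and vertex covariance are
    used instead with a warning.  Eigenvectors of the inertia tensor are
    ordered by descending *spatial extent* of the shape along each axis
    (not by eigenvalue), which keeps flat-and-wide bones stable.  Each of
    the first two axes is flipped so that it points towards the vertex
    farthest from the centroid along it; the third completes the
    right-handed triple.
    """
    if mesh.is_watertight:
        _, _, centroid, inertia = mass_properties(mesh)
        M = inertia
    else:
        warnings.warn(
            "mesh is open; using vertex mean/covariance instead of solid "
            "mass properties",
            stacklevel=2,
        )
        centroid = mesh.vertices.mean(axis=0)
        M = np.cov((mesh.vertices - centroid).T)
    _, vecs = np.linalg.eigh(M)
    axes = vecs.T  # candidate orthonormal axes (rows)
    rel = mesh.vertices - centroid
    proj = rel @ axes.T
    extents = proj.max(axis=0) - proj.min(axis=0)
    order = np.argsort(-extents)
    axes = axes[order]
    extents = extents[order]
    degenerate = bool(np.ptp(extents) < 1e-2 * max(extents.max(), 1e-12))
    # deterministic, rigid-equivariant sign rule for the first two axes
    for k in range(2):
        p = rel @ axes[k]
        if p[np.argmax(np.abs(p))] < 0:
            axes[k] = -axes[k]
    axes[2] = np.cross(axes[0], axes[1])
    return RGEFrame(
        centroid=np.asarray(centroid, dtype=float),
        axes=axes,
        extents=extents,
        degenerate=degenerate,
    )


def landmark_align(landmarks: LandmarkSet, convention=("L1", "L2", "L3")) -> np.ndarray:
    """Rigid transform (4x4) taking three landmarks to a canonical frame.

    Landmark 1 goes to the origin, landmark 2 onto the +x axis, landmark 3
    into the xy-plane with positive y.  The transform is rigid (rotation +
    translation, no scaling); applying it to the landmarks reproduces the
    canonical configuration exactly.
    """
    p = landmarks.ordered(convention)
    a = p[1] - p[0]
    b = p[2] - p[0]
    na = np.linalg.norm(a)
    cross = np.cross(a, b)
    sin_angle = np.linalg.norm(cross) / max(na * np.linalg.norm(b), 1e-300)
    if sin_angle < 1e-9:
        raise ValueError(
            f"landmarks are collinear (sin of spanned angle = {sin_angle:.3e})"
        )
    x = a / na
    z = cross / np.linalg.norm(cross)
    y = np.cross(z, x)
    R = np.stack([x, y, z])  # world -> canonical rotation
    T = np.eye(4)
    T[:3, :3] = R
    T[:3, 3] = -R @ p[0]
    return T


def apply_transform(points: np.ndarray, T: np.ndarray) -> np.ndarray:
    return points @ np.asarray(T)[:3, :3].T + np.asarray(T)[:3, 3]


def _loop_area_perimeter(loop: np.ndarray, normal: np.ndarray):
    """Planar polygon area (shoelace via the cross-product sum) and perimeter."""
    v = loop - loop.mean(axis=0)
    cross = np.cross(v, np.roll(v, -1, axis=0)).sum(axis=0)
    area = 0.5 * abs(cross @ normal)
    per = np.linalg.norm(np.diff(np.vstack([loop, loop[:1]]), axis=0), axis=1).sum()
    return float(area), float(per)


def cross_sections(
    mesh: TriangleMesh, frame: RGEFrame, n_stations: int
) -> CrossSectionSet:
    """Sections perpendicular to the primary axis at equally spaced stations.

    Stations span the axial extent (inset slightly from the extreme
    vertices so the cutting planes always intersect the surface).  Each
    section is one or more closed polylines from the mesh-plane
    intersection; stations that miss the mesh are skipped and recorded.
    """
    if n_stations < 2:
        raise ValueError("n_stations must be >= 2")
    axis = frame.axes[0]
    t = (mesh.vertices - frame.centroid) @ axis
    lo, hi = t.min(), t.max()
    inset = 1e-3 * (hi - lo)
    stations = np.linspace(lo + inset, hi - inset, n_stations)
    sections: list[CrossSection] = []
    skipped: list[float] = []
    kept: list[float] = []
    for s in stations:
        origin = frame.centroid + s * axis
        path = mesh.trimesh.section(plane_origin=origin, plane_normal=axis)
        if path is None:
            skipped.append(float(s))
            continue
        loops = [np.asarray(d) for d in path.discrete]
        area = 0.0
        per = 0.0
        for loop in loops:
            a, p = _loop_area_perimeter(loop, axis)
            area += a
            per += p
        if area <= 0:
            skipped.append(float(s))
            continue
        kept.append(float(s))
        sections.append(
            CrossSection(station=float(s), polylines=loops, area=area, perimeter=per)
        )
    return CrossSectionSet(stations=kept, sections=sections, skipped=skipped)


def _sphere_fit_algebraic(pts: np.ndarray):
    A = np.hstack([2 * pts, np.ones((len(pts), 1))])
    b = (pts**2).sum(axis=1)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    center = sol[:3]
    r2 = sol[3] + center @ center
    return center, float(np.sqrt(max(r2, 0.0)))


def fit_cor(region, model: str = "sphere") -> CorEstimate:
    """Fit a sphere (or a circle in a plane) to an articular head surface.

    Sphere mode: algebraic least squares refined by geometric
    (Levenberg-Marquardt) least squares; needs >= 4 non-coplanar points.
    Circle mode fits the condylar profile of a planar cross-section: the
    best-fit plane is found by SVD, points are projected into it and a
    circle fitted; the centre is reported in 3D.
    """
    if isinstance(region, TriangleMesh):
        pts = region.vertices
    elif isinstance(region, PointCloud):
        pts = region.points
    else:
        pts = np.asarray(region, dtype=float).reshape(-1, 3)
    if model == "sphere":
        if len(pts) < 4:
            raise ValueError("sphere fit needs >= 4 points")
        centered = pts - pts.mean(axis=0)
        svals = np.linalg.svd(centered, compute_uv=False)
        if svals[2] < 1e-9 * max(svals[0], 1e-300):
            raise ValueError("points are coplanar; use model='circle'")
        c0, r0 = _sphere_fit_algebraic(pts)

        def resid(x):
            return np.linalg.norm(pts - x[:3], axis=1) - x[3]

        sol = least_squares(resid, np.r_[c0, r0], method="lm")
        center, radius = sol.x[:3], float(sol.x[3])
        rms = float(np.sqrt(np.mean(resid(sol.x) ** 2)))
        return CorEstimate(center=center, radius=abs(radius), rms_residual=rms,
                           model="sphere")
    if model == "circle":
        if len(pts) < 3:
            raise ValueError("circle fit needs >= 3 points")
        mean = pts.mean(axis=0)
        _, _, vt = np.linalg.svd(pts - mean)
        normal = vt[2]
        u, v = vt[0], vt[1]
        xy = np.column_stack([(pts - mean) @ u, (pts - mean) @ v])
        A = np.hstack([2 * xy, np.ones((len(xy), 1))])
        b = (xy**2).sum(axis=1)
        sol, *_ = np.linalg.lstsq(A, b, rcond=None)
        c2 = sol[:2]
        r0 = float(np.sqrt(max(sol[2] + c2 @ c2, 0.0)))

        def resid2(x):
            return np.linalg.norm(xy - x[:2], axis=1) - x[2]

        ref = least_squares(resid2, np.r_[c2, r0], method="lm")
        c2, radius = ref.x[:2], float(abs(ref.x[2]))
        center = mean + c2[0] * u + c2[1] * v
        rms = float(np.sqrt(np.mean(resid2(ref.x) ** 2)))
        return CorEstimate(center=center, radius=radius, rms_residual=rms,
                           model="circle", plane_normal=normal)
    raise ValueError(f"unknown model {model!r}; expected 'sphere' or 'circle'")
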