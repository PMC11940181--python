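"""Geometry containers, file I/O and point-cloud/mesh utilities.

Units are millimetres throughout; masses in grams (density in g/mm^3).
Coordinates are right-handed. For hand fixtures the convention is
+x radial, +y distal (towards the fingertips), +z dorsal.

The containers are light dataclasses; heavy lifting (I/O, proximity
queries, mass properties) is delegated to :mod:`trimesh`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh
from scipy.spatial import cKDTree


class GeometryFormatError(ValueError):
    """Raised when a geometry file cannot be parsed under its format."""


class WatertightError(ValueError):
    """Raised when an operation requires a closed, consistently oriented mesh."""


@dataclass
class PointCloud:
    """Unordered 3D points (mm) with optional unit normals and view labels."""

    points: np.ndarray
    normals: np.ndarray | None = None
    view_id: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        if not np.all(np.isfinite(self.points)):
            raise ValueError("point coordinates must be finite")
        if self.normals is not None:
            self.normals = np.asarray(self.normals, dtype=float).reshape(-1, 3)
            if len(self.normals) != len(self.points):
                raise ValueError("normals must match points in length")
            norms = np.linalg.norm(self.normals, axis=1)
            if np.any(np.abs(norms - 1.0) > 1e-6):
                raise ValueError("normals must be unit length within 1e-6")
        if self.view_id is not None:
            self.view_id = np.asarray(self.view_id, dtype=int).reshape(-1)
            if len(self.view_id) != len(self.points):
                raise ValueError("view_id must match points in length")

    def __len__(self) -> int:
        return len(self.points)

    def select(self, mask: np.ndarray) -> "PointCloud":
        return PointCloud(
            self.points[mask],
            None if self.normals is None else self.normals[mask],
            None if self.view_id is None else self.view_id[mask],
        )


@dataclass
class TriangleMesh:
    """Triangle mesh: vertices (mm), faces (vertex index triples), vertex normals."""

    vertices: np.ndarray
    faces: np.ndarray
    _tm: trimesh.Trimesh | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if len(self.faces) and self.faces.max() >= len(self.vertices):
            raise ValueError("face indices out of range")
        if len(self.faces) and self.faces.min() < 0:
            raise ValueError("negative face index")

    @property
    def trimesh(self) -> trimesh.Trimesh:
        if self._tm is None:
            self._tm = trimesh.Trimesh(
                vertices=self.vertices, faces=self.faces, process=False
            )
        return self._tm

    @property
    def vertex_normals(self) -> np.ndarray:
        return np.asarray(self.trimesh.vertex_normals)

    @property
    def is_watertight(self) -> bool:
        return bool(self.trimesh.is_watertight)

    def copy(self) -> "TriangleMesh":
        return TriangleMesh(self.vertices.copy(), self.faces.copy())

    def transformed(self, matrix: np.ndarray) -> "TriangleMesh":
        """Apply a 4x4 homogeneous transform and return a new mesh."""
        matrix = np.asarray(matrix, dtype=float)
        v = self.vertices @ matrix[:3, :3].T + matrix[:3, 3]
        return TriangleMesh(v, self.faces.copy())

    @classmethod
    def from_trimesh(cls, tm: trimesh.Trimesh) -> "TriangleMesh":
        out = cls(np.asarray(tm.vertices), np.asarray(tm.faces))
        out._tm = tm
        return out


@dataclass
class DeviationReport:
    """Per-point distances (mm) from reference points to a model surface."""

    distances: np.ndarray
    max: float
    mean: float
    signed: bool = False

    def __post_init__(self) -> None:
        self.distances = np.asarray(self.distances, dtype=float).reshape(-1)


_MESH_FORMATS = {"ply", "stl", "obj"}


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt.lower()
    suffix = path.suffix.lower().lstrip(".")
    if suffix not in _MESH_FORMATS | {"xyz"}:
        raise GeometryFormatError(f"cannot infer format from suffix {path.suffix!r}")
    return suffix


def read_geometry(path, fmt: str | None = None) -> PointCloud | TriangleMesh:
    """Read PLY/STL/OBJ meshes or XYZ point clouds.

    XYZ files are whitespace-separated ``x y z [nx ny nz]`` lines; the mesh
    formats go through trimesh.  A PLY without faces loads as a PointCloud.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _infer_format(path, fmt)
    if fmt == "xyz":
        try:
            data = np.loadtxt(path, ndmin=2)
        except ValueError as exc:
            raise GeometryFormatError(f"{path}: not a valid XYZ file: {exc}") from exc
        if data.size == 0:
            return PointCloud(np.empty((0, 3)))
        if data.shape[1] not in (3, 6):
            raise GeometryFormatError(
                f"{path}: expected 3 or 6 columns, got {data.shape[1]}"
            )
        normals = data[:, 3:6] if data.shape[1] == 6 else None
        return PointCloud(data[:, :3], normals)
    if fmt == "stl":
        _validate_stl(path)
    try:
        loaded = trimesh.load(str(path), file_type=fmt, process=False, force="mesh")
    except Exception as exc:  # noqa: BLE001 - normalise loader errors
        raise GeometryFormatError(f"{path}: failed to parse as {fmt}: {exc}") from exc
    if isinstance(loaded, trimesh.PointCloud) or (
        hasattr(loaded, "faces") and len(loaded.faces) == 0
    ):
        return PointCloud(np.asarray(loaded.vertices))
    if not isinstance(loaded, trimesh.Trimesh):
        raise GeometryFormatError(f"{path}: did not load to a triangle mesh")
    return TriangleMesh.from_trimesh(loaded)


def _validate_stl(path: Path) -> None:
    """Reject truncated STL files before handing them to the loader."""
    data = path.read_bytes()
    if data[:5].lower() == b"solid" and b"facet" in data[:500]:
        if b"endsolid" not in data:
            raise GeometryFormatError(f"{path}: truncated ASCII STL (no endsolid)")
        return
    if len(data) < 84:
        raise GeometryFormatError(f"{path}: binary STL shorter than its header")
    n = int.from_bytes(data[80:84], "little")
    expected = 84 + 50 * n
    if len(data) < expected:
        raise GeometryFormatError(
            f"{path}: binary STL truncated at byte {len(data)} of {expected}"
        )


def write_geometry(obj: PointCloud | TriangleMesh, path, fmt: str | None = None) -> None:
    """Write a mesh (PLY/STL/OBJ) or point cloud (XYZ, or PLY without faces)."""
    path = Path(path)
    fmt = _infer_format(path, fmt)
    if isinstance(obj, PointCloud):
        if fmt == "xyz":
            cols = obj.points if obj.normals is None else np.hstack(
                [obj.points, obj.normals]
            )
            np.savetxt(path, cols, fmt="%.9g")
            return
        if fmt == "ply":
            trimesh.PointCloud(obj.points).export(str(path), file_type="ply")
            return
        raise GeometryFormatError(f"point clouds support xyz/ply, not {fmt}")
    if fmt == "xyz":
        raise GeometryFormatError("meshes cannot be written to xyz")
    obj.trimesh.export(str(path), file_type=fmt)


def clean_cloud(
    cloud: PointCloud, k_neighbors: int = 16, sigma_mult: float = 2.5
) -> PointCloud:
    """Statistical outlier removal on a point cloud.

    A point is dropped when its mean distance to its ``k_neighbors`` nearest
    neighbours exceeds ``mean + sigma_mult * std`` of that statistic over
    the whole cloud.  Point order is preserved.

    Like all statistical outlier filters, aggressive thresholds (small
    ``sigma_mult``) keep shaving the distribution tail under repeated
    application; with outliers well separated from the bulk the filter is
    idempotent.
    """
    n = len(cloud)
    if n == 0:
        warnings.warn("clean_cloud called on an empty cloud", stacklevel=2)
        return cloud
    if n < k_neighbors + 1:
        raise ValueError(
            f"cloud has {n} points, need at least k_neighbors+1={k_neighbors + 1}"
        )
    tree = cKDTree(cloud.points)
    # query k+1 because the nearest neighbour of each point is itself
    dists, _ = tree.query(cloud.points, k=k_neighbors + 1)
    mean_knn = dists[:, 1:].mean(axis=1)
    cutoff = mean_knn.mean() + sigma_mult * mean_knn.std()
    return cloud.select(mean_knn <= cutoff)


def merge_clouds(clouds: list[PointCloud], voxel: float) -> PointCloud:
    """Merge co-registered clouds by voxel-grid decimation.

    Points are binned on a regular grid of pitch ``voxel`` and each occupied
    voxel is replaced by the centroid of its points.  Output order follows
    the lexicographically sorted voxel keys, so the result is independent of
    input ordering.
    """
    if voxel <= 0:
        raise ValueError("voxel must be > 0")
    pts = [c.points for c in clouds if len(c)]
    if not pts:
        return PointCloud(np.empty((0, 3)))
    allpts = np.vstack(pts)
    keys = np.floor(allpts / voxel).astype(np.int64)
    order = np.lexsort((keys[:, 2], keys[:, 1], keys[:, 0]))
    keys = keys[order]
    allpts = allpts[order]
    uniq, inverse, counts = np.unique(
        keys, axis=0, return_inverse=True, return_counts=True
    )
    sums = np.zeros((len(uniq), 3))
    np.add.at(sums, inverse, allpts)
    return PointCloud(sums / counts[:, None])


def _open_edge_count(mesh: TriangleMesh) -> int:
    edges = mesh.trimesh.edges_sorted
    _, counts = np.unique(edges, axis=0, return_counts=True)
    return int(np.sum(counts == 1))


def mass_properties(mesh: TriangleMesh, density: float = 1e-3):
    """Volume (mm^3), mass (g), centroid (mm) and inertia tensor (g*mm^2).

    Divergence-theorem integrals over the closed surface; the mesh must be
    watertight and consistently outward-oriented.
    """
    tm = mesh.trimesh
    if not tm.is_watertight:
        raise WatertightError(
            f"mesh is not watertight ({_open_edge_count(mesh)} open edges)"
        )
    if tm.volume < 0:
        tm = tm.copy()
        tm.invert()
    volume = float(tm.volume)
    centroid = np.asarray(tm.center_mass, dtype=float)
    inertia = np.asarray(tm.moment_inertia, dtype=float) * density
    return volume, volume * density, centroid, inertia


def _closest_point_on_triangles(p: np.ndarray, tri: np.ndarray) -> np.ndarray:
    """Closest point on each triangle (n,3,3) to each point (n,3), paired.

    Vectorised barycentric clamping (Ericson, Real-Time Collision
    Detection): exact for all Voronoi regions of the triangle.
    """
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    ab = b - a
    ac = c - a
    ap = p - a
    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = p - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = p - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)
    out = np.empty_like(p)
    done = np.zeros(len(p), dtype=bool)

    m = (d1 <= 0) & (d2 <= 0)  # vertex a
    out[m] = a[m]
    done |= m
    m = ~done & (d3 >= 0) & (d4 <= d3)  # vertex b
    out[m] = b[m]
    done |= m
    m = ~done & (d6 >= 0) & (d5 <= d6)  # vertex c
    out[m] = c[m]
    done |= m
    vc = d1 * d4 - d3 * d2
    m = ~done & (vc <= 0) & (d1 >= 0) & (d3 <= 0)  # edge ab
    with np.errstate(invalid="ignore", divide="ignore"):
        t = d1 / (d1 - d3)
    out[m] = a[m] + t[m, None] * ab[m]
    done |= m
    vb = d5 * d2 - d1 * d6
    m = ~done & (vb <= 0) & (d2 >= 0) & (d6 <= 0)  # edge ac
    with np.errstate(invalid="ignore", divide="ignore"):
        t = d2 / (d2 - d6)
    out[m] = a[m] + t[m, None] * ac[m]
    done |= m
    va = d3 * d6 - d5 * d4
    m = ~done & (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)  # edge bc
    with np.errstate(invalid="ignore", divide="ignore"):
        t = (d4 - d3) / ((d4 - d3) + (d5 - d6))
    out[m] = b[m] + t[m, None] * (c[m] - b[m])
    done |= m
    m = ~done  # interior
    denom = va + vb + vc
    with np.errstate(invalid="ignore", divide="ignore"):
        v = vb / denom
        w = vc / denom
    out[m] = a[m] + v[m, None] * ab[m] + w[m, None] * ac[m]
    return out


def closest_on_surface(mesh: TriangleMesh, points: np.ndarray):
    """Exact nearest surface point, distance and face index per query point.

    Candidate faces are bounded through a KD-tree over face centroids (a
    face can only be nearest if its centroid lies within the best
    centroid distance plus two face circumradii), then resolved exactly.
    """
    points = np.asarray(points, dtype=float).reshape(-1, 3)
    tm = mesh.trimesh
    tri = mesh.vertices[mesh.faces]
    centroids = tri.mean(axis=1)
    rface = np.linalg.norm(tri - centroids[:, None, :], axis=2).max(axis=1)
    rmax = float(rface.max())
    tree = cKDTree(centroids)
    d0, _ = tree.query(points)
    dist = np.empty(len(points))
    closest = np.empty_like(points)
    face_id = np.empty(len(points), dtype=np.int64)
    groups = tree.query_ball_point(points, d0 + 2 * rmax + 1e-12)
    for i, cand in enumerate(groups):
        cand = np.asarray(cand, dtype=np.int64)
        p = np.broadcast_to(points[i], (len(cand), 3))
        cp = _closest_point_on_triangles(np.ascontiguousarray(p), tri[cand])
        d = np.linalg.norm(cp - points[i], axis=1)
        j = int(np.argmin(d))
        dist[i] = d[j]
        closest[i] = cp[j]
        face_id[i] = cand[j]
    return closest, dist, face_id


def signed_surface_distance(mesh: TriangleMesh, points: np.ndarray) -> np.ndarray:
    """Signed distance to a closed mesh surface: positive inside.

    The sign comes from the face normal at the exact closest point; for
    the watertight, finely meshed bodies this toolkit handles the
    nearest-face normal disambiguates inside/outside reliably.
    """
    closest, dist, fid = closest_on_surface(mesh, points)
    normals = np.asarray(mesh.trimesh.face_normals)[fid]
    outside = np.einsum("ij,ij->i", np.asarray(points) - closest, normals) > 0
    return np.where(outside, -dist, dist)


def deviation_map(
    model: TriangleMesh, reference: PointCloud, signed: bool = False
) -> DeviationReport:
    """Nearest point-to-surface distance from each reference point to the model.

    Distances are point-to-triangle.  With ``signed=True`` the sign follows
    the face normal at the closest point (positive outside).
    """
    if len(reference) == 0 or len(model.faces) == 0:
        raise ValueError("deviation_map requires a non-empty model and reference")
    closest, dist, tri_id = closest_on_surface(model, reference.points)
    dist = np.asarray(dist, dtype=float)
    if signed:
        normals = np.asarray(model.trimesh.face_normals)[tri_id]
        sign = np.sign(np.einsum("ij,ij->i", reference.points - closest, normals))
        sign[sign == 0] = 1.0
        dist = dist * sign
    return DeviationReport(
        distances=dist,
        max=float(np.abs(dist).max()),
        mean=float(np.abs(dist).mean()),
        signed=signed,
    )


def interference_check(
    assembly: list[TriangleMesh], clearance: float = 0.0
) -> list[tuple[int, int]]:
    """Find assembly members that penetrate or violate a clearance gap.

    Returns unordered index pairs ``(i, j)`` with ``i < j`` whose surfaces
    intersect or come closer than ``clearance`` mm.  Proximity is evaluated
    at mesh vertices, so members should be meshed finely relative to the
    clearance of interest.
    """
    for idx, m in enumerate(assembly):
        if not m.is_watertight:
            raise WatertightError(f"assembly member {idx} is not watertight")
    pairs: list[tuple[int, int]] = []
    boxes = [(m.vertices.min(axis=0), m.vertices.max(axis=0)) for m in assembly]
    for i in range(len(assembly)):
        for j in range(i + 1, len(assembly)):
            lo_i, hi_i = boxes[i]
            lo_j, hi_j = boxes[j]
            if np.any(lo_i > hi_j + clearance) or np.any(lo_j > hi_i + clearance):
                continue
            if _surfaces_too_close(assembly[i], assembly[j], clearance):
                pairs.append((i, j))
    return pairs


def _surfaces_too_close(a: TriangleMesh, b: TriangleMesh, clearance: float) -> bool:
    # signed distance is positive inside the mesh
    sd_ab = signed_surface_distance(b, a.vertices)
    if np.max(sd_ab) > -clearance:
        return True
    sd_ba = signed_surface_distance(a, b.vertices)
    return bool(np.max(sd_ba) > -clearance)


def smooth_mesh(mesh: TriangleMesh, iterations: int = 80) -> TriangleMesh:
    """Taubin (volume-preserving) smoothing, the cleaning step for noisy scans."""
    tm = mesh.trimesh.copy()
    trimesh.smoothing.filter_taubin(tm, iterations=iterations)
    return TriangleMesh.from_trimesh(tm)


def repair_mesh(mesh: TriangleMesh, weld_tol: float = 1e-6) -> TriangleMesh:
    """Weld duplicate vertices, drop degenerate faces, and fix winding."""
    tm = trimesh.Trimesh(
        vertices=mesh.vertices.copy(), faces=mesh.faces.copy(), process=False
    )
    tm.merge_vertices(digits_vertex=max(1, int(round(-np.log10(weld_tol)))))
    tm.update_faces(tm.nondegenerate_faces())
    tm.remove_unreferenced_vertices()
    trimesh.repair.fix_winding(tm)
    if tm.is_watertight and tm.volume < 0:
        tm.invert()
    return TriangleMesh.from_trimesh(tm)
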