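"""Shared fixtures: analytic surfaces with known curvature, and the
(expensive) default skeleton and reference trajectory bundle."""

from __future__ import annotations

import numpy as np
import pytest
import trimesh

from rebiom.geometry import TriangleMesh


def grid_mesh(height_fn, n: int = 40, span: float = 10.0, center: bool = True):
    """Triangulated height-field z = f(x, y) over a square grid."""
    lin = np.linspace(0, span, n)
    if center:
        lin = lin - span / 2.0
    gx, gy = np.meshgrid(lin, lin, indexing="ij")
    gz = height_fn(gx, gy)
    V = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    faces = []
    for i in range(n - 1):
        for j in range(n - 1):
            a = i * n + j
            b = (i + 1) * n + j
            c = (i + 1) * n + j + 1
            d = i * n + j + 1
            faces.append([a, c, b])
            faces.append([a, d, c])
    mesh = TriangleMesh(V, np.asarray(faces))
    if mesh.trimesh.face_normals[:, 2].mean() < 0:
        mesh = TriangleMesh(V, np.asarray(faces)[:, ::-1])
    return mesh


def interior_mask(mesh: TriangleMesh, margin: float = 0.2) -> np.ndarray:
    """Vertices away from the open boundary (fraction of the bbox span)."""
    v = mesh.vertices
    lo = v.min(axis=0)
    hi = v.max(axis=0)
    pad = margin * (hi - lo)
    keep = np.ones(len(v), dtype=bool)
    for k in range(2):
        keep &= (v[:, k] > lo[k] + pad[k]) & (v[:, k] < hi[k] - pad[k])
    return keep


def revolved_cylinder(radius: float = 5.0, height: float = 30.0,
                      n_axial: int = 30, n_circ: int = 48) -> TriangleMesh:
    """Open cylinder wall with axial subdivisions (no caps)."""
    theta = np.linspace(0, 2 * np.pi, n_circ, endpoint=False)
    ys = np.linspace(0, height, n_axial)
    verts = []
    for y in ys:
        verts.append(np.column_stack(
            [radius * np.cos(theta), np.full(n_circ, y), radius * np.sin(theta)]
        ))
    V = np.vstack(verts)
    faces = []
    for i in range(n_axial - 1):
        a0 = i * n_circ
        b0 = (i + 1) * n_circ
        for j in range(n_circ):
            j1 = (j + 1) % n_circ
            faces.append([a0 + j, b0 + j, b0 + j1])
            faces.append([a0 + j, b0 + j1, a0 + j1])
    return TriangleMesh(V, np.asarray(faces))


@pytest.fixture(scope="session")
def sphere10() -> TriangleMesh:
    return TriangleMesh.from_trimesh(trimesh.creation.icosphere(3, 10.0))


@pytest.fixture(scope="session")
def plane_grid() -> TriangleMesh:
    return grid_mesh(lambda x, y: np.zeros_like(x))


@pytest.fixture(scope="session")
def saddle_grid() -> TriangleMesh:
    return grid_mesh(lambda x, y: x * y / 5.0)


@pytest.fixture(scope="session")
def cylinder5() -> TriangleMesh:
    return revolved_cylinder()


@pytest.fixture(scope="session")
def skeleton():
    from rebiom.fixtures import gen_skeleton
    from rebiom.hand import build_skeleton

    return build_skeleton(gen_skeleton(seed=0))


@pytest.fixture(scope="session")
def bundle(skeleton):
    from rebiom.trajectories import gen_trajectories

    return gen_trajectories(skeleton)


@pytest.fixture(scope="session")
def default_bone():
    from rebiom.fixtures import BoneSpec, gen_bone

    return gen_bone(BoneSpec())
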