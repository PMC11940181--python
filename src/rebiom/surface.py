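"""B-spline curve-network and surface fitting with fairing.

Free-form reconstruction of segmented regions: least-squares cubic
B-spline curves through boundary loops and section polylines, and
penalised least-squares tensor-product B-spline surfaces over a
principal-plane parameterisation, with a thin-plate-style second
difference penalty on the control net for fairing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.interpolate import BSpline
from scipy.sparse.linalg import spsolve


@dataclass
class BsplineCurve:
    degree: int
    knots: np.ndarray
    control_points: np.ndarray  # (n, 3)

    def evaluate(self, t) -> np.ndarray:
        t = np.atleast_1d(np.asarray(t, dtype=float))
        B = BSpline.design_matrix(
            np.clip(t, self.knots[self.degree], self.knots[-self.degree - 1]),
            self.knots,
            self.degree,
        )
        return B @ self.control_points


@dataclass
class BsplineSurface:
    degrees: tuple[int, int]
    knots_u: np.ndarray
    knots_v: np.ndarray
    control_net: np.ndarray  # (nu, nv, 3)

    def evaluate(self, u, v) -> np.ndarray:
        """Evaluate at paired parameters (u_i, v_i)."""
        u = np.atleast_1d(np.asarray(u, dtype=float))
        v = np.atleast_1d(np.asarray(v, dtype=float))
        du, dv = self.degrees
        Bu = BSpline.design_matrix(
            np.clip(u, self.knots_u[du], self.knots_u[-du - 1]), self.knots_u, du
        ).tocsr()
        Bv = BSpline.design_matrix(
            np.clip(v, self.knots_v[dv], self.knots_v[-dv - 1]), self.knots_v, dv
        ).tocsr()
        nu, nv, _ = self.control_net.shape
        P = self.control_net.reshape(nu * nv, 3)
        out = np.empty((len(u), 3))
        for i in range(len(u)):
            w = np.outer(
                Bu[i].toarray().ravel(), Bv[i].toarray().ravel()
            ).ravel()
            out[i] = w @ P
        return out

    def to_dict(self) -> dict:
        return {
            "degrees": list(self.degrees),
            "knots_u": self.knots_u.tolist(),
            "knots_v": self.knots_v.tolist(),
            "control_net": self.control_net.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BsplineSurface":
        return cls(
            degrees=tuple(d["degrees"]),
            knots_u=np.asarray(d["knots_u"], dtype=float),
            knots_v=np.asarray(d["knots_v"], dtype=float),
            control_net=np.asarray(d["control_net"], dtype=float),
        )


@dataclass
class FitReport:
    max_deviation: float
    mean_deviation: float
    control_point_count: int
    smoothing_weight: float


def _clamped_knots(n_ctrl: int, degree: int) -> np.ndarray:
    if n_ctrl < degree + 1:
        raise ValueError(f"need at least degree+1={degree + 1} control points")
    n_int = n_ctrl - degree - 1
    interior = np.linspace(0, 1, n_int + 2)[1:-1]
    return np.r_[np.zeros(degree + 1), interior, np.ones(degree + 1)]


def chord_length_parameterise(points: np.ndarray) -> np.ndarray:
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    t = np.r_[0.0, np.cumsum(seg)]
    total = t[-1]
    if total == 0:
        raise ValueError("degenerate polyline (zero length)")
    return t / total


def fit_curve(
    polyline: np.ndarray, n_ctrl: int = 12, degree: int = 3
) -> tuple[BsplineCurve, FitReport]:
    """Least-squares clamped B-spline through a polyline.

    Chord-length parameterisation; the first and last control points are
    pinned to the polyline endpoints so the curve interpolates them.
    """
    pts = np.asarray(polyline, dtype=float).reshape(-1, 3)
    if len(pts) < degree + 1:
        raise ValueError(
            f"polyline has {len(pts)} points; need >= degree+1 = {degree + 1}"
        )
    n_ctrl = min(n_ctrl, len(pts))
    knots = _clamped_knots(n_ctrl, degree)
    t = chord_length_parameterise(pts)
    B = BSpline.design_matrix(
        np.clip(t, 0.0, 1.0 - 1e-12), knots, degree
    ).toarray()
    # pin endpoint control points: move their contribution to the RHS
    interior = slice(1, n_ctrl - 1)
    rhs = pts - np.outer(B[:, 0], pts[0]) - np.outer(B[:, -1], pts[-1])
    sol, *_ = np.linalg.lstsq(B[:, interior], rhs, rcond=None)
    ctrl = np.vstack([pts[0], sol, pts[-1]])
    curve = BsplineCurve(degree=degree, knots=knots, control_points=ctrl)
    dev = np.linalg.norm(curve.evaluate(t) - pts, axis=1)
    report = FitReport(
        max_deviation=float(dev.max()),
        mean_deviation=float(dev.mean()),
        control_point_count=n_ctrl,
        smoothing_weight=0.0,
    )
    return curve, report


def fit_curve_network(polylines, n_ctrl: int = 12, degree: int = 3):
    """Fit one B-spline per polyline (boundary loops, section curves)."""
    return [fit_curve(p, n_ctrl=n_ctrl, degree=degree) for p in polylines]


def pca_parameterise(points: np.ndarray):
    """(u, v) in [0, 1]^2 by projection onto the point set's principal plane.

    The in-plane directions come from the covariance eigenvectors with a
    deterministic, rigid-motion-equivariant sign rule (the point farthest
    from the centroid along each direction projects positively).
    """
    pts = np.asarray(points, dtype=float)
    c = pts.mean(axis=0)
    rel = pts - c
    _, _, vt = np.linalg.svd(rel, full_matrices=False)
    dirs = vt[:2]
    for k in range(2):
        p = rel @ dirs[k]
        if p[np.argmax(np.abs(p))] < 0:
            dirs[k] = -dirs[k]
    uv = rel @ dirs.T
    lo = uv.min(axis=0)
    span = uv.max(axis=0) - lo
    span[span == 0] = 1.0
    return (uv - lo) / span


def _second_difference_penalty(nu: int, nv: int) -> sparse.csr_matrix:
    """Thin-plate-style penalty: squared second differences over the net."""
    def d2(n):
        if n < 3:
            return sparse.csr_matrix((0, n))
        data = np.tile([1.0, -2.0, 1.0], (n - 2, 1))
        return sparse.diags(
            [data[:, 0], data[:, 1], data[:, 2]], [0, 1, 2], shape=(n - 2, n)
        ).tocsr()
    Iu = sparse.eye(nu, format="csr")
    Iv = sparse.eye(nv, format="csr")
    Du = sparse.kron(d2(nu), Iv)
    Dv = sparse.kron(Iu, d2(nv))
    return (Du.T @ Du + Dv.T @ Dv).tocsr()


def fit_surface(
    points: np.ndarray,
    degrees: tuple[int, int] = (3, 3),
    net: tuple[int, int] = (8, 8),
    smoothing: float = 1e-3,
    uv: np.ndarray | None = None,
) -> tuple[BsplineSurface, FitReport]:
    """Penalised least-squares tensor-product B-spline surface.

    Minimises ``||B P - X||^2 + lambda * ||D2 P||^2`` where B is the
    tensor-product basis at the data parameters, P the control net and D2
    second differences along both net directions.  Coordinates are
    normalised to the bounding-box diagonal during the solve, making the
    default ``smoothing`` weight dimensionless.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    nu, nv = net
    du, dv = degrees
    if len(pts) < nu * nv and smoothing == 0:
        raise ValueError("fewer points than control points; increase smoothing")
    if uv is None:
        uv = pca_parameterise(pts)
    u, v = uv[:, 0], uv[:, 1]
    ku = _clamped_knots(nu, du)
    kv = _clamped_knots(nv, dv)
    Bu = BSpline.design_matrix(np.clip(u, 0, 1 - 1e-12), ku, du).tocsr()
    Bv = BSpline.design_matrix(np.clip(v, 0, 1 - 1e-12), kv, dv).tocsr()
    # row-wise Khatri-Rao product gives the tensor basis at each datum
    B = _row_kron(Bu, Bv)
    scale = float(np.linalg.norm(pts.max(axis=0) - pts.min(axis=0)))
    scale = scale if scale > 0 else 1.0
    X = pts / scale
    P2 = _second_difference_penalty(nu, nv)
    A = (B.T @ B + smoothing * P2).tocsc()
    rhs = B.T @ X
    try:
        P = spsolve(A, rhs)
    except Exception as exc:  # singular at lambda=0
        raise ValueError(
            "rank-deficient fit; increase smoothing or reduce the control net"
        ) from exc
    if P.ndim == 1:
        P = P.reshape(-1, 3)
    if not np.all(np.isfinite(P)):
        raise ValueError(
            "rank-deficient fit; increase smoothing or reduce the control net"
        )
    surf = BsplineSurface(
        degrees=(du, dv),
        knots_u=ku,
        knots_v=kv,
        control_net=(P * scale).reshape(nu, nv, 3),
    )
    dev = np.linalg.norm(surf.evaluate(u, v) - pts, axis=1)
    report = FitReport(
        max_deviation=float(dev.max()),
        mean_deviation=float(dev.mean()),
        control_point_count=nu * nv,
        smoothing_weight=smoothing,
    )
    return surf, report


def _row_kron(A: sparse.csr_matrix, B: sparse.csr_matrix) -> sparse.csr_matrix:
    """Row-wise Kronecker product of two sparse matrices with equal row counts."""
    n = A.shape[0]
    rows = []
    for i in range(n):
        rows.append(sparse.kron(A[i], B[i], format="csr"))
    return sparse.vstack(rows, format="csr")


def control_net_roughness(surface: BsplineSurface) -> float:
    """Sum of squared second differences of the control net (fairness proxy)."""
    nu, nv, _ = surface.control_net.shape
    P = surface.control_net.reshape(nu * nv, 3)
    P2 = _second_difference_penalty(nu, nv)
    return float(np.einsum("ij,ij->", P, P2 @ P))


def surface_boundaries(surface: BsplineSurface, n: int = 100) -> list[np.ndarray]:
    """The four boundary curves sampled with n points each."""
    s = np.linspace(0, 1, n)
    z = np.zeros(n)
    o = np.ones(n)
    return [
        surface.evaluate(s, z),
        surface.evaluate(s, o),
        surface.evaluate(z, s),
        surface.evaluate(o, s),
    ]


@dataclass
class StitchReport:
    shared_pairs: list[tuple[int, int, int, int, float]]  # (si, side_i, sj, side_j, gap)
    max_gap: float
    passed: bool


def stitch_and_validate(
    surfaces: list[BsplineSurface],
    tol: float,
    n_samples: int = 100,
    adjacency_frac: float = 0.25,
) -> StitchReport:
    """Check watertightness of a patch collection along shared boundaries.

    Boundary curves of all patches are sampled; two boundary curves from
    different patches count as *shared* when their symmetric mean distance
    is below ``adjacency_frac`` times the shorter curve's length.  The gap
    of a shared pair is the maximum sample-to-nearest-sample distance;
    the report passes iff every shared pair's gap is <= ``tol``.
    """
    from scipy.spatial import cKDTree

    bounds = [surface_boundaries(s, n_samples) for s in surfaces]
    shared = []
    max_gap = 0.0
    for i in range(len(surfaces)):
        for j in range(i + 1, len(surfaces)):
            for bi, ci in enumerate(bounds[i]):
                for bj, cj in enumerate(bounds[j]):
                    ti, tj = cKDTree(ci), cKDTree(cj)
                    dij, _ = tj.query(ci)
                    dji, _ = ti.query(cj)
                    mean_d = 0.5 * (dij.mean() + dji.mean())
                    li = np.linalg.norm(np.diff(ci, axis=0), axis=1).sum()
                    lj = np.linalg.norm(np.diff(cj, axis=0), axis=1).sum()
                    if mean_d <= adjacency_frac * max(min(li, lj), 1e-12):
                        gap = float(max(dij.max(), dji.max()))
                        shared.append((i, bi, j, bj, gap))
                        max_gap = max(max_gap, gap)
    return StitchReport(
        shared_pairs=shared,
        max_gap=max_gap,
        passed=bool(shared) and max_gap <= tol,
    )
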