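"""Per-vertex principal curvatures and the HK / SC shape classifications.

Two classification schemes operate on the principal curvatures k1 >= k2:

* **HK** — the sign pattern of mean curvature ``H = (k1 + k2)/2`` and
  Gaussian curvature ``K = k1 * k2`` yields eight surface types (plus one
  impossible cell, H = 0 with K > 0, labelled ``invalid``).
* **SC** — the shape index ``S = -(2/pi) * atan((k1 + k2)/(k1 - k2))``
  and curvedness ``C = sqrt((k1^2 + k2^2)/2)``.  S lives in [-1, 1] with
  critical points at 0, +/-0.5 and +/-1 where the shape class changes;
  C = 0 marks flat regions where S is unspecified.

Sign convention: a region bulging along the *outward* normal (convex) has
k1, k2 < 0, so H < 0 marks convex and H > 0 concave.  Under this
convention S = +1 on a convex spherical cap and S = -1 on a concave cup.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy.spatial import cKDTree

from .geometry import TriangleMesh


class ShapeLabel(Enum):
    CONVEX_ELLIPTICAL = "convex_elliptical"
    CONVEX_CYLINDER = "convex_cylinder"
    SADDLE_RIDGE = "saddle_ridge"
    PLANAR = "planar"
    SADDLE_SYMMETRY = "saddle_symmetry"
    CONCAVE_ELLIPTICAL = "concave_elliptical"
    CONCAVE_CYLINDER = "concave_cylinder"
    SADDLE_VALLEY = "saddle_valley"
    INVALID = "invalid"


CONVEX_LABELS = {ShapeLabel.CONVEX_ELLIPTICAL, ShapeLabel.CONVEX_CYLINDER}
SADDLE_LABELS = {
    ShapeLabel.SADDLE_RIDGE,
    ShapeLabel.SADDLE_SYMMETRY,
    ShapeLabel.SADDLE_VALLEY,
}
CONCAVE_LABELS = {ShapeLabel.CONCAVE_ELLIPTICAL, ShapeLabel.CONCAVE_CYLINDER}


@dataclass
class CurvatureField:
    """Per-vertex curvature descriptors.

    ``k1 >= k2`` everywhere (1/mm); ``H`` (1/mm) and ``K`` (1/mm^2) are the
    mean and Gaussian curvatures; ``S`` is the dimensionless shape index in
    [-1, 1] (NaN where unspecified, i.e. k1 = k2 = 0); ``C >= 0`` (1/mm) is
    the curvedness.  ``defined`` flags vertices with a valid estimate.
    """

    k1: np.ndarray
    k2: np.ndarray
    H: np.ndarray
    K: np.ndarray
    S: np.ndarray
    C: np.ndarray
    defined: np.ndarray

    def __len__(self) -> int:
        return len(self.k1)


def shape_index(k1, k2):
    """Shape index S in [-1, 1].

    ``S = -(2/pi) * arctan((k1 + k2) / (k1 - k2))`` with the arguments
    reordered so k1 >= k2.  At umbilics (k1 = k2 != 0) the 0/0 form is
    resolved by continuity: S -> sign(-(k1 + k2)).  At k1 = k2 = 0 the
    index is unspecified and NaN is returned.
    """
    k1 = np.asarray(k1, dtype=float)
    k2 = np.asarray(k2, dtype=float)
    lo = np.minimum(k1, k2)
    hi = np.maximum(k1, k2)
    ssum = hi + lo
    diff = hi - lo
    with np.errstate(divide="ignore", invalid="ignore"):
        s = -(2.0 / np.pi) * np.arctan(ssum / diff)
    umbilic = diff == 0
    s = np.where(umbilic, np.sign(-ssum), s)
    s = np.where(umbilic & (ssum == 0), np.nan, s)
    return s if s.ndim else float(s)


def curvedness(k1, k2):
    """Curvedness C = sqrt((k1^2 + k2^2) / 2) >= 0, zero only at flat points."""
    k1 = np.asarray(k1, dtype=float)
    k2 = np.asarray(k2, dtype=float)
    c = np.sqrt((k1 * k1 + k2 * k2) / 2.0)
    return c if c.ndim else float(c)


def hk_classify(H, K, eps_h: float, eps_k: float):
    """Classify by the sign pattern of mean and Gaussian curvature.

    ``|H| <= eps_h`` is treated as H = 0 and ``|K| <= eps_k`` as K = 0.
    The cell H = 0 with K > 0 is geometrically impossible (K <= H^2) and
    returns ``invalid``.
    """
    if eps_h <= 0 or eps_k <= 0:
        raise ValueError("eps_h and eps_k must be > 0")
    H = np.asarray(H, dtype=float)
    K = np.asarray(K, dtype=float)
    scalar = H.ndim == 0
    H, K = np.atleast_1d(H), np.atleast_1d(K)
    sh = np.where(np.abs(H) <= eps_h, 0, np.sign(H)).astype(int)
    sk = np.where(np.abs(K) <= eps_k, 0, np.sign(K)).astype(int)
    table = {
        (-1, 1): ShapeLabel.CONVEX_ELLIPTICAL,
        (-1, 0): ShapeLabel.CONVEX_CYLINDER,
        (-1, -1): ShapeLabel.SADDLE_RIDGE,
        (0, 1): ShapeLabel.INVALID,
        (0, 0): ShapeLabel.PLANAR,
        (0, -1): ShapeLabel.SADDLE_SYMMETRY,
        (1, 1): ShapeLabel.CONCAVE_ELLIPTICAL,
        (1, 0): ShapeLabel.CONCAVE_CYLINDER,
        (1, -1): ShapeLabel.SADDLE_VALLEY,
    }
    out = np.array([table[(h, k)] for h, k in zip(sh, sk)], dtype=object)
    return out[0] if scalar else out


def sc_classify(S, C, eps_c: float, eps_s: float = 0.05):
    """Classify by shape index and curvedness.

    ``C <= eps_c`` is flat (planar, S unspecified).  Elsewhere S is binned
    at its critical points 0, +/-0.5, +/-1: the open intervals give the
    elliptical and saddle families and a band of half-width ``eps_s``
    around +/-0.5 gives the developable (cylinder) classes; an exact
    boundary value falls in the lower bin.
    """
    if eps_c <= 0:
        raise ValueError("eps_c must be > 0")
    S = np.asarray(S, dtype=float)
    C = np.asarray(C, dtype=float)
    scalar = S.ndim == 0
    S, C = np.atleast_1d(S), np.atleast_1d(C)
    out = np.empty(S.shape, dtype=object)
    out[:] = ShapeLabel.PLANAR
    curved = C > eps_c
    s = S[curved]
    lab = np.empty(s.shape, dtype=object)
    lab[:] = ShapeLabel.SADDLE_SYMMETRY
    lab[(s > 0) & (s < 0.5 - eps_s)] = ShapeLabel.SADDLE_RIDGE
    lab[(s < 0) & (s > -0.5 + eps_s)] = ShapeLabel.SADDLE_VALLEY
    lab[np.abs(s - 0.5) <= eps_s] = ShapeLabel.CONVEX_CYLINDER
    lab[np.abs(s + 0.5) <= eps_s] = ShapeLabel.CONCAVE_CYLINDER
    lab[s > 0.5 + eps_s] = ShapeLabel.CONVEX_ELLIPTICAL
    lab[s < -0.5 - eps_s] = ShapeLabel.CONCAVE_ELLIPTICAL
    lab[np.isnan(s)] = ShapeLabel.PLANAR
    out[curved] = lab
    return out[0] if scalar else out


def _vertex_rings(mesh: TriangleMesh, ring: int) -> list[np.ndarray]:
    """Indices within ``ring`` edge hops of each vertex (excluding itself)."""
    n = len(mesh.vertices)
    adj = [[] for _ in range(n)]
    for a, b in mesh.trimesh.edges_unique:
        adj[a].append(b)
        adj[b].append(a)
    rings = []
    for v in range(n):
        seen = {v}
        frontier = [v]
        for _ in range(ring):
            nxt = []
            for u in frontier:
                for w in adj[u]:
                    if w not in seen:
                        seen.add(w)
                        nxt.append(w)
            frontier = nxt
        seen.discard(v)
        rings.append(np.fromiter(seen, dtype=np.int64))
    return rings


def estimate_principal_curvatures(mesh: TriangleMesh, ring: int = 2) -> CurvatureField:
    """Principal curvatures by local quadric (osculating paraboloid) fits.

    For each vertex the ring-neighbourhood is expressed in a tangent frame
    whose third axis is the outward vertex normal, and a quadric
    ``h(u, v) = a u^2/2 + b u v + c v^2/2 + d u + e v`` is fitted by least
    squares.  The Weingarten map built from the first and second
    fundamental forms of that graph yields k1 >= k2.  With the outward
    normal as height direction, convex regions come out negative.

    Vertices with fewer than 5 usable neighbours are flagged undefined and
    inherit the values of the nearest defined vertex.
    """
    if ring < 1:
        raise ValueError("ring must be >= 1")
    V = mesh.vertices
    N = mesh.vertex_normals
    rings = _vertex_rings(mesh, ring)
    n = len(V)
    k1 = np.full(n, np.nan)
    k2 = np.full(n, np.nan)
    defined = np.zeros(n, dtype=bool)
    # open-boundary vertices get one-sided stencils with biased curvature;
    # flag them and let them inherit the nearest interior estimate instead
    edges = mesh.trimesh.edges_sorted
    uniq, counts = np.unique(edges, axis=0, return_counts=True)
    on_boundary = np.zeros(n, dtype=bool)
    if np.any(counts == 1):
        on_boundary[np.unique(uniq[counts == 1])] = True
    for i in range(n):
        nbr = rings[i]
        if len(nbr) < 5 or on_boundary[i]:
            continue
        nz = N[i]
        # tangent basis orthogonal to the vertex normal
        t = np.array([1.0, 0.0, 0.0])
        if abs(nz[0]) > 0.9:
            t = np.array([0.0, 1.0, 0.0])
        tu = np.cross(nz, t)
        tu /= np.linalg.norm(tu)
        tv = np.cross(nz, tu)
        rel = V[nbr] - V[i]
        u = rel @ tu
        v = rel @ tv
        h = rel @ nz
        A = np.column_stack([0.5 * u * u, u * v, 0.5 * v * v, u, v])
        coef, *_ = np.linalg.lstsq(A, h, rcond=None)
        a, b, c, d, e = coef
        # graph fundamental forms: I from the gradient, II scaled by its norm
        g = 1.0 + d * d + e * e
        inv_sqrt = 1.0 / np.sqrt(g)
        II = np.array([[a, b], [b, c]]) * inv_sqrt
        I = np.array([[1 + d * d, d * e], [d * e, 1 + e * e]])
        W = np.linalg.solve(I, II)
        eigs = np.linalg.eigvals(W)
        eigs = np.sort(np.real(eigs))
        k2[i], k1[i] = eigs[0], eigs[1]
        defined[i] = True
    if not defined.any():
        raise ValueError("no vertex had enough neighbours for a quadric fit")
    if not defined.all():
        starved = int((~defined & ~on_boundary).sum())
        if starved:
            warnings.warn(
                f"{starved} interior vertices had <5 neighbours; "
                "inheriting nearest defined curvature",
                stacklevel=2,
            )
        tree = cKDTree(V[defined])
        _, nearest = tree.query(V[~defined])
        src = np.where(defined)[0][nearest]
        k1[~defined] = k1[src]
        k2[~defined] = k2[src]
    H = 0.5 * (k1 + k2)
    K = k1 * k2
    return CurvatureField(
        k1=k1, k2=k2, H=H, K=K, S=shape_index(k1, k2), C=curvedness(k1, k2),
        defined=defined,
    )


def robust_epsilons(field: CurvatureField, fraction: float = 0.05):
    """Zero-thresholds for classification from the field's robust scale.

    The common scale is the median-absolute curvedness of the field (a
    robust "typical curvature" in 1/mm).  ``eps_h`` and ``eps_c`` are
    ``fraction`` of that scale; ``eps_k``, which lives in 1/mm^2, is
    ``fraction`` times the scale squared.  Deriving all three from the
    curvedness keeps developable surfaces (where |K| itself is pure
    noise) classifiable.  Tiny floors let exact zeros on analytic
    fixtures classify as flat.
    """
    c = field.C[np.isfinite(field.C)]
    scale = float(np.median(np.abs(c))) if len(c) else 0.0
    eps_h = max(fraction * scale, 1e-12)
    eps_k = max(fraction * scale**2, 1e-14)
    eps_c = max(fraction * scale, 1e-12)
    return eps_h, eps_k, eps_c


def classify_field(
    field: CurvatureField,
    scheme: str = "hk",
    eps_h: float | None = None,
    eps_k: float | None = None,
    eps_c: float | None = None,
):
    """Per-vertex shape labels under the chosen scheme ('hk' or 'sc')."""
    auto_h, auto_k, auto_c = robust_epsilons(field)
    scheme = scheme.lower()
    if scheme == "hk":
        return hk_classify(field.H, field.K, eps_h or auto_h, eps_k or auto_k)
    if scheme == "sc":
        return sc_classify(field.S, field.C, eps_c or auto_c)
    raise ValueError(f"unknown scheme {scheme!r}; expected 'hk' or 'sc'")
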