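"""Region segmentation of classified meshes.

Connected-component growth over per-vertex shape classes partitions a mesh
into disjoint regions (tooth cusps, bone feature regions); small regions
are merged into their largest neighbour.  Long bones are additionally
partitioned into head / shaft / base zones from the minima of their
cross-section area profile.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .curvature import CONVEX_LABELS, CurvatureField, ShapeLabel, classify_field
from .geometry import TriangleMesh


@dataclass
class Region:
    region_id: int
    shape_class: ShapeLabel
    vertex_count: int
    area: float
    seed_vertex: int


@dataclass
class RegionLabeling:
    """Per-vertex region ids (>= 0, or -1 unassigned) plus a region table."""

    vertex_region: np.ndarray
    regions: dict[int, Region] = field(default_factory=dict)
    labels: np.ndarray | None = None  # per-vertex ShapeLabel after cleanup


@dataclass
class CuspRecord:
    region_id: int
    apex: np.ndarray
    apex_vertex: int
    area: float
    boundary_loop: np.ndarray  # ordered vertex indices; empty if none
    boundary_closed: bool


@dataclass
class FeaturePartition:
    """head/shaft/base/end labels per vertex plus the axial boundary stations."""

    labels: np.ndarray  # array of strings
    boundary_stations: tuple[float, float]  # axial positions (mm) head|shaft, shaft|base


def _vertex_areas(mesh: TriangleMesh) -> np.ndarray:
    areas = np.zeros(len(mesh.vertices))
    fa = mesh.trimesh.area_faces / 3.0
    for k in range(3):
        np.add.at(areas, mesh.faces[:, k], fa)
    return areas


def _adjacency(mesh: TriangleMesh) -> list[list[int]]:
    adj: list[list[int]] = [[] for _ in range(len(mesh.vertices))]
    for a, b in mesh.trimesh.edges_unique:
        adj[a].append(b)
        adj[b].append(a)
    return adj


def segment_regions(
    mesh: TriangleMesh,
    fld: CurvatureField,
    scheme: str = "hk",
    min_vertices: int = 20,
    **classify_kwargs,
) -> RegionLabeling:
    """Flood-fill same-class connected components of the classified mesh.

    Components smaller than ``min_vertices`` are merged into their
    largest-area neighbouring region (ties broken by lowest region id).
    Deterministic for a fixed vertex order: seeds are taken in index order.
    """
    if not fld.defined.any():
        raise ValueError("curvature field is undefined everywhere")
    labels = classify_field(fld, scheme=scheme, **classify_kwargs)
    n = len(mesh.vertices)
    adj = _adjacency(mesh)
    region = np.full(n, -1, dtype=np.int64)
    next_id = 0
    for seed in range(n):
        if region[seed] >= 0:
            continue
        lab = labels[seed]
        stack = [seed]
        region[seed] = next_id
        while stack:
            u = stack.pop()
            for w in adj[u]:
                if region[w] < 0 and labels[w] == lab:
                    region[w] = next_id
                    stack.append(w)
        next_id += 1
    region, labels = _merge_small(mesh, region, labels, adj, min_vertices)
    areas = _vertex_areas(mesh)
    table: dict[int, Region] = {}
    for rid in np.unique(region):
        mask = region == rid
        seed = int(np.where(mask)[0][0])
        table[int(rid)] = Region(
            region_id=int(rid),
            shape_class=labels[seed],
            vertex_count=int(mask.sum()),
            area=float(areas[mask].sum()),
            seed_vertex=seed,
        )
    return RegionLabeling(vertex_region=region, regions=table, labels=labels)


def _merge_small(mesh, region, labels, adj, min_vertices):
    """Iteratively absorb undersized components into their biggest neighbour."""
    areas = _vertex_areas(mesh)
    labels = labels.copy()
    while True:
        ids, counts = np.unique(region, return_counts=True)
        region_area = {int(r): float(areas[region == r].sum()) for r in ids}
        small = [int(r) for r, c in zip(ids, counts) if c < min_vertices]
        if not small:
            break
        # absorb the smallest first so cascades resolve deterministically
        small.sort(key=lambda r: (region_area[r], r))
        merged_any = False
        for rid in small:
            mask = region == rid
            if mask.sum() >= min_vertices:
                continue  # grew by absorbing another small region
            nbrs: set[int] = set()
            for u in np.where(mask)[0]:
                for w in adj[u]:
                    if region[w] != rid:
                        nbrs.add(int(region[w]))
            if not nbrs:
                continue  # isolated component (whole shell)
            target = max(nbrs, key=lambda r: (region_area[r], -r))
            seed_t = np.where(region == target)[0][0]
            region[mask] = target
            labels[mask] = labels[seed_t]
            region_area[target] += region_area[rid]
            merged_any = True
        if not merged_any:
            break
    # compact ids to 0..m-1 in order of first appearance
    _, compact = np.unique(region, return_inverse=True)
    order = {}
    out = np.empty_like(region)
    nxt = 0
    for i, r in enumerate(region):
        if r not in order:
            order[r] = nxt
            nxt += 1
        out[i] = order[r]
    return out, labels


def _boundary_loop(mesh: TriangleMesh, mask: np.ndarray):
    """Ordered vertex loop around a vertex region; (indices, closed_flag)."""
    # boundary edges: mesh edges with exactly one face inside the region,
    # where a face is inside if all three vertices carry the region label
    faces = mesh.faces
    inside_face = mask[faces].all(axis=1)
    edge_count: dict[tuple[int, int], int] = {}
    for f, inside in zip(faces, inside_face):
        if not inside:
            continue
        for a, b in ((f[0], f[1]), (f[1], f[2]), (f[2], f[0])):
            key = (min(a, b), max(a, b))
            edge_count[key] = edge_count.get(key, 0) + 1
    border = [e for e, c in edge_count.items() if c == 1]
    if not border:
        return np.empty(0, dtype=np.int64), True
    nxt: dict[int, list[int]] = {}
    for a, b in border:
        nxt.setdefault(a, []).append(b)
        nxt.setdefault(b, []).append(a)
    start = min(nxt)
    loop = [start]
    prev = -1
    cur = start
    closed = False
    for _ in range(len(border) + 1):
        cands = [w for w in nxt[cur] if w != prev]
        if not cands:
            break
        prev, cur = cur, cands[0]
        if cur == start:
            closed = True
            break
        loop.append(cur)
    return np.asarray(loop, dtype=np.int64), closed


def extract_cusps(mesh: TriangleMesh, labeling: RegionLabeling) -> list[CuspRecord]:
    """One record per convex region whose apex lies inside the region.

    The apex is the region vertex extreme along the region's mean outward
    normal.  The boundary loop is the closed edge path around the region;
    regions touching the mesh border get a partial (open) loop.
    """
    normals = mesh.vertex_normals
    adj = _adjacency(mesh)
    out: list[CuspRecord] = []
    for rid, reg in sorted(labeling.regions.items()):
        if reg.shape_class not in CONVEX_LABELS:
            continue
        mask = labeling.vertex_region == rid
        idx = np.where(mask)[0]
        mean_n = normals[idx].mean(axis=0)
        nrm = np.linalg.norm(mean_n)
        if nrm < 1e-12:
            # closed shell (e.g. a full sphere): any apex direction works
            mean_n = normals[idx[0]]
        else:
            mean_n /= nrm
        heights = mesh.vertices[idx] @ mean_n
        apex_v = int(idx[np.argmax(heights)])
        # a genuine cusp peaks strictly inside its region; slivers peak on
        # their border and are rejected
        if any(not mask[w] for w in adj[apex_v]):
            continue
        loop, closed = _boundary_loop(mesh, mask)
        out.append(
            CuspRecord(
                region_id=rid,
                apex=mesh.vertices[apex_v].copy(),
                apex_vertex=apex_v,
                area=reg.area,
                boundary_loop=loop,
                boundary_closed=closed,
            )
        )
    return out


def partition_bone_features(
    mesh: TriangleMesh,
    frame,
    n_stations: int = 60,
    head_is_larger_end: bool = True,
) -> FeaturePartition:
    """Partition a long bone into head / shaft / base along its principal axis.

    Cross-section areas are sampled along the primary axis; the local
    minimum of the area profile nearest each extremity (the anatomical
    "neck") sets the head|shaft and shaft|base boundary stations.  The
    extremity with the larger maximal cross-section is the head by default
    (metacarpal/phalanx anatomy); set ``head_is_larger_end=False`` to flip.

    Raises for compact (non-long) bones, which should be treated as single
    regions instead.
    """
    from .rge import cross_sections  # local import to avoid a cycle

    axis = frame.axes[0]
    t = (mesh.vertices - frame.centroid) @ axis
    extent = t.max() - t.min()
    transverse = np.linalg.norm(
        (mesh.vertices - frame.centroid)
        - np.outer(t, axis),
        axis=1,
    )
    if extent < 1.5 * 2 * transverse.max():
        raise ValueError(
            "bone is not long (axial extent < 1.5x max transverse extent); "
            "treat compact carpal-like bones as single regions"
        )
    secs = cross_sections(mesh, frame, n_stations)
    stations = np.asarray(secs.stations)
    areas = np.asarray([s.area for s in secs.sections])
    # prominent local minima of the area profile: the area must rise by at
    # least 5% on both sides, which rejects flat (cylinder) profiles and
    # discretisation wiggles near the articular caps
    mins = []
    for i in range(1, len(areas) - 1):
        if areas[i] <= areas[i - 1] and areas[i] <= areas[i + 1]:
            rise = min(areas[: i + 1].max(), areas[i:].max()) - areas[i]
            if rise > 0.05 * areas[i]:
                mins.append(i)
    if len(mins) < 2:
        raise ValueError("no neck minima found; bone may be a plain cylinder")
    lo_neck = min(mins)
    hi_neck = max(mins)
    if hi_neck == lo_neck:
        raise ValueError("only one neck minimum found")
    s_lo, s_hi = float(stations[lo_neck]), float(stations[hi_neck])
    # decide which extremity is the head
    max_area_low = areas[: lo_neck + 1].max()
    max_area_high = areas[hi_neck:].max()
    head_at_high = max_area_high >= max_area_low
    if not head_is_larger_end:
        head_at_high = not head_at_high
    labels = np.empty(len(mesh.vertices), dtype=object)
    mid = (t >= s_lo) & (t <= s_hi)
    labels[mid] = "shaft"
    if head_at_high:
        labels[t > s_hi] = "head"
        labels[t < s_lo] = "base"
        bounds = (s_hi, s_lo)
    else:
        labels[t < s_lo] = "head"
        labels[t > s_hi] = "base"
        bounds = (s_lo, s_hi)
    return FeaturePartition(labels=labels, boundary_stations=bounds)
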