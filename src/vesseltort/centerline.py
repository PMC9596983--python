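"""Centerline extraction from tubular meshes and stent-segment clipping.

The centerline is the locus of centers of maximal inscribed spheres along
the vessel.  For an unbranched tube this is realized cross-section by
cross-section: the tube is sliced by planes advanced along the running
tangent, each planar section's maximal-inscribed-circle center is taken,
and a second pass re-slices with planes normal to the smoothed tangent of
the first-pass polyline.  Inscribed-circle centers of convex sections are
computed exactly as Chebyshev centers (a small linear program); nonconvex
sections fall back to shapely's pole of inaccessibility.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import shapely
import trimesh
import trimesh.transformations as tf
from scipy.optimize import linprog
from shapely.ops import polylabel

from .curves import SampledCurve
from .meshing import VesselMesh

logger = logging.getLogger(__name__)

__all__ = [
    "TopologyError",
    "SegmentLandmarks",
    "extract_centerline",
    "clip_segment",
    "project_to_curve",
]


class TopologyError(ValueError):
    """Mesh is not a single unbranched open-ended tube."""


@dataclass(frozen=True)
class SegmentLandmarks:
    """Proximal and distal stent-end positions (mm) used to clip a segment."""

    proximal: np.ndarray
    distal: np.ndarray

    def __post_init__(self) -> None:
        for name in ("proximal", "distal"):
            p = np.asarray(getattr(self, name), dtype=float)
            if p.shape != (3,) or not np.all(np.isfinite(p)):
                raise ValueError(f"{name} landmark must be a finite 3-vector")
            object.__setattr__(self, name, p)


def _chebyshev_center_2d(ring: np.ndarray) -> tuple[np.ndarray, float] | None:
    """Center/radius of the largest circle inside a convex polygon (exact LP)."""
    # ensure counter-clockwise orientation
    area2 = np.sum(ring[:, 0] * np.roll(ring[:, 1], -1) - np.roll(ring[:, 0], -1) * ring[:, 1])
    if area2 < 0:
        ring = ring[::-1]
    edges = np.roll(ring, -1, axis=0) - ring
    norms = np.hypot(edges[:, 0], edges[:, 1])
    keep = norms > 1e-12
    ring, edges, norms = ring[keep], edges[keep], norms[keep]
    # outward normal of a CCW edge is (dy, -dx)
    normals = np.column_stack([edges[:, 1], -edges[:, 0]]) / norms[:, None]
    A = np.column_stack([normals, np.ones(len(ring))])
    b = np.einsum("ij,ij->i", normals, ring)
    res = linprog(
        c=[0.0, 0.0, -1.0],
        A_ub=A,
        b_ub=b,
        bounds=[(None, None), (None, None), (0.0, None)],
        method="highs",
    )
    if not res.success:
        return None
    return res.x[:2], float(res.x[2])


def _section_center(
    mesh: trimesh.Trimesh, origin: np.ndarray, normal: np.ndarray, near: np.ndarray
) -> np.ndarray | None:
    """Maximal-inscribed-circle center of the cross-section nearest ``near``."""
    try:
        sec = mesh.section(plane_origin=origin, plane_normal=normal)
    except Exception:
        return None
    if sec is None or len(sec.entities) == 0:
        return None
    try:
        planar, to_3d = sec.to_2D()
    except Exception:
        return None
    # build polygons straight from the discrete closed curves (tube
    # cross-sections have no holes)
    polys = []
    for loop in planar.discrete:
        if len(loop) >= 4:
            poly = shapely.Polygon(loop)
            if poly.is_valid and poly.area > 0:
                polys.append(poly)
    if not polys:
        return None
    to_2d = np.linalg.inv(to_3d)
    near2 = tf.transform_points(near[None], to_2d)[0, :2]
    pt = shapely.Point(near2)
    polys.sort(key=lambda p: p.distance(pt))
    poly = polys[0]
    hull = poly.convex_hull
    ring = np.asarray(poly.exterior.coords)[:-1]
    if poly.area >= 0.999 * hull.area:
        got = _chebyshev_center_2d(ring)
        if got is not None:
            c2, _ = got
        else:
            c2 = np.asarray(polylabel(poly, tolerance=1e-4 * np.sqrt(poly.area)).coords)[0]
    else:
        c2 = np.asarray(polylabel(poly, tolerance=1e-4 * np.sqrt(poly.area)).coords)[0]
    return tf.transform_points(np.array([[c2[0], c2[1], 0.0]]), to_3d)[0]


def _boundary_loops(mesh: trimesh.Trimesh) -> list[np.ndarray]:
    """Vertex-index loops of the mesh boundary, in deterministic order."""
    import networkx as nx

    unique = trimesh.grouping.group_rows(mesh.edges_sorted, require_count=1)
    if len(unique) == 0:
        return []
    g = nx.Graph()
    g.add_edges_from(mesh.edges_sorted[unique])
    loops = []
    for comp in nx.connected_components(g):
        loops.append(np.array(sorted(comp)))
    loops.sort(key=lambda ix: ix[0])
    return loops


def _ring_plane(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Centroid and unit normal of the best-fit plane through ``points``."""
    c = points.mean(axis=0)
    _, _, vt = np.linalg.svd(points - c)
    return c, vt[2]


def _canonical_frame(
    vertices: np.ndarray, refs: list[np.ndarray]
) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic mesh-intrinsic pose (origin + axes).

    Principal axes of the vertex cloud, signed by the third moment along
    each axis (falling back to reference vectors derived from the boundary
    rings when the shape is symmetric).  Working in this pose makes the
    extraction exactly independent of how the mesh happens to be oriented
    in space: every plane-slicing decision is taken in coordinates that a
    rigid motion of the input cannot change.
    """
    mu = vertices.mean(axis=0)
    X = vertices - mu
    w, E = np.linalg.eigh(X.T @ X / len(X))
    E = E[:, ::-1]
    w = w[::-1]
    scale = np.sqrt(np.abs(w).max()) + 1e-300
    for j in range(3):
        s = float(np.mean((X @ E[:, j]) ** 3))
        if abs(s) > 1e-9 * scale**3:
            if s < 0:
                E[:, j] = -E[:, j]
            continue
        for ref in refs:
            d = float(np.dot(E[:, j], ref))
            if abs(d) > 1e-9 * scale:
                if d < 0:
                    E[:, j] = -E[:, j]
                break
    return mu, E


def extract_centerline(
    mesh: VesselMesh | trimesh.Trimesh,
    step: float = 0.5,
    tangent_smoothing: float = 0.3,
) -> SampledCurve:
    """March cross-section inscribed-circle centers through a tubular mesh.

    Parameters
    ----------
    mesh:
        Open-ended unbranched tube (two boundary rings).
    step:
        Target spacing between returned centerline points (mm).
    tangent_smoothing:
        Weight of the newest direction estimate when updating the marching
        tangent; lower values damp cross-section wobble.

    Raises
    ------
    TopologyError
        If the mesh has several connected components or does not expose
        exactly two boundary rings (branching, closed, or capped meshes).
    """
    if step <= 0:
        raise ValueError("step must be positive")
    tm = mesh.to_trimesh() if isinstance(mesh, VesselMesh) else mesh
    if len(tm.faces) == 0 or len(tm.vertices) < 4:
        raise ValueError("degenerate mesh")
    if tm.body_count != 1:
        raise TopologyError(f"mesh has {tm.body_count} connected components; expected 1")
    loops = _boundary_loops(tm)
    if len(loops) != 2:
        raise TopologyError(
            f"mesh has {len(loops)} boundary rings; expected 2 open tube ends "
            "(branching or capped meshes are not supported)"
        )
    # work in the mesh's intrinsic pose so results do not depend on the
    # incidental orientation of the input
    mu0 = tm.vertices.mean(axis=0)
    ref_c = tm.vertices[loops[0]].mean(axis=0) - mu0
    ref_v = tm.vertices[loops[0][0]] - mu0
    mu, frame = _canonical_frame(tm.vertices, [ref_c, ref_v])
    tm = trimesh.Trimesh((tm.vertices - mu) @ frame, tm.faces, process=False)
    ring0, ring1 = (tm.vertices[ix] for ix in loops)
    c0, n0 = _ring_plane(ring0)
    c1, _ = _ring_plane(ring1)
    if np.dot(n0, c1 - c0) < 0:
        n0 = -n0

    # pass 1: march from one end ring toward the other
    centers = [c0]
    tangent = n0
    p = c0
    scale = np.linalg.norm(c1 - c0) + step
    max_steps = int(50 * scale / step) + 1000
    for _ in range(max_steps):
        target = p + step * tangent
        c = _section_center(tm, target, tangent, target)
        if c is None:
            break
        d = c - p
        nd = np.linalg.norm(d)
        # a center jumping by much more than one step means the slicing
        # plane left the local channel and hit a distant part of the tube
        if nd < 1e-9 or nd > 3.0 * step:
            break
        new_dir = d / nd
        tangent = (1.0 - tangent_smoothing) * tangent + tangent_smoothing * new_dir
        tangent /= np.linalg.norm(tangent)
        centers.append(c)
        p = c
        if np.linalg.norm(p - c1) < 0.75 * step:
            break
    centers.append(c1)
    line = np.asarray(centers)
    if len(line) < 4:
        raise TopologyError("marching produced too few cross-sections; not a tube?")

    # pass 2: re-slice with planes normal to the smoothed running tangent
    tangents = np.gradient(line, axis=0)
    tangents /= np.linalg.norm(tangents, axis=1, keepdims=True)
    refined = [line[0]]
    for i in range(1, len(line) - 1):
        c = _section_center(tm, line[i], tangents[i], line[i])
        if c is None or np.linalg.norm(c - line[i]) > 3.0 * step:
            c = line[i]
        refined.append(c)
    refined.append(line[-1])
    out = np.asarray(refined) @ frame.T + mu
    return SampledCurve(out)


def project_to_curve(curve: SampledCurve, point: np.ndarray) -> tuple[float, np.ndarray]:
    """Arc-length position and foot point of the closest point on a polyline."""
    pts = curve.points
    a, b = pts[:-1], pts[1:]
    ab = b - a
    denom = np.einsum("ij,ij->i", ab, ab)
    t = np.clip(np.einsum("ij,ij->i", point[None] - a, ab) / denom, 0.0, 1.0)
    feet = a + t[:, None] * ab
    d = np.linalg.norm(feet - point[None], axis=1)
    i = int(np.argmin(d))
    seg_start = np.concatenate([[0.0], np.cumsum(np.sqrt(denom))])
    return float(seg_start[i] + t[i] * np.sqrt(denom[i])), feet[i]


def clip_segment(
    curve: SampledCurve,
    landmarks: SegmentLandmarks,
    tube_radius: float | None = None,
    normalize_orientation: bool = True,
) -> SampledCurve:
    """Cut the sub-curve between the projections of two stent landmarks.

    Endpoints of the result are the exact projection points (linearly
    interpolated between samples).  With ``normalize_orientation`` the output
    always runs proximal -> distal, even if the distal landmark projects
    earlier along the stored point order.
    """
    s_prox, foot_prox = project_to_curve(curve, landmarks.proximal)
    s_dist, foot_dist = project_to_curve(curve, landmarks.distal)
    if abs(s_prox - s_dist) < 1e-12:
        raise ValueError("landmarks project to the same point on the curve")
    if tube_radius is not None:
        for name, lm, foot in (
            ("proximal", landmarks.proximal, foot_prox),
            ("distal", landmarks.distal, foot_dist),
        ):
            gap = float(np.linalg.norm(lm - foot))
            if gap > tube_radius:
                logger.warning(
                    "%s landmark is %.3f mm from the centerline "
                    "(> tube radius %.3f mm); projection used anyway",
                    name, gap, tube_radius,
                )
    lo, hi = sorted((s_prox, s_dist))
    s = np.concatenate([[0.0], np.cumsum(curve.segment_lengths)])
    inside = (s > lo + 1e-12) & (s < hi - 1e-12)
    first_pt = foot_prox if s_prox < s_dist else foot_dist
    last_pt = foot_dist if s_prox < s_dist else foot_prox
    pts = np.vstack([first_pt[None], curve.points[inside], last_pt[None]])
    # drop duplicated endpoints created when a foot coincides with a sample
    keep = np.ones(len(pts), dtype=bool)
    keep[1:] = np.linalg.norm(np.diff(pts, axis=0), axis=1) > 1e-12
    pts = pts[keep]
    if len(pts) < 4:
        # densify a very short clip by linear interpolation so it remains a
        # valid sampled curve
        t = np.linspace(0.0, 1.0, 5)
        pts = pts[0] + t[:, None] * (pts[-1] - pts[0])
    out = SampledCurve(pts)
    if normalize_orientation and s_prox > s_dist:
        out = out.reversed()
    return out
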