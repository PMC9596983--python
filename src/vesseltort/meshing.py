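"""Triangulated tube meshes swept along a centerline.

Stands in for the surface models that segmentation/reconstruction software
produces from 3D rotational angiography: a tube of known radius around a
known centerline, so extraction accuracy can be measured against ground
truth.  Cross-section frames are propagated by parallel transport
(rotation-minimizing), which is stable where the Frenet frame is not
(straight runs, inflections).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import trimesh

from .curves import SampledCurve

__all__ = ["VesselMesh", "make_tube_mesh", "discrete_curvature"]


@dataclass(frozen=True)
class VesselMesh:
    """Triangulated tubular surface with its nominal tube radius (mm)."""

    vertices: np.ndarray
    faces: np.ndarray
    tube_radius: float

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        f = np.asarray(self.faces, dtype=np.int64)
        if v.ndim != 2 or v.shape[1] != 3:
            raise ValueError("vertices must be (n, 3)")
        if f.ndim != 2 or f.shape[1] != 3:
            raise ValueError("faces must be (m, 3) triangles")
        if f.min() < 0 or f.max() >= len(v):
            raise ValueError("face indices out of range")
        object.__setattr__(self, "vertices", v)
        object.__setattr__(self, "faces", f)

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(self.vertices, self.faces, process=False)


def discrete_curvature(points: np.ndarray) -> np.ndarray:
    """Menger curvature of each interior triple of a polyline.

    kappa = 4 * area(p0, p1, p2) / (|p0p1| |p1p2| |p0p2|); zero where the
    triple is collinear.
    """
    p0, p1, p2 = points[:-2], points[1:-1], points[2:]
    a = np.linalg.norm(p1 - p0, axis=1)
    b = np.linalg.norm(p2 - p1, axis=1)
    c = np.linalg.norm(p2 - p0, axis=1)
    cross = np.cross(p1 - p0, p2 - p0)
    area2 = np.linalg.norm(cross, axis=1)  # = 2 * triangle area
    with np.errstate(divide="ignore", invalid="ignore"):
        kappa = np.where(area2 > 0, 2.0 * area2 / (a * b * c), 0.0)
    return kappa


def _parallel_transport_frames(
    points: np.ndarray, tangents: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    if tangents is None:
        T = np.gradient(points, axis=0, edge_order=2)
    else:
        T = np.asarray(tangents, dtype=float).copy()
    T /= np.linalg.norm(T, axis=1, keepdims=True)
    N = np.empty_like(T)
    t0 = T[0]
    ref = np.array([1.0, 0.0, 0.0]) if abs(t0[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    n = np.cross(t0, ref)
    N[0] = n / np.linalg.norm(n)
    for i in range(1, len(T)):
        axis = np.cross(T[i - 1], T[i])
        s = np.linalg.norm(axis)
        if s < 1e-14:
            N[i] = N[i - 1]
        else:
            axis /= s
            ang = np.arctan2(s, float(np.dot(T[i - 1], T[i])))
            v = N[i - 1]
            N[i] = (
                v * np.cos(ang)
                + np.cross(axis, v) * np.sin(ang)
                + axis * np.dot(axis, v) * (1.0 - np.cos(ang))
            )
        # re-orthogonalize against accumulated drift
        N[i] -= T[i] * np.dot(N[i], T[i])
        N[i] /= np.linalg.norm(N[i])
    B = np.cross(T, N)
    return T, N, B


def make_tube_mesh(
    curve: SampledCurve,
    tube_radius: float,
    circumferential_resolution: int = 16,
    capped: bool = False,
    tangents: np.ndarray | None = None,
) -> VesselMesh:
    """Sweep a circular cross-section of ``tube_radius`` along ``curve``.

    Cross-sections are circles normal to the local tangent, centered on the
    curve points.  The tube radius must stay below the minimum radius of
    curvature of the centerline, otherwise opposite walls would
    self-intersect on the inner bend.

    Parameters
    ----------
    capped:
        If True, close both end rings with triangle fans (watertight solid);
        otherwise the tube has two open boundary rings.
    tangents:
        Optional exact tangent vectors per curve point; by default tangents
        come from second-order finite differences of the points.
    """
    if tube_radius <= 0:
        raise ValueError("tube_radius must be positive")
    if circumferential_resolution < 3:
        raise ValueError("circumferential_resolution must be >= 3")
    kappa = discrete_curvature(curve.points)
    kmax = float(kappa.max()) if len(kappa) else 0.0
    if kmax > 0 and tube_radius >= 1.0 / kmax:
        raise ValueError(
            f"tube_radius {tube_radius:g} >= minimum radius of curvature "
            f"{1.0 / kmax:g}; tube would self-intersect"
        )
    pts = curve.points
    T, N, B = _parallel_transport_frames(pts, tangents)
    ang = np.linspace(0.0, 2.0 * np.pi, circumferential_resolution, endpoint=False)
    cos_a, sin_a = np.cos(ang), np.sin(ang)
    rings = (
        pts[:, None, :]
        + tube_radius * (cos_a[None, :, None] * N[:, None, :] + sin_a[None, :, None] * B[:, None, :])
    )
    verts = rings.reshape(-1, 3)
    n, res = len(pts), circumferential_resolution
    i = np.arange(n - 1)[:, None]
    j = np.arange(res)[None, :]
    j2 = (j + 1) % res
    a0 = i * res + j
    a1 = i * res + j2
    b0 = (i + 1) * res + j
    b1 = (i + 1) * res + j2
    quads_lower = np.stack([a0, b0, a1], axis=-1).reshape(-1, 3)
    quads_upper = np.stack([a1, b0, b1], axis=-1).reshape(-1, 3)
    faces = np.vstack([quads_lower, quads_upper])
    if capped:
        c0 = len(verts)
        verts = np.vstack([verts, pts[0][None], pts[-1][None]])
        c1 = c0 + 1
        jj = np.arange(res)
        jj2 = (jj + 1) % res
        cap0 = np.column_stack([np.full(res, c0), jj2, jj])
        cap1 = np.column_stack([np.full(res, c1), (n - 1) * res + jj, (n - 1) * res + jj2])
        faces = np.vstack([faces, cap0, cap1])
    return VesselMesh(verts, faces, tube_radius)
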