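"""Synthetic 3D centerline curves with closed-form differential geometry.

Curves are represented as ordered point sequences (:class:`SampledCurve`),
the same form a centerline-extraction tool emits.  The generator families
(line, arc, helix) have analytic curvature, torsion and distance-metric (DM)
values, which makes them exact oracles for the spline-based estimators; the
``composite`` family produces smooth random space curves without closed
forms for stress testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "SampledCurve",
    "CurveSpec",
    "CurveGroundTruth",
    "make_curve",
]

_FAMILIES = ("line", "arc", "helix", "composite")


@dataclass(frozen=True)
class SampledCurve:
    """Ordered sequence of 3D points (mm) along an open vessel centerline."""

    points: np.ndarray
    is_closed: bool = False

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise ValueError(f"points must be (n, 3), got {pts.shape}")
        if len(pts) < 4:
            raise ValueError("a sampled curve needs at least 4 points")
        if not np.all(np.isfinite(pts)):
            raise ValueError("curve coordinates must be finite")
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        if np.any(seg == 0.0):
            raise ValueError("consecutive curve points must be distinct")
        object.__setattr__(self, "points", pts)

    @property
    def n_points(self) -> int:
        return len(self.points)

    @property
    def segment_lengths(self) -> np.ndarray:
        return np.linalg.norm(np.diff(self.points, axis=0), axis=1)

    @property
    def polyline_length(self) -> float:
        """Total chord length L of the polyline (mm)."""
        return float(self.segment_lengths.sum())

    @property
    def endpoint_distance(self) -> float:
        """Straight-line distance l between the two endpoints (mm)."""
        return float(np.linalg.norm(self.points[-1] - self.points[0]))

    @property
    def dm(self) -> float:
        """Polyline distance metric l / L (no spline smoothing applied)."""
        return self.endpoint_distance / self.polyline_length

    def arc_length_parameters(self) -> np.ndarray:
        """Cumulative chord length per point, normalized to [0, 1]."""
        s = np.concatenate([[0.0], np.cumsum(self.segment_lengths)])
        return s / s[-1]

    def reversed(self) -> "SampledCurve":
        return SampledCurve(self.points[::-1].copy(), self.is_closed)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "SampledCurve":
        """Apply a rigid motion ``x -> R x + t``."""
        R = np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float)
        return SampledCurve(self.points @ R.T + t, self.is_closed)


@dataclass(frozen=True)
class CurveGroundTruth:
    """Analytic geometry of a generated curve, where closed forms exist.

    ``curvature``/``torsion`` are the constant pointwise values of the family
    (None for composite curves, whose geometry varies along the curve).
    Torsion is stored as a magnitude, matching how tortuosity summaries
    report it.
    """

    curvature: Optional[float]
    torsion: Optional[float]
    dm: Optional[float]
    length: Optional[float]
    endpoint_distance: Optional[float]


@dataclass(frozen=True)
class CurveSpec:
    """Recipe for one synthetic centerline.

    Parameters
    ----------
    family:
        "line", "arc", "helix" or "composite".
    a:
        Radius (mm): line length for "line", circle radius for "arc",
        helix radius for "helix", overall scale for "composite".
    b:
        Helix pitch parameter (mm per radian of turn); rise per unit angle
        in ``r(t) = (a cos t, a sin t, b t)``.
    turns:
        Number of full turns for "helix".
    arc_angle:
        Subtended angle (radians) for "arc".
    n_points:
        Number of samples, uniform in the curve parameter.
    noise_sd:
        Isotropic Gaussian perturbation per coordinate (mm).
    seed:
        Seed for the noise (and for composite shape draws).
    """

    family: str
    a: float = 10.0
    b: float = 0.0
    turns: float = 1.0
    arc_angle: float = np.pi
    n_points: int = 100
    noise_sd: float = 0.0
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(f"family must be one of {_FAMILIES}, got {self.family!r}")
        if self.n_points < 10:
            raise ValueError("n_points must be at least 10")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.a < 0:
            raise ValueError("a must be nonnegative")
        if self.family in ("arc", "helix") and self.a == 0:
            raise ValueError(f"{self.family} requires a > 0")
        if self.family == "arc" and not 0 < self.arc_angle <= 2 * np.pi:
            raise ValueError("arc_angle must lie in (0, 2*pi]")
        if self.family == "helix" and self.turns <= 0:
            raise ValueError("turns must be positive")


def _line(spec: CurveSpec) -> tuple[np.ndarray, CurveGroundTruth]:
    t = np.linspace(0.0, spec.a, spec.n_points)
    pts = np.column_stack([np.zeros_like(t), np.zeros_like(t), t])
    truth = CurveGroundTruth(0.0, 0.0, 1.0, spec.a, spec.a)
    return pts, truth


def _arc(spec: CurveSpec) -> tuple[np.ndarray, CurveGroundTruth]:
    theta = np.linspace(0.0, spec.arc_angle, spec.n_points)
    pts = np.column_stack(
        [spec.a * np.cos(theta), spec.a * np.sin(theta), np.zeros_like(theta)]
    )
    L = spec.a * spec.arc_angle
    ell = 2.0 * spec.a * np.sin(spec.arc_angle / 2.0)
    truth = CurveGroundTruth(1.0 / spec.a, 0.0, ell / L, L, ell)
    return pts, truth


def _helix(spec: CurveSpec) -> tuple[np.ndarray, CurveGroundTruth]:
    theta_max = 2.0 * np.pi * spec.turns
    theta = np.linspace(0.0, theta_max, spec.n_points)
    a, b = spec.a, spec.b
    pts = np.column_stack([a * np.cos(theta), a * np.sin(theta), b * theta])
    denom = a * a + b * b
    L = theta_max * np.sqrt(denom)
    ell = float(np.hypot(2.0 * a * np.sin(theta_max / 2.0), b * theta_max))
    truth = CurveGroundTruth(a / denom, abs(b) / denom, ell / L, L, ell)
    return pts, truth


def _composite(spec: CurveSpec, rng: np.random.Generator) -> tuple[np.ndarray, CurveGroundTruth]:
    # smooth random space curve: low-order Fourier series per coordinate,
    # superposed on a gentle sweep so the curve stays open and non-degenerate
    t = np.linspace(0.0, 1.0, spec.n_points)
    n_modes = 3
    pts = np.column_stack([spec.a * 2.0 * t, np.zeros_like(t), np.zeros_like(t)])
    for j in range(3):
        amp = rng.normal(scale=spec.a / 4.0, size=n_modes)
        phase = rng.uniform(0, 2 * np.pi, size=n_modes)
        for m in range(n_modes):
            pts[:, j] += amp[m] / (m + 1) * np.sin(2 * np.pi * (m + 1) * t + phase[m])
    return pts, CurveGroundTruth(None, None, None, None, None)


def make_curve(spec: CurveSpec) -> tuple[SampledCurve, CurveGroundTruth]:
    """Generate a sampled centerline plus its analytic ground truth.

    Points are sampled at uniform parameter steps.  When ``spec.noise_sd > 0``
    each coordinate receives independent Gaussian noise drawn from
    ``spec.seed``; the ground truth always refers to the noiseless curve.
    """
    rng = np.random.default_rng(spec.seed)
    if spec.family == "line":
        pts, truth = _line(spec)
    elif spec.family == "arc":
        pts, truth = _arc(spec)
    elif spec.family == "helix":
        pts, truth = _helix(spec)
    else:
        pts, truth = _composite(spec, rng)
    if spec.noise_sd > 0:
        pts = pts + rng.normal(scale=spec.noise_sd, size=pts.shape)
    return SampledCurve(pts), truth
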