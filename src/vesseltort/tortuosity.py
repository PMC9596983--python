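"""Frenet curvature/torsion profiles and tortuosity summary metrics.

Given a fitted spline r(u), curvature and torsion follow the standard
Frenet formulas

    kappa = |r' x r''| / |r'|^3
    tau   = ((r' x r'') . r''') / |r' x r''|^2

evaluated at parameters uniform in arc length.  Torsion is undefined where
the curve is locally straight (|r' x r''| ~ 0); such points are assigned
tau = 0.  Summaries are the per-vessel statistics used to quantify parent
artery tortuosity: mean/max/range of kappa and |tau|, total path length L,
endpoint distance l, and the distance metric DM = l / L.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .curves import SampledCurve
from .spline import SplineCurve, fit_free_knot_spline

__all__ = [
    "GeometryProfile",
    "TortuosityMetrics",
    "geometry_profile",
    "summarize",
    "compute_tortuosity",
]

#: |r' x r''| below this multiple of |r'|^3 marks a degenerate Frenet frame
#: (equivalent to kappa < 1e-8 per mm, far straighter than any vessel)
DEGENERACY_TOL = 1e-8

METRIC_COLUMNS = [
    "mean_curvature",
    "max_curvature",
    "range_curvature",
    "mean_torsion",
    "max_torsion",
    "range_torsion",
    "DM",
    "L",
    "l",
]


@dataclass(frozen=True)
class GeometryProfile:
    """Pointwise curvature/torsion along a fitted curve.

    ``s`` is arc length (mm), ``kappa`` and ``tau`` are in 1/mm; ``tau`` is
    the magnitude, ``tau_signed`` retains chirality.
    """

    u: np.ndarray
    s: np.ndarray
    kappa: np.ndarray
    tau: np.ndarray
    tau_signed: np.ndarray

    def __post_init__(self) -> None:
        if not (len(self.u) == len(self.s) == len(self.kappa) == len(self.tau)):
            raise ValueError("profile vectors must have equal length")
        if np.any(self.kappa < 0) or not np.all(np.isfinite(self.kappa)):
            raise ValueError("curvature must be finite and nonnegative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"s": self.s, "kappa": self.kappa, "tau": self.tau})


@dataclass(frozen=True)
class TortuosityMetrics:
    """Per-vessel tortuosity summary (units: 1/mm for kappa/tau, mm for L, l)."""

    mean_curvature: float
    max_curvature: float
    range_curvature: float
    mean_torsion: float
    max_torsion: float
    range_torsion: float
    DM: float
    L: float
    l: float  # noqa: E741 - field name mirrors the conventional symbol

    def __post_init__(self) -> None:
        if not 0 < self.DM <= 1 + 1e-9:
            raise ValueError(f"DM must lie in (0, 1], got {self.DM}")
        if self.l > self.L * (1 + 1e-9):
            raise ValueError("straight-line distance cannot exceed path length")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [[getattr(self, c) for c in METRIC_COLUMNS]], columns=METRIC_COLUMNS
        )


def geometry_profile(spline: SplineCurve, n_samples: int = 200) -> GeometryProfile:
    """Evaluate kappa/tau at ``n_samples`` points uniform in arc length."""
    if n_samples < 10:
        raise ValueError("n_samples must be at least 10")
    u = spline.uniform_arclength_params(n_samples)
    r1, r2, r3 = spline.derivatives(u)
    cross = np.cross(r1, r2)
    ncross = np.linalg.norm(cross, axis=1)
    speed = np.linalg.norm(r1, axis=1)
    kappa = ncross / speed**3
    degenerate = ncross <= DEGENERACY_TOL * speed**3
    with np.errstate(divide="ignore", invalid="ignore"):
        tau_signed = np.einsum("ij,ij->i", cross, r3) / ncross**2
    tau_signed = np.where(degenerate, 0.0, tau_signed)
    # arc length at the sample parameters
    total = spline.arc_length()
    s = np.linspace(0.0, total, n_samples)
    return GeometryProfile(u, s, kappa, np.abs(tau_signed), tau_signed)


def summarize(profile: GeometryProfile, spline: SplineCurve) -> TortuosityMetrics:
    """Collapse a geometry profile into the per-vessel tortuosity metrics.

    Means are arc-length weighted; since the profile is sampled uniformly in
    arc length this is the plain average over samples.  L comes from
    adaptive quadrature of |r'|, l from the endpoint distance of the fitted
    curve, DM = l / L.
    """
    L = spline.arc_length()
    if L <= 0:
        raise ValueError("zero-length curve")
    ends = spline(np.array([0.0, 1.0]))
    ell = float(np.linalg.norm(ends[1] - ends[0]))
    kap, tau = profile.kappa, profile.tau
    return TortuosityMetrics(
        mean_curvature=float(kap.mean()),
        max_curvature=float(kap.max()),
        range_curvature=float(kap.max() - kap.min()),
        mean_torsion=float(tau.mean()),
        max_torsion=float(tau.max()),
        range_torsion=float(tau.max() - tau.min()),
        DM=min(ell / L, 1.0),
        L=L,
        l=ell,
    )


def compute_tortuosity(
    curve: SampledCurve,
    degree: int = 3,
    max_interior_knots: int = 25,
    n_samples: int = 200,
    **fit_kwargs,
) -> tuple[TortuosityMetrics, GeometryProfile, SplineCurve]:
    """One-shot pipeline: free-knot fit, Frenet profile, summary metrics."""
    spline = fit_free_knot_spline(
        curve, degree=degree, max_interior_knots=max_interior_knots, **fit_kwargs
    )
    profile = geometry_profile(spline, n_samples=n_samples)
    return summarize(profile, spline), profile, spline
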