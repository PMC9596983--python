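"""Shared geometric helpers: canonical pose for point clouds.

Several routines (spline fitting, centerline extraction) want results that
are exactly independent of the incidental rigid placement of their input.
Working in a pose derived from the data itself - principal axes, signed by
third moments with deterministic fallbacks - achieves this: a rigid motion
of the input changes the canonical coordinates only at rounding level.
"""

from __future__ import annotations

import numpy as np

__all__ = ["canonical_axes"]


def canonical_axes(points: np.ndarray, refs: list[np.ndarray]) -> np.ndarray:
    """Deterministic principal-axis frame (columns = axes).

    Axis signs come from the third moment of the coordinates along each
    axis; when a distribution is too symmetric for that, the sign is taken
    from the first reference vector with a nonzero projection.  ``refs``
    must be rotation-covariant quantities (e.g. a boundary centroid or an
    endpoint, relative to the centroid).
    """
    X = points - points.mean(axis=0)
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
    return E
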