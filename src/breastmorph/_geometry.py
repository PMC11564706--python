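"""Continuous-geometry helpers for analytic phantom ground truth.

Extremal distances between a point and an axis-aligned ellipsoid surface
have no closed form in general; they are computed here by a coarse search
over spherical surface parameters followed by local refinement.  Accuracy
is far below a hundredth of a millimetre, i.e. negligible against voxel
discretisation error.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize


def _surface_point(params: np.ndarray, center: np.ndarray, semi: np.ndarray) -> np.ndarray:
    theta, phi = params
    st, ct = np.sin(theta), np.cos(theta)
    return center + semi * np.array([st * np.cos(phi), st * np.sin(phi), ct])


def ellipsoid_extremal_distance(
    point, center, semi_axes, mode: str = "min", n_theta: int = 96, n_phi: int = 192
) -> float:
    """Min or max Euclidean distance from ``point`` to an ellipsoid surface.

    The ellipsoid is axis-aligned with the given center and semi-axes (mm).
    """
    q = np.asarray(point, dtype=float)
    c = np.asarray(center, dtype=float)
    s = np.asarray(semi_axes, dtype=float)
    if np.allclose(s, s[0]):  # sphere: closed form
        d = float(np.linalg.norm(q - c))
        return abs(d - s[0]) if mode == "min" else d + s[0]
    sign = 1.0 if mode == "min" else -1.0

    theta = np.linspace(0.0, np.pi, n_theta)
    phi = np.linspace(0.0, 2 * np.pi, n_phi, endpoint=False)
    tt, pp = np.meshgrid(theta, phi, indexing="ij")
    st, ct = np.sin(tt), np.cos(tt)
    pts = np.stack(
        [
            c[0] + s[0] * st * np.cos(pp),
            c[1] + s[1] * st * np.sin(pp),
            c[2] + s[2] * ct,
        ],
        axis=-1,
    )
    dist = np.linalg.norm(pts - q, axis=-1)
    flat = np.argmin(sign * dist)
    x0 = np.array([tt.ravel()[flat], pp.ravel()[flat]])

    res = minimize(
        lambda p: sign * np.linalg.norm(_surface_point(p, c, s) - q),
        x0,
        method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 2000},
    )
    return float(sign * res.fun)


def point_segment_distance_grid(X, Y, Z, p0, p1) -> np.ndarray:
    """Distance from every grid point to the segment ``p0``–``p1`` (broadcasting)."""
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    d = p1 - p0
    L2 = float(d @ d)
    if L2 == 0.0:
        return np.sqrt((X - p0[0]) ** 2 + (Y - p0[1]) ** 2 + (Z - p0[2]) ** 2)
    t = ((X - p0[0]) * d[0] + (Y - p0[1]) * d[1] + (Z - p0[2]) * d[2]) / L2
    t = np.clip(t, 0.0, 1.0)
    return np.sqrt(
        (X - (p0[0] + t * d[0])) ** 2
        + (Y - (p0[1] + t * d[1])) ** 2
        + (Z - (p0[2] + t * d[2])) ** 2
    )
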