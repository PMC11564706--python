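"""Breast quadrant localization via a tissue-balancing plane.

Two planes through the nipple partition the breast: the transverse plane
(splits superior/inferior) and a near-sagittal plane containing the
superior-inferior direction, rotated about that axis until the breast
tissue inside the breast box is balanced on both sides (< 0.5 % of the
total by default).  Quadrants are named upper/lower x inner/outer with
"outer" meaning lateral (away from the body midline) for the given side.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .labelmap import LabelMap, PhysicalPoint, side_subvolume
from .landmarks import BreastBox
from .metrics import EmptyMaskError

__all__ = ["BalancePlane", "QuadrantReport", "balance_plane", "assign_quadrants"]

_TIE_EPS = 1e-9

QUADRANTS = ("upper-outer", "upper-inner", "lower-outer", "lower-inner")


@dataclass(frozen=True)
class BalancePlane:
    """Plane through ``point`` containing the superior-inferior axis, at
    ``angle_deg`` about that axis from the sagittal orientation."""

    point: PhysicalPoint
    angle_deg: float
    residual: float
    balanced: bool

    def signed_distance(self, x, y):
        th = np.deg2rad(self.angle_deg)
        return (x - self.point.x) * np.cos(th) + (y - self.point.y) * np.sin(th)


@dataclass
class QuadrantReport:
    rotation_angle_deg: float
    quadrant: str
    fractions: dict
    balance_residual: float
    flags: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "rotation_angle_deg": round(self.rotation_angle_deg, 3),
            "quadrant": self.quadrant,
            "volume_fractions": {k: round(v, 6) for k, v in self.fractions.items()},
            "balance_residual": round(self.balance_residual, 6),
            "flags": list(self.flags),
        }


def _tissue_xy(labelmap, side, box, midline):
    sub = side_subvolume(labelmap, side, midline) if side else labelmap
    mask = sub.breast_tissue_mask() & box.contains_centers(sub)
    idx = np.argwhere(mask)
    if idx.size == 0:
        raise EmptyMaskError("no breast tissue inside the breast box")
    centers = np.asarray(sub.origin_mm) + (idx + 0.5) * np.asarray(sub.spacing_mm)
    return sub, centers[:, 0], centers[:, 1]


def _medial_sign(side: str | None) -> float:
    # at angle 0 the signed distance is +x minus the nipple x; for the left
    # breast (high x = lateral) the medial side is negative
    return -1.0 if side != "right" else 1.0


def _imbalance(x, y, nipple, angle_deg, medial_sign):
    th = np.deg2rad(angle_deg)
    s = (x - nipple.x) * np.cos(th) + (y - nipple.y) * np.sin(th)
    pos = int(np.count_nonzero(s > _TIE_EPS))
    neg = int(np.count_nonzero(s < -_TIE_EPS))
    ties = s.size - pos - neg
    if medial_sign > 0:
        pos += ties
    else:
        neg += ties
    return (pos - neg) / s.size


def balance_plane(
    labelmap: LabelMap,
    side: str | None,
    nipple: PhysicalPoint,
    box: BreastBox,
    tol_frac: float = 0.005,
    angle_range_deg: float = 45.0,
    midline: int | None = None,
):
    """Find the rotation angle balancing breast tissue across the plane.

    Solved by bisection of the signed imbalance over the angle range; if
    the imbalance does not change sign across the range, the angle of
    minimal absolute imbalance on a coarse grid is returned, flagged.
    Returns ``(angle_deg, BalancePlane)``.
    """
    _, x, y = _tissue_xy(labelmap, side, box, midline)
    if not (
        box.lo_mm[0] < nipple.x < box.hi_mm[0] and box.lo_mm[2] < nipple.z < box.hi_mm[2]
    ):
        import warnings

        warnings.warn("nipple outside the breast-box footprint; proceeding")
    ms = _medial_sign(side)
    f = lambda a: _imbalance(x, y, nipple, a, ms)

    lo, hi = -angle_range_deg, angle_range_deg
    flo, fhi = f(lo), f(hi)
    if flo == 0.0:
        return lo, BalancePlane(nipple, lo, 0.0, True)
    if fhi == 0.0:
        return hi, BalancePlane(nipple, hi, 0.0, True)
    if np.sign(flo) == np.sign(fhi):
        grid = np.linspace(lo, hi, 181)
        vals = [abs(f(a)) for a in grid]
        best = int(np.argmin(vals))
        ang = float(grid[best])
        return ang, BalancePlane(nipple, ang, float(vals[best]), False)

    best_ang, best_val = lo, abs(flo)
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        fm = f(mid)
        if abs(fm) < best_val:
            best_ang, best_val = mid, abs(fm)
        if abs(fm) < tol_frac or (hi - lo) < 1e-5:
            break
        if np.sign(fm) == np.sign(flo):
            lo, flo = mid, fm
        else:
            hi, fhi = mid, fm
    return float(best_ang), BalancePlane(nipple, float(best_ang), float(best_val), best_val < tol_frac)


def assign_quadrants(
    labelmap: LabelMap,
    side: str | None,
    nipple: PhysicalPoint,
    plane: BalancePlane,
    tumor_mask: np.ndarray | None = None,
    midline: int | None = None,
) -> QuadrantReport:
    """Locate the tumor in the four nipple-centered quadrants.

    The primary quadrant holds the tumor center of mass (unweighted voxel
    centers); per-quadrant volume fractions are voxel-center memberships.
    A center of mass exactly on a plane goes to the upper and/or outer
    quadrant (flagged).
    """
    sub = side_subvolume(labelmap, side, midline) if side else labelmap
    if tumor_mask is None:
        tumor_mask = sub.tissue_mask("tumor")
    tumor_mask = np.asarray(tumor_mask, dtype=bool)
    if not tumor_mask.any():
        raise EmptyMaskError("tumor mask is empty")
    idx = np.argwhere(tumor_mask)
    centers = np.asarray(sub.origin_mm) + (idx + 0.5) * np.asarray(sub.spacing_mm)

    lateral_sign = 1.0 if side != "right" else -1.0
    flags = []

    s = plane.signed_distance(centers[:, 0], centers[:, 1])
    z = centers[:, 2]
    outer = s * lateral_sign
    # voxel counting: plane ties go medial, transverse ties go upper
    horiz = np.where(outer > _TIE_EPS, "outer", "inner")
    vert = np.where(z >= nipple.z, "upper", "lower")
    fractions = {}
    names = np.char.add(np.char.add(vert, "-"), horiz)
    for q in QUADRANTS:
        fractions[q] = float(np.count_nonzero(names == q)) / len(names)

    com = centers.mean(axis=0)
    s_com = float(plane.signed_distance(com[0], com[1])) * lateral_sign
    if abs(s_com) <= _TIE_EPS:
        flags.append("com_on_balance_plane")
        h = "outer"
    else:
        h = "outer" if s_com > 0 else "inner"
    dz = com[2] - nipple.z
    if abs(dz) <= _TIE_EPS:
        flags.append("com_on_transverse_plane")
        v = "upper"
    else:
        v = "upper" if dz > 0 else "lower"

    return QuadrantReport(
        rotation_angle_deg=plane.angle_deg,
        quadrant=f"{v}-{h}",
        fractions=fractions,
        balance_residual=plane.residual,
        flags=flags,
    )
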