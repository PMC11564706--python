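"""Automated nipple localization and breast-box construction.

The nipple heuristic finds the unweighted center of mass of all voxels
lying within a neighborhood radius (default 8 mm, center-to-center) of at
least one voxel each of air, skin and fibroglandular tissue, then offsets
the result posteriorly (default 6 mm).

The breast box is an axis-aligned region enclosing all breast tissue of
one side, seeded by five skin-anchored key points and finished by a
corrective pass that pushes any face excluding breast tissue outward one
voxel at a time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import distance_transform_edt

from ._voxels import face_neighbor_count
from .labelmap import BREAST_TISSUES, LabelMap, PhysicalPoint, side_subvolume

__all__ = [
    "NippleParams",
    "BreastBox",
    "LandmarkNotFoundError",
    "locate_nipple",
    "build_breast_box",
    "skin_surface_mask",
]


class LandmarkNotFoundError(RuntimeError):
    """A required anatomical landmark could not be located."""


@dataclass(frozen=True)
class NippleParams:
    neighborhood_radius_mm: float = 8.0
    posterior_offset_mm: float = 6.0

    def __post_init__(self) -> None:
        if self.neighborhood_radius_mm <= 0 or self.posterior_offset_mm <= 0:
            raise ValueError("nipple parameters must be positive")


@dataclass
class BreastBox:
    """Axis-aligned breast extents; voxel bounds are inclusive and refer to
    the full-map index frame; mm bounds are outer voxel edges."""

    side: str
    i_bounds: tuple
    j_bounds: tuple
    k_bounds: tuple
    lo_mm: tuple
    hi_mm: tuple
    key_points: dict
    corrected_faces: dict = field(default_factory=dict)
    fallback: bool = False

    def contains_centers(self, labelmap: LabelMap) -> np.ndarray:
        """Mask of voxels (on ``labelmap``'s grid) whose centers lie inside."""
        sel = np.ones(labelmap.shape, dtype=bool)
        lo = np.asarray(self.lo_mm)
        hi = np.asarray(self.hi_mm)
        for axis in range(3):
            c = labelmap.axis_centers_mm(axis)
            inside = (c > lo[axis]) & (c < hi[axis])
            shape = [1, 1, 1]
            shape[axis] = -1
            sel &= inside.reshape(shape)
        return sel

    def to_dict(self) -> dict:
        return {
            "side": self.side,
            "i_bounds": list(self.i_bounds),
            "j_bounds": list(self.j_bounds),
            "k_bounds": list(self.k_bounds),
            "lo_mm": [round(v, 3) for v in self.lo_mm],
            "hi_mm": [round(v, 3) for v in self.hi_mm],
            "key_points": {k: list(np.round(p.as_array(), 3)) for k, p in self.key_points.items()},
            "corrected_faces": dict(self.corrected_faces),
            "fallback": self.fallback,
        }


def _resolve_side(labelmap: LabelMap, side: str | None, midline: int | None):
    if side is None:
        return labelmap, 0
    sub = side_subvolume(labelmap, side, midline)
    i_off = int(round((sub.origin_mm[0] - labelmap.origin_mm[0]) / labelmap.spacing_mm[0]))
    return sub, i_off


def locate_nipple(
    labelmap: LabelMap,
    side: str | None = None,
    params: NippleParams = NippleParams(),
    midline: int | None = None,
) -> PhysicalPoint:
    """Locate the nipple on one side; returns a global-frame point in mm.

    Raises :class:`LandmarkNotFoundError` when the candidate set is empty
    (never returns a silent default).
    """
    sub, _ = _resolve_side(labelmap, side, midline)
    spacing = sub.spacing_mm
    r = params.neighborhood_radius_mm

    candidates = None
    for tissue in ("air", "skin", "fibroglandular"):
        mask = sub.tissue_mask(tissue)
        if not mask.any():
            raise LandmarkNotFoundError(
                f"no {tissue} voxels on side {side!r}; cannot locate the nipple"
            )
        d = distance_transform_edt(~mask, sampling=spacing)
        near = d <= r
        candidates = near if candidates is None else (candidates & near)
    if not candidates.any():
        raise LandmarkNotFoundError(
            "empty nipple candidate set: no voxel is within "
            f"{r} mm of air, skin and fibroglandular tissue simultaneously"
        )
    idx = np.argwhere(candidates)
    centers = np.asarray(sub.origin_mm) + (idx + 0.5) * np.asarray(spacing)
    com = centers.mean(axis=0)
    return PhysicalPoint(com[0], com[1] + params.posterior_offset_mm, com[2])


def skin_surface_mask(labelmap: LabelMap) -> np.ndarray:
    """Skin voxels with at least one face neighbor labeled air."""
    skin = labelmap.tissue_mask("skin")
    air = labelmap.tissue_mask("air")
    return skin & (face_neighbor_count(skin, air) > 0)


def _centers(sub: LabelMap, idx: np.ndarray) -> np.ndarray:
    return np.asarray(sub.origin_mm) + (np.asarray(idx, dtype=float) + 0.5) * np.asarray(
        sub.spacing_mm
    )


def build_breast_box(
    labelmap: LabelMap,
    side: str | None = None,
    midline: int | None = None,
    anterior_offset_mm: float = 6.0,
) -> BreastBox:
    """Construct the breast box of one side via the 5-key-point procedure.

    Postcondition: no breast-tissue voxel of the side lies outside the box.
    """
    sub, i_off = _resolve_side(labelmap, side, midline)
    ni, nj, nk = sub.shape
    spacing = np.asarray(sub.spacing_mm)
    origin = np.asarray(sub.origin_mm)

    breast = sub.breast_tissue_mask()
    if not breast.any():
        raise LandmarkNotFoundError(f"no breast tissue on side {side!r}")
    surface = skin_surface_mask(sub)
    if not surface.any():
        raise LandmarkNotFoundError(f"no skin surface on side {side!r}")

    bidx = np.argwhere(breast)
    com = _centers(sub, bidx).mean(axis=0)

    # key point 2: most anterior skin-surface voxel along the subvolume's
    # central sagittal plane; ties -> smallest k, then smallest i
    i_mid = ni // 2
    if not surface[i_mid].any():
        has = np.where(surface.any(axis=(1, 2)))[0]
        i_mid = int(has[np.argmin(np.abs(has - i_mid))])
    plane = np.argwhere(surface[i_mid])
    order = np.lexsort((plane[:, 1], plane[:, 0]))  # sort by j then k
    j_a, k_a = plane[order[0]]
    anterior_idx = np.array([i_mid, j_a, k_a])
    anterior_mm = _centers(sub, anterior_idx)

    # key point 3: reference 6 mm posterior, medial-laterally aligned with com
    ref = np.array([com[0], anterior_mm[1] + anterior_offset_mm, anterior_mm[2]])

    sidx = np.argwhere(surface)
    smm = _centers(sub, sidx)
    fallback_faces = []

    def nearest_split(drop_axis: int, split_axis: int):
        """Nearest surface voxels to ref in a 2D projection, one on each
        side of the reference along ``split_axis``."""
        keep = [a for a in range(3) if a != drop_axis]
        d2 = ((smm[:, keep] - ref[keep]) ** 2).sum(axis=1)
        below = smm[:, split_axis] < ref[split_axis]
        picks = []
        for group in (below, ~below):
            if group.any():
                rows = np.where(group)[0]
                picks.append(rows[np.argmin(d2[rows])])
            else:
                picks.append(None)
        return picks

    key_points = {
        "center_of_mass": PhysicalPoint(*com),
        "anterior_midline": PhysicalPoint(*anterior_mm),
        "reference": PhysicalPoint(*ref),
    }

    # key points 4a/4b: transverse projection (drop k) -> medial/lateral extents
    p_lo, p_hi = nearest_split(drop_axis=2, split_axis=0)
    if p_lo is None or p_hi is None:
        i_lo, i_hi = int(bidx[:, 0].min()), int(bidx[:, 0].max())
        fallback_faces.append("i")
    else:
        i_lo = int(min(sidx[p_lo, 0], sidx[p_hi, 0]))
        i_hi = int(max(sidx[p_lo, 0], sidx[p_hi, 0]))
        key_points["medial_lateral_a"] = PhysicalPoint(*smm[p_lo])
        key_points["medial_lateral_b"] = PhysicalPoint(*smm[p_hi])

    # key points 5a/5b: sagittal projection (drop i) -> inferior/superior extents
    p_lo, p_hi = nearest_split(drop_axis=0, split_axis=2)
    if p_lo is None or p_hi is None:
        k_lo, k_hi = int(bidx[:, 2].min()), int(bidx[:, 2].max())
        fallback_faces.append("k")
    else:
        k_lo = int(min(sidx[p_lo, 2], sidx[p_hi, 2]))
        k_hi = int(max(sidx[p_lo, 2], sidx[p_hi, 2]))
        key_points["inferior_superior_a"] = PhysicalPoint(*smm[p_lo])
        key_points["inferior_superior_b"] = PhysicalPoint(*smm[p_hi])

    # anterior extent: most anterior skin-surface voxel of the side
    j_lo = int(sidx[:, 1].min())
    row = sidx[sidx[:, 1] == j_lo][0]
    key_points["most_anterior"] = PhysicalPoint(*_centers(sub, row))

    # posterior face: most anterior chest voxel within the box footprint
    chest = sub.tissue_mask("chest")
    foot = chest[i_lo : i_hi + 1, :, k_lo : k_hi + 1]
    if foot.any():
        j_hi = int(np.argwhere(foot)[:, 1].min())
    else:
        j_hi = nj - 1
        fallback_faces.append("j_posterior")

    # corrective pass: push any face excluding breast tissue outward, one
    # voxel step at a time
    bounds = {"i_lo": i_lo, "i_hi": i_hi, "j_lo": j_lo, "j_hi": j_hi, "k_lo": k_lo, "k_hi": k_hi}
    limits = {"i_lo": 0, "i_hi": ni - 1, "j_lo": 0, "j_hi": nj - 1, "k_lo": 0, "k_hi": nk - 1}
    mins = {"i": int(bidx[:, 0].min()), "j": int(bidx[:, 1].min()), "k": int(bidx[:, 2].min())}
    maxs = {"i": int(bidx[:, 0].max()), "j": int(bidx[:, 1].max()), "k": int(bidx[:, 2].max())}
    corrected = {}
    cap = 2 * (ni + nj + nk)
    for face in bounds:
        axis, end = face.split("_")
        steps = 0
        while steps < cap:
            ok = bounds[face] <= mins[axis] if end == "lo" else bounds[face] >= maxs[axis]
            at_edge = bounds[face] == (0 if end == "lo" else limits[face])
            if ok or at_edge:
                break
            bounds[face] += -1 if end == "lo" else 1
            steps += 1
        if steps:
            corrected[face] = steps

    box_ok = (
        bounds["i_lo"] <= mins["i"]
        and bounds["i_hi"] >= maxs["i"]
        and bounds["j_lo"] <= mins["j"]
        and bounds["j_hi"] >= maxs["j"]
        and bounds["k_lo"] <= mins["k"]
        and bounds["k_hi"] >= maxs["k"]
    )
    fallback = bool(fallback_faces)
    if not box_ok:  # exhausted walk: tight bounding box of breast tissue
        bounds = {
            "i_lo": mins["i"],
            "i_hi": maxs["i"],
            "j_lo": mins["j"],
            "j_hi": maxs["j"],
            "k_lo": mins["k"],
            "k_hi": maxs["k"],
        }
        fallback = True

    lo_mm = origin + np.array([bounds["i_lo"], bounds["j_lo"], bounds["k_lo"]]) * spacing
    hi_mm = origin + (np.array([bounds["i_hi"], bounds["j_hi"], bounds["k_hi"]]) + 1) * spacing
    return BreastBox(
        side=side or "both",
        i_bounds=(bounds["i_lo"] + i_off, bounds["i_hi"] + i_off),
        j_bounds=(bounds["j_lo"], bounds["j_hi"]),
        k_bounds=(bounds["k_lo"], bounds["k_hi"]),
        lo_mm=tuple(lo_mm),
        hi_mm=tuple(hi_mm),
        key_points=key_points,
        corrected_faces=corrected,
        fallback=fallback,
    )
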