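"""Axis-aligned tumor dimensions, volumes, and tumor-to-landmark distances.

Axis extents are outer-edge-to-outer-edge spans of occupied voxels, so the
longest dimension is the max of the three extents and the bounding-box
volume is their product.  Distances are vertex-set distances: the minimum
Euclidean distance between deduplicated voxel-corner sets (or a corner set
and a physical point), evaluated with a KD-tree.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import generate_binary_structure, label as ndi_label
from scipy.spatial import KDTree

from ._voxels import corner_points_mm
from .labelmap import LabelMap, PhysicalPoint, side_subvolume
from .landmarks import BreastBox

__all__ = [
    "EmptyMaskError",
    "connected_components",
    "dominant_mass",
    "axis_extents",
    "tumor_volume",
    "breast_volume",
    "tumor_to_landmark_distance",
    "ScopeMetrics",
    "TumorMetricsReport",
    "tumor_metrics_report",
]

_STRUCTURES = {"face": 1, "edge": 2, "corner": 3}


class EmptyMaskError(ValueError):
    """An operation that requires a nonempty mask received an empty one."""


def connected_components(mask: np.ndarray, connectivity: str = "face"):
    """Label connected components; ids are deterministic in raster-scan
    order of each component's first voxel.  Returns ``(labels, n)``."""
    if connectivity not in _STRUCTURES:
        raise ValueError(f"connectivity must be one of {sorted(_STRUCTURES)}")
    structure = generate_binary_structure(3, _STRUCTURES[connectivity])
    labels, n = ndi_label(np.asarray(mask, dtype=bool), structure=structure)
    if n == 0:
        return labels, 0
    # re-id by raster order of first voxel (scipy already scans in raster
    # order, but the contract should not depend on that implementation detail)
    flat = labels.ravel()
    first = np.full(n + 1, flat.size, dtype=np.int64)
    nz = np.flatnonzero(flat)
    np.minimum.at(first, flat[nz], nz)
    order = np.argsort(first[1:], kind="stable")
    remap = np.zeros(n + 1, dtype=labels.dtype)
    remap[1 + order] = np.arange(1, n + 1)
    return remap[labels], n


def dominant_mass(mask: np.ndarray, connectivity: str = "face") -> np.ndarray:
    """Largest connected component; ties go to the smallest component id."""
    labels, n = connected_components(mask, connectivity)
    if n == 0:
        raise EmptyMaskError("dominant mass of an empty mask is undefined")
    counts = np.bincount(labels.ravel())[1:]
    winner = 1 + int(np.argmax(counts))  # argmax returns the first maximum
    return labels == winner


def axis_extents(mask: np.ndarray, spacing_mm) -> tuple:
    """Per-axis outer-edge extents (dx, dy, dz) in mm of occupied voxels."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise EmptyMaskError("axis extents of an empty mask are undefined")
    idx = np.argwhere(mask)
    spans = idx.max(axis=0) - idx.min(axis=0) + 1
    return tuple(float(s * sp) for s, sp in zip(spans, spacing_mm))


def tumor_volume(mask: np.ndarray, spacing_mm) -> float:
    """Voxel count times voxel volume, in mm^3 (empty mask -> 0)."""
    return float(np.count_nonzero(mask) * np.prod(np.asarray(spacing_mm, dtype=float)))


def breast_volume(labelmap: LabelMap, box: BreastBox) -> float:
    """Summed voxel volume of breast tissues whose centers lie in the box."""
    sel = box.contains_centers(labelmap)
    count = int(np.count_nonzero(labelmap.breast_tissue_mask() & sel))
    return count * labelmap.voxel_volume_mm3


def tumor_to_landmark_distance(
    tumor_mask: np.ndarray,
    target,
    spacing_mm,
    origin_mm=(0.0, 0.0, 0.0),
    target_origin_mm=None,
) -> float:
    """Minimum corner-to-corner (or corner-to-point) distance in mm.

    ``target`` is a binary mask on the same-spacing grid or a
    :class:`PhysicalPoint`.  Equals the brute-force pairwise minimum over
    deduplicated voxel-corner vertex sets.
    """
    tumor_mask = np.asarray(tumor_mask, dtype=bool)
    if not tumor_mask.any():
        raise EmptyMaskError("tumor mask is empty")
    tpts = corner_points_mm(tumor_mask, spacing_mm, origin_mm)
    if isinstance(target, PhysicalPoint):
        return float(np.min(np.linalg.norm(tpts - target.as_array(), axis=1)))
    target = np.asarray(target, dtype=bool)
    if not target.any():
        raise EmptyMaskError("target mask is empty")
    if target_origin_mm is None:
        target_origin_mm = origin_mm
    gpts = corner_points_mm(target, spacing_mm, target_origin_mm)
    d, _ = KDTree(gpts).query(tpts)
    return float(np.min(d))


@dataclass(frozen=True)
class ScopeMetrics:
    extents_mm: tuple
    longest_dimension_mm: float
    bounding_box_volume_mm3: float

    @classmethod
    def from_mask(cls, mask, spacing_mm):
        ext = axis_extents(mask, spacing_mm)
        return cls(ext, max(ext), float(np.prod(ext)))


@dataclass
class TumorMetricsReport:
    side: str
    n_components: int
    whole_tumor: ScopeMetrics
    dominant_mass: ScopeMetrics
    tumor_volume_mm3: float
    breast_volume_mm3: float
    tumor_to_breast_ratio: float | None
    to_skin_mm: float
    to_chest_mm: float
    to_nipple_mm: float

    def to_dict(self) -> dict:
        def scope(s: ScopeMetrics) -> dict:
            return {
                "extents_mm": [round(v, 1) for v in s.extents_mm],
                "longest_dimension_mm": round(s.longest_dimension_mm, 1),
                "bounding_box_volume_mm3": round(s.bounding_box_volume_mm3, 1),
            }

        return {
            "side": self.side,
            "n_components": self.n_components,
            "whole_tumor": scope(self.whole_tumor),
            "dominant_mass": scope(self.dominant_mass),
            "tumor_volume_mm3": round(self.tumor_volume_mm3, 1),
            "breast_volume_mm3": round(self.breast_volume_mm3, 1),
            "tumor_to_breast_ratio": (
                None if self.tumor_to_breast_ratio is None
                else round(self.tumor_to_breast_ratio, 4)
            ),
            "to_skin_mm": round(self.to_skin_mm, 1),
            "to_chest_mm": round(self.to_chest_mm, 1),
            "to_nipple_mm": round(self.to_nipple_mm, 1),
        }


def tumor_metrics_report(
    labelmap: LabelMap,
    side: str | None,
    nipple: PhysicalPoint,
    box: BreastBox,
    connectivity: str = "face",
    midline: int | None = None,
) -> TumorMetricsReport:
    """Assemble all tumor metrics for one side.

    Whole-tumor and dominant-mass scopes coincide exactly when the tumor is
    unifocal.  The tumor-to-breast ratio is ``None`` if the breast volume
    is zero (flagged upstream).
    """
    sub = side_subvolume(labelmap, side, midline) if side else labelmap
    spacing = sub.spacing_mm
    origin = sub.origin_mm
    tumor = sub.tissue_mask("tumor")
    if not tumor.any():
        raise EmptyMaskError(f"no tumor voxels on side {side!r}")

    _, n = connected_components(tumor, connectivity)
    dom = dominant_mass(tumor, connectivity)
    vol = tumor_volume(tumor, spacing)
    bvol = breast_volume(labelmap, box)
    ratio = vol / bvol if bvol > 0 else None

    skin = sub.tissue_mask("skin")
    chest = sub.tissue_mask("chest")
    return TumorMetricsReport(
        side=side or "both",
        n_components=n,
        whole_tumor=ScopeMetrics.from_mask(tumor, spacing),
        dominant_mass=ScopeMetrics.from_mask(dom, spacing),
        tumor_volume_mm3=vol,
        breast_volume_mm3=bvol,
        tumor_to_breast_ratio=ratio,
        to_skin_mm=tumor_to_landmark_distance(tumor, skin, spacing, origin),
        to_chest_mm=tumor_to_landmark_distance(tumor, chest, spacing, origin),
        to_nipple_mm=tumor_to_landmark_distance(tumor, nipple, spacing, origin),
    )
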