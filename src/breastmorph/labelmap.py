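"""Multi-tissue 3D label maps: data model, NIfTI I/O, orientation handling.

The canonical anatomical frame is LPS-like and image-intrinsic:

* axis ``i`` increases patient-right → patient-left,
* axis ``j`` increases anterior → posterior,
* axis ``k`` increases inferior → superior.

Voxel ``(i, j, k)`` occupies the half-open box
``[i*si, (i+1)*si) x [j*sj, (j+1)*sj) x [k*sk, (k+1)*sk)`` (plus the map's
physical origin), so its center sits at ``origin + ((i+0.5)*si, ...)`` and
its corners on integer multiples of the spacing.  Keeping voxel corners on
an exact lattice makes the vertex-based distance and hull operations exact.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterator, Mapping

import nibabel as nib
import numpy as np

__all__ = [
    "TISSUE_CLASSES",
    "BREAST_TISSUES",
    "CANONICAL_AXCODES",
    "TissueSchema",
    "LabelMap",
    "PhysicalPoint",
    "SchemaViolationError",
    "OrientationError",
    "FormatError",
    "load_labelmap",
    "save_labelmap",
    "tissue_mask",
    "split_laterality",
    "side_subvolume",
]

#: The seven semantic tissue classes every schema must cover.
TISSUE_CLASSES = ("air", "skin", "adipose", "fibroglandular", "vessel", "chest", "tumor")

#: Classes counted as breast tissue (for breast volume, boxes, balance planes).
BREAST_TISSUES = ("skin", "adipose", "fibroglandular", "vessel", "tumor")

#: nibabel axis codes of the canonical frame (+i→Left, +j→Posterior, +k→Superior).
CANONICAL_AXCODES = ("L", "P", "S")


class SchemaViolationError(ValueError):
    """A voxel value or schema entry violates the tissue schema contract."""


class OrientationError(ValueError):
    """The file's affine cannot be reduced to an axis-permutation/flip."""


class FormatError(ValueError):
    """The file does not contain integer label data."""


@dataclass(frozen=True)
class TissueSchema:
    """Mapping from the seven semantic tissue classes to integer labels."""

    label_of: Mapping[str, int]

    def __post_init__(self) -> None:
        missing = set(TISSUE_CLASSES) - set(self.label_of)
        if missing:
            raise SchemaViolationError(f"schema missing classes: {sorted(missing)}")
        extra = set(self.label_of) - set(TISSUE_CLASSES)
        if extra:
            raise SchemaViolationError(f"schema has unknown classes: {sorted(extra)}")
        values = list(self.label_of.values())
        if any((not isinstance(v, (int, np.integer))) or v < 0 for v in values):
            raise SchemaViolationError("labels must be non-negative integers")
        if len(set(values)) != len(values):
            raise SchemaViolationError("labels must be pairwise distinct")
        object.__setattr__(self, "label_of", dict(self.label_of))

    def __getitem__(self, tissue: str) -> int:
        try:
            return self.label_of[tissue]
        except KeyError:
            raise SchemaViolationError(f"unknown tissue class {tissue!r}") from None

    @property
    def labels(self) -> frozenset:
        return frozenset(int(v) for v in self.label_of.values())

    @classmethod
    def default(cls) -> "TissueSchema":
        return cls({name: i for i, name in enumerate(TISSUE_CLASSES)})

    @classmethod
    def from_json(cls, path) -> "TissueSchema":
        with open(path) as fh:
            return cls(json.load(fh))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({k: int(v) for k, v in self.label_of.items()}, fh, indent=1)


@dataclass(frozen=True)
class PhysicalPoint:
    """A point in mm in the canonical frame."""

    x: float
    y: float
    z: float

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.as_array())):
            raise ValueError("PhysicalPoint coordinates must be finite")

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)

    def translated(self, dx: float = 0.0, dy: float = 0.0, dz: float = 0.0) -> "PhysicalPoint":
        return PhysicalPoint(self.x + dx, self.y + dy, self.z + dz)

    def __iter__(self) -> Iterator[float]:
        return iter((self.x, self.y, self.z))


@dataclass
class LabelMap:
    """A 3D integer label volume in the canonical frame.

    ``origin_mm`` is the physical coordinate of the corner of voxel
    ``(0, 0, 0)``; it is nonzero for laterality subvolumes so that halves
    retain global physical coordinates.
    """

    voxels: np.ndarray
    spacing_mm: tuple
    schema: TissueSchema
    origin_mm: tuple = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise FormatError("label map must be a 3D array")
        if not np.issubdtype(self.voxels.dtype, np.integer):
            raise FormatError(f"label map must hold integers, got {self.voxels.dtype}")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing must be three positive reals")
        self.origin_mm = tuple(float(o) for o in self.origin_mm)
        present = set(np.unique(self.voxels).tolist())
        unknown = present - self.schema.labels
        if unknown:
            raise SchemaViolationError(
                f"voxel values {sorted(unknown)} not present in the tissue schema"
            )

    @property
    def shape(self) -> tuple:
        return self.voxels.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))

    def axis_centers_mm(self, axis: int) -> np.ndarray:
        """Physical center coordinates of all voxels along one axis."""
        n = self.voxels.shape[axis]
        s = self.spacing_mm[axis]
        return self.origin_mm[axis] + (np.arange(n) + 0.5) * s

    def center_grids_mm(self):
        """Broadcastable (X, Y, Z) center-coordinate arrays."""
        cs = [self.axis_centers_mm(a) for a in range(3)]
        return (
            cs[0][:, None, None],
            cs[1][None, :, None],
            cs[2][None, None, :],
        )

    def tissue_mask(self, tissue: str) -> np.ndarray:
        return np.asarray(self.voxels == self.schema[tissue])

    def breast_tissue_mask(self) -> np.ndarray:
        mask = np.zeros(self.shape, dtype=bool)
        for t in BREAST_TISSUES:
            mask |= self.voxels == self.schema[t]
        return mask


def tissue_mask(labelmap: LabelMap, tissue: str) -> np.ndarray:
    """Binary mask of one semantic class (same grid as ``labelmap``)."""
    return labelmap.tissue_mask(tissue)


def _axis_aligned_or_raise(affine: np.ndarray, rtol: float = 1e-3) -> None:
    R = np.asarray(affine, dtype=float)[:3, :3]
    for col in range(3):
        mags = np.abs(R[:, col])
        top = mags.max()
        if top <= 0:
            raise OrientationError("degenerate affine column")
        if np.sort(mags)[-2] > rtol * top:
            raise OrientationError(
                "oblique affine: only axis-permutation/flip orientations are supported"
            )


def load_labelmap(path, schema: TissueSchema) -> LabelMap:
    """Load a NIfTI label volume and reconcile it to the canonical frame.

    Only axis-permutation/flip affines are accepted (no resampling); the
    direction cosines are reduced to nearest axis codes and the data array
    reordered/flipped so that axes run R→L, A→P, I→S.
    """
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises a zoo of types
        raise FormatError(f"cannot read NIfTI file {path}: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if not np.issubdtype(data.dtype, np.integer):
        if np.issubdtype(data.dtype, np.floating) and np.all(data == np.round(data)):
            data = data.astype(np.int32)
        else:
            raise FormatError(f"label volume must contain integers, got {data.dtype}")
    affine = img.affine
    if affine is None:
        raise OrientationError("file has no affine orientation metadata")
    _axis_aligned_or_raise(affine)
    current = nib.orientations.io_orientation(affine)
    target = nib.orientations.axcodes2ornt(CANONICAL_AXCODES)
    xfer = nib.orientations.ornt_transform(current, target)
    data = nib.orientations.apply_orientation(data, xfer)
    zooms = np.asarray(img.header.get_zooms()[:3], dtype=float)
    # output axis a originates from input axis xfer[a, 0]
    spacing = tuple(float(zooms[int(xfer[a, 0])]) for a in range(3))
    return LabelMap(np.ascontiguousarray(data), spacing, schema)


def save_labelmap(labelmap: LabelMap, path) -> None:
    """Write a canonical-orientation NIfTI (.nii / .nii.gz) file."""
    si, sj, sk = labelmap.spacing_mm
    # canonical +i→L, +j→P, +k→S is (-si, -sj, +sk) in NIfTI's RAS frame
    affine = np.diag([-si, -sj, sk, 1.0])
    img = nib.Nifti1Image(labelmap.voxels.astype(np.int16), affine)
    img.header.set_zooms((si, sj, sk))
    nib.save(img, str(path))


def split_laterality(labelmap: LabelMap, midline: int | None = None):
    """Split a bilateral map at the mid-sagittal grid plane.

    Returns ``(left, right, midline)``: patient-left half (indices >=
    ``midline``), patient-right half (indices < ``midline``) and the index
    used.  Halves keep global physical coordinates via ``origin_mm``.
    """
    ni = labelmap.shape[0]
    if midline is None:
        midline = ni // 2
    if not 0 < midline < ni:
        raise ValueError(f"midline {midline} outside the grid (Ni={ni})")
    ox, oy, oz = labelmap.origin_mm
    right = LabelMap(
        labelmap.voxels[:midline].copy(),
        labelmap.spacing_mm,
        labelmap.schema,
        origin_mm=(ox, oy, oz),
    )
    left = LabelMap(
        labelmap.voxels[midline:].copy(),
        labelmap.spacing_mm,
        labelmap.schema,
        origin_mm=(ox + midline * labelmap.spacing_mm[0], oy, oz),
    )
    return left, right, midline


def side_subvolume(labelmap: LabelMap, side: str, midline: int | None = None) -> LabelMap:
    """Return one laterality half ('left' or 'right') of a bilateral map."""
    left, right, _ = split_laterality(labelmap, midline)
    if side == "left":
        return left
    if side == "right":
        return right
    raise ValueError(f"side must be 'left' or 'right', got {side!r}")
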