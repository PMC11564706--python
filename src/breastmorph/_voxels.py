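"""Shared low-level voxel-lattice helpers."""

from __future__ import annotations

import numpy as np

FACE_SHIFTS = ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1))


def corner_lattice(mask: np.ndarray) -> np.ndarray:
    """Boolean array of shape ``mask.shape + 1`` marking occupied voxel corners.

    Corner ``(i, j, k)`` (at physical ``origin + (i*si, j*sj, k*sk)``) is set
    iff it belongs to at least one occupied voxel.
    """
    mask = np.asarray(mask, dtype=bool)
    out = np.zeros(tuple(s + 1 for s in mask.shape), dtype=bool)
    ni, nj, nk = mask.shape
    for di in (0, 1):
        for dj in (0, 1):
            for dk in (0, 1):
                out[di : di + ni, dj : dj + nj, dk : dk + nk] |= mask
    return out


def corner_points_mm(mask: np.ndarray, spacing_mm, origin_mm=(0.0, 0.0, 0.0)) -> np.ndarray:
    """Deduplicated corner coordinates (N, 3) in mm of all occupied voxels."""
    idx = np.argwhere(corner_lattice(mask))
    return np.asarray(origin_mm, dtype=float) + idx * np.asarray(spacing_mm, dtype=float)


def face_neighbor_count(mask: np.ndarray, other: np.ndarray) -> np.ndarray:
    """Per-voxel count of face neighbors (6-connectivity) lying in ``other``.

    Outside the image counts as not-in-``other``.
    """
    counts = np.zeros(mask.shape, dtype=np.int8)
    for shift in FACE_SHIFTS:
        shifted = np.zeros_like(other)
        src = tuple(
            slice(max(-s, 0), other.shape[a] - max(s, 0)) for a, s in enumerate(shift)
        )
        dst = tuple(
            slice(max(s, 0), other.shape[a] + min(s, 0)) for a, s in enumerate(shift)
        )
        shifted[dst] = other[src]
        counts += shifted
    return counts
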