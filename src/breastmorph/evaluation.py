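"""Segmentation-quality metrics and reader-agreement statistics.

Dice = 2TP / (2TP + FP + FN) over voxels; the Hausdorff distance is taken
between boundary-voxel centers (face-neighbor boundary rule, image border
counting as outside) in mm.  Reader agreement between two raters' binary
accept/reject calls is summarized by percent concordance and Gwet's AC1,
the chance-corrected coefficient that stays stable under prevalence
imbalance:

    pa = (a + d) / n,   pi = (2a + b + c) / (2n),
    pe = 2 pi (1 - pi), AC1 = (pa - pe) / (1 - pe).

The exact one-sided binomial lower confidence bound (Clopper-Pearson,
beta-quantile form) supports approval-rate sample-size reasoning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy.ndimage import binary_erosion, generate_binary_structure
from scipy.spatial import KDTree
from scipy.stats import beta as beta_dist

__all__ = [
    "OverlapCounts",
    "AgreementTable",
    "Concordance",
    "overlap_counts",
    "dice",
    "boundary_voxels",
    "hausdorff",
    "concordance",
    "gwet_ac1",
    "exact_binomial_lower_bound",
]


@dataclass(frozen=True)
class OverlapCounts:
    tp: int
    fp: int
    fn: int


def overlap_counts(pred: np.ndarray, ref: np.ndarray) -> OverlapCounts:
    pred = np.asarray(pred, dtype=bool)
    ref = np.asarray(ref, dtype=bool)
    if pred.shape != ref.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {ref.shape}")
    return OverlapCounts(
        tp=int(np.count_nonzero(pred & ref)),
        fp=int(np.count_nonzero(pred & ~ref)),
        fn=int(np.count_nonzero(~pred & ref)),
    )


def dice(pred: np.ndarray, ref: np.ndarray) -> float:
    """Sørensen-Dice overlap in [0, 1]; both-empty is defined as 1.0
    (identity of empties) with a warning."""
    c = overlap_counts(pred, ref)
    denom = 2 * c.tp + c.fp + c.fn
    if denom == 0:
        warnings.warn("Dice of two empty masks: defined as 1.0", stacklevel=2)
        return 1.0
    return 2.0 * c.tp / denom


def boundary_voxels(mask: np.ndarray, spacing_mm, origin_mm=(0.0, 0.0, 0.0)) -> np.ndarray:
    """(N, 3) mm centers of voxels with a face neighbor outside the mask
    (the image border counts as outside)."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("boundary of an empty mask is undefined")
    interior = binary_erosion(
        mask, structure=generate_binary_structure(3, 1), border_value=0
    )
    idx = np.argwhere(mask & ~interior)
    return np.asarray(origin_mm, dtype=float) + (idx + 0.5) * np.asarray(spacing_mm, dtype=float)


def hausdorff(pred: np.ndarray, ref: np.ndarray, spacing_mm) -> float:
    """Symmetric Hausdorff distance between boundary-voxel centers, mm."""
    X = boundary_voxels(pred, spacing_mm)
    Y = boundary_voxels(ref, spacing_mm)
    d_xy = KDTree(Y).query(X)[0].max()
    d_yx = KDTree(X).query(Y)[0].max()
    return float(max(d_xy, d_yx))


@dataclass(frozen=True)
class AgreementTable:
    """2x2 cross-classification of two raters' accept/reject calls."""

    a: int  # both approve
    b: int  # rater 1 approves, rater 2 rejects
    c: int  # rater 1 rejects, rater 2 approves
    d: int  # both reject

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")
        if self.n == 0:
            raise ValueError("agreement table is empty")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def pa(self) -> float:
        return (self.a + self.d) / self.n

    @property
    def pi(self) -> float:
        return (2 * self.a + self.b + self.c) / (2 * self.n)

    @property
    def pe(self) -> float:
        return 2.0 * self.pi * (1.0 - self.pi)


class Concordance(NamedTuple):
    percent: float
    rounded: int


def concordance(table: AgreementTable) -> Concordance:
    """Percent agreement 100 (a + d) / n, exact and integer-rounded."""
    pct = 100.0 * table.pa
    return Concordance(percent=pct, rounded=int(round(pct)))


def gwet_ac1(table: AgreementTable) -> float:
    """Gwet's AC1 for two raters and two categories.

    Depends on the discordant total b + c only, not on the b/c split.
    """
    pe = table.pe
    if pe >= 1.0:
        raise ValueError("degenerate table: chance agreement is 1")
    return (table.pa - pe) / (1.0 - pe)


def exact_binomial_lower_bound(x: int, n: int, alpha: float) -> float:
    """One-sided Clopper-Pearson lower bound for a binomial proportion."""
    if not 0 <= x <= n or n <= 0:
        raise ValueError("require 0 <= x <= n with n > 0")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if x == 0:
        return 0.0
    return float(beta_dist.ppf(alpha, x, n - x + 1))
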