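"""Brute-force reference implementations used only to cross-check the
package's fast code paths.  Everything here is deliberately naive."""

import numpy as np
from scipy.spatial.distance import cdist


def brute_corner_set(mask, spacing, origin=(0.0, 0.0, 0.0)):
    """All 8 corners of every occupied voxel, deduplicated, in mm."""
    corners = set()
    spacing = tuple(float(s) for s in spacing)
    for i, j, k in np.argwhere(np.asarray(mask, dtype=bool)):
        for di in (0, 1):
            for dj in (0, 1):
                for dk in (0, 1):
                    corners.add(
                        (
                            origin[0] + (i + di) * spacing[0],
                            origin[1] + (j + dj) * spacing[1],
                            origin[2] + (k + dk) * spacing[2],
                        )
                    )
    return np.array(sorted(corners), dtype=float)


def brute_min_corner_distance(mask_a, mask_b, spacing, origin=(0.0, 0.0, 0.0)):
    """Exhaustive all-pairs minimum corner-to-corner distance in mm."""
    A = brute_corner_set(mask_a, spacing, origin)
    B = brute_corner_set(mask_b, spacing, origin)
    return float(cdist(A, B).min())


def brute_dice(pred, ref):
    pred = np.asarray(pred, dtype=bool).ravel()
    ref = np.asarray(ref, dtype=bool).ravel()
    tp = fp = fn = 0
    for p, r in zip(pred, ref):
        if p and r:
            tp += 1
        elif p:
            fp += 1
        elif r:
            fn += 1
    if 2 * tp + fp + fn == 0:
        return 1.0
    return 2 * tp / (2 * tp + fp + fn)


def brute_boundary_centers(mask, spacing):
    """Voxel centers with a face neighbor outside the mask (border=outside)."""
    mask = np.asarray(mask, dtype=bool)
    out = []
    ni, nj, nk = mask.shape
    for i, j, k in np.argwhere(mask):
        boundary = False
        for di, dj, dk in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)):
            a, b, c = i + di, j + dj, k + dk
            if not (0 <= a < ni and 0 <= b < nj and 0 <= c < nk) or not mask[a, b, c]:
                boundary = True
                break
        if boundary:
            out.append(((i + 0.5) * spacing[0], (j + 0.5) * spacing[1], (k + 0.5) * spacing[2]))
    return np.array(out, dtype=float)


def brute_hausdorff(pred, ref, spacing):
    X = brute_boundary_centers(pred, spacing)
    Y = brute_boundary_centers(ref, spacing)
    D = cdist(X, Y)
    return float(max(D.min(axis=1).max(), D.min(axis=0).max()))


def brute_clopper_pearson_lower(x, n, alpha, tol=1e-12):
    """Lower bound via bisection of the binomial tail (independent of any
    beta-quantile identity)."""
    from scipy.stats import binom

    if x == 0:
        return 0.0
    lo, hi = 0.0, 1.0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        # P(X >= x | p=mid): increasing in p
        if binom.sf(x - 1, n, mid) < alpha:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def brute_balance_sweep(x, y, nipple_xy, medial_sign, step_deg=0.1, lo=-45.0, hi=45.0):
    """Minimal |imbalance| over a dense angle grid (tissue-count balance)."""
    best = None
    for ang in np.arange(lo, hi + step_deg / 2, step_deg):
        th = np.deg2rad(ang)
        s = (x - nipple_xy[0]) * np.cos(th) + (y - nipple_xy[1]) * np.sin(th)
        pos = int(np.count_nonzero(s > 1e-9))
        neg = int(np.count_nonzero(s < -1e-9))
        ties = s.size - pos - neg
        if medial_sign > 0:
            pos += ties
        else:
            neg += ties
        val = abs(pos - neg) / s.size
        if best is None or val < best:
            best = val
    return best
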