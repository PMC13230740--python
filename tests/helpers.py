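"""Independent oracles and scoring utilities shared by the tests.

Everything here is deliberately brute-force and kept independent of the
package's own implementation paths: exhaustive permutation search for
optimal assignment, grid scans of shifted-difference energy for image
translation, and direct Hungarian matching of detections to ground
truth for recall/precision scoring.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy import ndimage
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist


def brute_force_assignment_cost(cost: np.ndarray) -> float:
    """Minimal total cost over all full assignments, by enumeration.

    Rectangular matrices assign every row (rows <= cols required).
    """
    n_r, n_c = cost.shape
    assert n_r <= n_c, "transpose first"
    best = np.inf
    for perm in itertools.permutations(range(n_c), n_r):
        best = min(best, float(cost[np.arange(n_r), perm].sum()))
    return best


def brute_force_match_count(
    ref: np.ndarray, query: np.ndarray, threshold_px: float, cap_px: float
) -> int:
    """Sub-threshold pair count of the optimal capped assignment, by
    enumeration: pairs beyond the cap cost a large constant, the best
    full assignment minimizes total cost, and pairs at or beyond the
    threshold are discarded afterwards -- the matching semantics, solved
    without the Hungarian algorithm."""
    d = cdist(ref, query)
    n_r, n_q = d.shape
    if n_r == 0 or n_q == 0:
        return 0
    cost = np.where(d > cap_px, 1e12, d)
    dd, sub = (cost, d) if n_r <= n_q else (cost.T, d.T)
    small = dd.shape[0]
    best_cost, best_count = np.inf, 0
    for perm in itertools.permutations(range(dd.shape[1]), small):
        c = float(dd[np.arange(small), perm].sum())
        if c < best_cost - 1e-9:
            best_cost = c
            best_count = int((sub[np.arange(small), perm] < threshold_px).sum())
    return best_count


def brute_force_shift(
    reference: np.ndarray,
    moving: np.ndarray,
    search_px: int = 6,
    fine_step: float = 0.05,
) -> tuple[float, float]:
    """Translation minimizing shifted-difference energy, by grid scan.

    Coarse integer scan over +-search_px, then a fine scan at
    ``fine_step`` resolution around the coarse optimum. Energies are
    evaluated on a central crop so edge padding never dominates.
    """
    crop = search_px + 2

    def energy(dy: float, dx: float) -> float:
        sh = ndimage.shift(moving, (dy, dx), order=3, mode="nearest")
        diff = (sh - reference)[crop:-crop, crop:-crop]
        return float((diff**2).sum())

    coarse = [
        (energy(dy, dx), dy, dx)
        for dy in range(-search_px, search_px + 1)
        for dx in range(-search_px, search_px + 1)
    ]
    _, by, bx = min(coarse)
    offsets = np.arange(-1.0, 1.0 + fine_step / 2, fine_step)
    fine = [
        (energy(by + oy, bx + ox), by + oy, bx + ox) for oy in offsets for ox in offsets
    ]
    _, fy, fx = min(fine)
    return float(fy), float(fx)


def score_detection(
    truth_zyx: np.ndarray, detected_zyx: np.ndarray, match_radius_px: float = 2.0
) -> tuple[float, float, float]:
    """(recall, precision, lateral RMSE) by one-to-one matching to truth."""
    if len(truth_zyx) == 0 or len(detected_zyx) == 0:
        return 0.0, 0.0, np.nan
    d = cdist(truth_zyx, detected_zyx)
    ri, ci = linear_sum_assignment(np.where(d > 1.5 * match_radius_px, 1e6, d))
    ok = d[ri, ci] < match_radius_px
    err = truth_zyx[ri[ok], 1:] - detected_zyx[ci[ok], 1:]
    rmse = float(np.sqrt((err**2).sum(axis=1).mean())) if ok.any() else np.nan
    return ok.sum() / len(truth_zyx), ok.sum() / len(detected_zyx), rmse


def make_snr_patch() -> tuple[np.ndarray, float, float, float]:
    """A 3D patch with an exactly known intensity / background / SNR.

    Peak voxel 110 at the center; annulus pixels (radii 3..5 around the
    center on the central plane) alternate 8 and 12 in equal numbers, so
    the background mean is exactly 10 and the population SD exactly 2.
    Returns (stack, expected_intensity, expected_bg_mean, expected_snr).
    """
    patch = np.full((3, 21, 21), 10.0)
    yy, xx = np.mgrid[0:21, 0:21]
    r = np.hypot(yy - 10, xx - 10)
    sel = np.argwhere((r >= 3) & (r <= 5))
    assert len(sel) % 2 == 0
    for i, (y, x) in enumerate(sel):
        patch[1, y, x] = 8.0 if i % 2 == 0 else 12.0
    patch[1, 10, 10] = 110.0
    return patch, 100.0, 10.0, 50.0
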