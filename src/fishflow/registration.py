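"""Per-round drift correction by phase cross-correlation.

Mechanical stage drift between hybridization rounds is modeled as a
global lateral translation. The shift of each round relative to a
reference round is estimated by phase cross-correlation, either on
binary spot maps (point-set mode, useful when spot tables are already
available) or on maximum-intensity projections of the raw stacks. The
estimated (delta_y, delta_x) is ADDED to moving-round spot coordinates
to bring them into the reference frame.

Rotation and scale changes are outside the model: they degrade the
correlation peak ratio, which is reported as a per-round confidence
score.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.draw import disk
from skimage.registration import phase_cross_correlation

from .simkit import ImageStack

__all__ = [
    "DriftEstimate",
    "spots_to_binary_map",
    "phase_correlation_shift",
    "register_rounds",
    "apply_shift",
    "drift_table",
]

PEAK_RATIO_CAP = 1e6


@dataclass
class DriftEstimate:
    """Global shift of one round; add (delta_y, delta_x) to that round's
    coordinates to land in the reference frame. ``peak_ratio`` is the
    correlation peak over the second-highest peak (>= 1; higher = more
    confident)."""

    round: int
    delta_y: float
    delta_x: float
    peak_ratio: float = 1.0
    mode: str = "spots"
    flags: str = ""


def spots_to_binary_map(
    spots: pd.DataFrame, shape_yx: tuple[int, int], dot_radius_px: float = 2.0
) -> np.ndarray:
    """Rasterize spot (y, x) positions into a 2D binary map.

    Each spot paints a disk of ``dot_radius_px`` centered on its rounded
    (y, x); z is collapsed. An empty table gives an all-zero map.
    """
    out = np.zeros(shape_yx, dtype=bool)
    ny, nx = shape_yx
    for y, x in spots[["y", "x"]].to_numpy(float):
        yi, xi = int(round(y)), int(round(x))
        if not (0 <= yi < ny and 0 <= xi < nx):
            continue
        if dot_radius_px <= 0:
            out[yi, xi] = True
        else:
            rr, cc = disk((yi, xi), dot_radius_px + 0.5, shape=shape_yx)
            out[rr, cc] = True
    return out


def _peak_ratio(reference: np.ndarray, moving: np.ndarray) -> float:
    """Peak / second-peak of the normalized cross-power correlation surface."""
    f = np.fft.fftn(reference) * np.conj(np.fft.fftn(moving))
    mag = np.abs(f)
    mag[mag == 0] = 1.0
    surf = np.abs(np.fft.ifftn(f / mag))
    peak_idx = np.unravel_index(np.argmax(surf), surf.shape)
    peak = surf[peak_idx]
    # blank a 5x5 (circular) neighborhood around the main peak
    blanked = surf.copy()
    for dy in range(-2, 3):
        for dx in range(-2, 3):
            blanked[(peak_idx[0] + dy) % surf.shape[0], (peak_idx[1] + dx) % surf.shape[1]] = 0
    second = blanked.max()
    if second <= 0:
        return PEAK_RATIO_CAP
    return float(min(max(peak / second, 1.0), PEAK_RATIO_CAP))


def phase_correlation_shift(
    reference: np.ndarray, moving: np.ndarray, upsample: int = 20
) -> tuple[float, float, float]:
    """Estimate the translation between two 2D images.

    Returns ``(delta_y, delta_x, peak_ratio)`` with the convention
    ``moving coordinates + delta = reference coordinates``. Integer
    shifts of noise-free inputs are recovered exactly; ``upsample > 1``
    refines the estimate to 1/upsample px by local upsampled
    cross-correlation around the integer peak.
    """
    reference = np.asarray(reference, float)
    moving = np.asarray(moving, float)
    if reference.shape != moving.shape:
        raise ValueError("reference and moving must have the same shape")
    if np.ptp(reference) == 0 or np.ptp(moving) == 0:
        raise ValueError("phase correlation is undefined for constant images")
    shift, _, _ = phase_cross_correlation(
        reference, moving, upsample_factor=max(int(upsample), 1), normalization="phase"
    )
    ratio = _peak_ratio(reference, moving)
    return float(shift[0]), float(shift[1]), ratio


def register_rounds(
    tables: dict[int, pd.DataFrame] | None = None,
    stacks: dict[int, ImageStack | np.ndarray] | None = None,
    reference_round: int = 1,
    mode: str = "spots",
    shape_yx: tuple[int, int] | None = None,
    dot_radius_px: float = 2.0,
    upsample: int = 20,
    min_spots: int = 3,
) -> list[DriftEstimate]:
    """Estimate per-round drift against a reference round.

    ``mode="spots"`` correlates binary spot maps built from the spot
    tables (``shape_yx`` required); ``mode="image"`` correlates maximum
    intensity projections of the stacks. A round with fewer than
    ``min_spots`` spots in spots mode falls back to image mode when
    stacks are available, else reports (0, 0) flagged
    ``low_confidence``.
    """
    if mode not in ("spots", "image"):
        raise ValueError("mode must be 'spots' or 'image'")
    if mode == "spots":
        if tables is None or shape_yx is None:
            raise ValueError("spots mode needs tables and shape_yx")
        rounds = sorted(tables)
    else:
        if stacks is None:
            raise ValueError("image mode needs stacks")
        rounds = sorted(stacks)
    if reference_round not in rounds:
        raise ValueError(f"reference round {reference_round} not present")

    def _mip(r: int) -> np.ndarray:
        s = stacks[r]
        return s.mip() if isinstance(s, ImageStack) else np.asarray(s, float).max(axis=0)

    if mode == "spots":
        ref_img = spots_to_binary_map(tables[reference_round], shape_yx, dot_radius_px).astype(float)
    else:
        ref_img = _mip(reference_round)

    out = []
    for r in rounds:
        if r == reference_round:
            out.append(DriftEstimate(r, 0.0, 0.0, PEAK_RATIO_CAP, mode, "reference"))
            continue
        if mode == "spots" and len(tables[r]) < min_spots:
            if stacks is not None and r in stacks and reference_round in stacks:
                dy, dx, pr = phase_correlation_shift(_mip(reference_round), _mip(r), upsample)
                out.append(DriftEstimate(r, round(dy, 3), round(dx, 3), pr, "image", "low_confidence;image_fallback"))
            else:
                out.append(DriftEstimate(r, 0.0, 0.0, 1.0, mode, "low_confidence"))
            continue
        mov_img = (
            spots_to_binary_map(tables[r], shape_yx, dot_radius_px).astype(float)
            if mode == "spots"
            else _mip(r)
        )
        dy, dx, pr = phase_correlation_shift(ref_img, mov_img, upsample)
        out.append(DriftEstimate(r, round(dy, 3), round(dx, 3), pr, mode, ""))
    return out


def apply_shift(spots: pd.DataFrame, estimate: DriftEstimate) -> pd.DataFrame:
    """Shift a spot table into the reference frame (y += dy, x += dx).

    Coordinates may leave the pixel grid; they are frame-of-reference
    positions, not array indices.
    """
    out = spots.copy()
    out["y"] = out["y"] + estimate.delta_y
    out["x"] = out["x"] + estimate.delta_x
    return out


def drift_table(estimates: list[DriftEstimate]) -> pd.DataFrame:
    """Serialize estimates in the canonical drift.csv column order."""
    return pd.DataFrame(
        [
            {
                "round": e.round,
                "delta_y": e.delta_y,
                "delta_x": e.delta_x,
                "peak_ratio": e.peak_ratio,
                "mode": e.mode,
                "flags": e.flags,
            }
            for e in estimates
        ]
    )
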