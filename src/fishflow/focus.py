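"""Shape-from-focus scoring of nuclear z-stacks.

Sharpness is measured with the Helmli-Scherer mean-ratio contrast: for
each pixel, the ratio between its intensity and the local mean over a
small window, taken in whichever direction exceeds 1. The measure is 1
on perfectly flat regions, grows with local texture, is invariant to
multiplying the image by a positive constant, and decreases under
blurring -- so, per nucleus, the z-plane maximizing the mean contrast
over its bounding box is its best focal plane. A composite image stitches
each nucleus's best plane together, filling background pixels from the
plane at the median best-z across nuclei.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label

from .simkit import ImageStack

__all__ = [
    "FocusResult",
    "mean_ratio_contrast",
    "nucleus_focus_curves",
    "composite_best_focus",
    "segment_nuclei_fallback",
    "condition_summary",
]

RATIO_CAP = 1e6


@dataclass
class FocusResult:
    """Per-nucleus focus curve and best plane."""

    label: int
    bbox: tuple[int, int, int, int]  # (y0, x0, y1, x1), half-open
    fm_curve: np.ndarray  # mean contrast per z
    best_z: int
    fm_best: float


def mean_ratio_contrast(
    plane: np.ndarray, window_px: int = 7, cap: float = RATIO_CAP
) -> np.ndarray:
    """Helmli-Scherer mean-ratio contrast map of a 2D image.

    Per pixel: mu = local mean over a ``window_px`` square;
    R = max(I/mu, mu/I), with R = 1 where both I and mu are 0 and R
    capped at ``cap`` where exactly one of them is 0. R >= 1 everywhere;
    R = 1 on constant images.
    """
    if window_px < 3 or window_px % 2 == 0:
        raise ValueError("window_px must be an odd integer >= 3")
    img = np.asarray(plane, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError("plane must be 2D")
    if np.any(img < 0):
        raise ValueError("intensities must be nonnegative")
    mu = ndimage.uniform_filter(img, size=window_px, mode="reflect")
    mu = np.clip(mu, 0, None)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.maximum(img / mu, mu / img)
    both_zero = (img == 0) & (mu == 0)
    r[both_zero] = 1.0
    r = np.where(np.isfinite(r), r, cap)
    return np.clip(r, 1.0, cap)


def nucleus_focus_curves(
    stack: ImageStack | np.ndarray,
    label_mask: np.ndarray,
    window_px: int = 7,
    restrict_to_mask: bool = False,
) -> list[FocusResult]:
    """Score every z-plane of each labeled nucleus and pick the sharpest.

    The per-plane focus measure is the mean of the contrast map over the
    nucleus bounding box (or over the exact mask when
    ``restrict_to_mask``). ``best_z`` is the argmax of the curve; ties
    resolve to the lowest z.
    """
    data = stack.data if isinstance(stack, ImageStack) else np.asarray(stack, float)
    label_mask = np.asarray(label_mask)
    if label_mask.shape != data.shape[1:]:
        raise ValueError("label_mask must match the stack's (ny, nx)")
    contrast = np.stack([mean_ratio_contrast(p, window_px) for p in data])
    results = []
    objects = ndimage.find_objects(label_mask)
    for lab, sl in enumerate(objects, start=1):
        if sl is None:
            warnings.warn(f"label {lab} is empty; skipped", stacklevel=2)
            continue
        ys, xs = sl
        region = contrast[:, ys, xs]
        if restrict_to_mask:
            m = label_mask[ys, xs] == lab
            curve = region[:, m].mean(axis=1)
        else:
            curve = region.reshape(region.shape[0], -1).mean(axis=1)
        best_z = int(np.argmax(curve))  # argmax returns the lowest index on ties
        results.append(
            FocusResult(
                label=lab,
                bbox=(ys.start, xs.start, ys.stop, xs.stop),
                fm_curve=curve,
                best_z=best_z,
                fm_best=float(curve[best_z]),
            )
        )
    return results


def composite_best_focus(
    stack: ImageStack | np.ndarray,
    label_mask: np.ndarray,
    focus_results: list[FocusResult],
) -> tuple[np.ndarray, str]:
    """All-in-focus 2D image from per-nucleus best planes.

    Pixels of nucleus L come from plane best_z(L); background pixels come
    from the plane at the median best_z over all nuclei (rounded to the
    nearest integer, ties toward the lower plane). With no nuclei the
    middle plane is returned, flagged.
    """
    data = stack.data if isinstance(stack, ImageStack) else np.asarray(stack, float)
    nz = data.shape[0]
    if not focus_results:
        return data[nz // 2].copy(), "no_nuclei"
    best = {r.label: r.best_z for r in focus_results}
    missing = set(np.unique(label_mask)) - {0} - set(best)
    if missing:
        raise ValueError(f"labels without focus results: {sorted(missing)}")
    med = float(np.median(list(best.values())))
    bg_z = int(np.ceil(med - 0.5))  # nearest integer, half-values down
    out = data[int(np.clip(bg_z, 0, nz - 1))].copy()
    for lab, z in best.items():
        m = label_mask == lab
        out[m] = data[z][m]
    return out, ""


def segment_nuclei_fallback(
    projection: np.ndarray, min_size_px: int = 64
) -> tuple[np.ndarray, str]:
    """Threshold-based nucleus segmentation for tests and demos.

    Otsu global threshold, hole filling, connected components, and a
    small-object size filter; labels are consecutive positive integers.
    Externally produced masks (e.g. from a learned segmenter) are
    accepted by every downstream function and preferred for real data.
    """
    img = np.asarray(projection, float)
    if np.ptp(img) == 0:
        return np.zeros(img.shape, dtype=np.int32), "all_background"
    thr = threshold_otsu(img)
    mask = ndimage.binary_fill_holes(img > thr)
    comps = cc_label(mask)
    sizes = np.bincount(comps.ravel())
    keep = np.flatnonzero(sizes >= min_size_px)
    keep = keep[keep > 0]
    labels = cc_label(np.isin(comps, keep)).astype(np.int32)
    flag = "all_background" if labels.max() == 0 else ""
    return labels, flag


def condition_summary(
    results_by_condition: dict[str, list[FocusResult]],
) -> pd.DataFrame:
    """Boxplot-ready stats (median and quartiles of fm_best) per condition."""
    if not results_by_condition:
        raise ValueError("need at least one condition")
    rows = []
    for cond, results in results_by_condition.items():
        vals = np.array([r.fm_best for r in results], float)
        if vals.size:
            q25, med, q75 = np.percentile(vals, [25, 50, 75])
        else:
            q25 = med = q75 = np.nan
        rows.append(
            {
                "condition": cond,
                "n_nuclei": vals.size,
                "fm_best_median": med,
                "fm_best_q25": q25,
                "fm_best_q75": q75,
            }
        )
    return pd.DataFrame(rows)
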