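"""Gene-by-cell expression matrices and cosine-distance cell typing.

Spots are assigned to the nearest nucleus (by 2D Euclidean distance to
the nucleus boundary or interior, capped at a maximum reach) to build a
cells x genes count matrix. Cells are then typed by cosine distance to
reference per-type centroids -- median expression profiles, typically
derived from scRNA-seq -- under two gates: the nearest centroid must lie
at cosine distance below ``d_max`` (default 0.8) and the cell must carry
strictly more than ``min_rna`` RNAs (default 10). Cells failing either
gate stay "unclassified" with a reason code.

The nearest-nucleus assignment is a deliberately simple baseline for
point-cloud cell segmentation; dedicated segmenters can supply the label
mask instead.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "assign_spots_to_cells",
    "cosine_distance",
    "call_cell_types",
    "marker_centroids_from_reference",
]

UNCLASSIFIED = "unclassified"


def assign_spots_to_cells(
    spots: pd.DataFrame,
    nucleus_label_mask: np.ndarray,
    max_dist_um: float = 5.0,
    pixel_size_nm: float = 100.0,
    genes: list[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Count spots per (cell, gene) by nearest-nucleus assignment.

    A spot is assigned to the label whose nucleus is nearest in (y, x)
    (distance 0 inside a nucleus) provided that distance is at most
    ``max_dist_um``; equidistant nuclei resolve to the lower label.
    Returns ``(matrix, spots_with_assignment)`` where ``matrix`` is a
    cells x genes integer DataFrame over all labels in the mask and the
    spot table gains ``cell_id`` (0 = unassigned) and ``assign_dist_um``
    columns.
    """
    mask = np.asarray(nucleus_label_mask)
    if mask.ndim != 2:
        raise ValueError("nucleus_label_mask must be 2D")
    labels = [int(v) for v in np.unique(mask) if v > 0]
    spots = spots.reset_index(drop=True)
    out = spots.copy()
    if not labels:
        out["cell_id"] = 0
        out["assign_dist_um"] = np.nan
        if genes is None:
            genes = sorted(spots["gene"].unique()) if len(spots) else []
        empty = pd.DataFrame(0, index=pd.Index([], name="cell_id"), columns=genes)
        warnings.warn("no nuclei in the label mask; all spots unassigned", stacklevel=2)
        return empty, out

    # per-label distance transform; strict '<' update keeps the lower
    # label on exact ties
    best_d = np.full(mask.shape, np.inf)
    best_l = np.zeros(mask.shape, dtype=np.int32)
    for lab in labels:
        d = ndimage.distance_transform_edt(mask != lab)
        upd = d < best_d
        best_d[upd] = d[upd]
        best_l[upd] = lab

    max_dist_px = max_dist_um * 1000.0 / pixel_size_nm
    ny, nx = mask.shape
    cell_ids = np.zeros(len(spots), dtype=np.int64)
    dists = np.full(len(spots), np.nan)
    for i, (y, x) in enumerate(spots[["y", "x"]].to_numpy(float)):
        yi = int(np.clip(round(y), 0, ny - 1))
        xi = int(np.clip(round(x), 0, nx - 1))
        d = best_d[yi, xi]
        dists[i] = d * pixel_size_nm / 1000.0
        if d <= max_dist_px:
            cell_ids[i] = best_l[yi, xi]
    out["cell_id"] = cell_ids
    out["assign_dist_um"] = dists

    if genes is None:
        genes = sorted(spots["gene"].unique()) if len(spots) else []
    matrix = pd.DataFrame(0, index=pd.Index(labels, name="cell_id"), columns=genes)
    assigned = out[out["cell_id"] > 0]
    for (cid, gene), g in assigned.groupby(["cell_id", "gene"]):
        if gene in matrix.columns:
            matrix.loc[cid, gene] = len(g)
    return matrix, out


def cosine_distance(x: np.ndarray, c: np.ndarray) -> float:
    """1 - cos(angle) between an expression vector and a centroid.

    Scale-invariant in both arguments. A zero expression vector is at
    distance 1 by convention (no direction to compare).
    """
    x = np.asarray(x, float)
    c = np.asarray(c, float)
    if np.any(np.isnan(x)) or np.any(np.isnan(c)):
        raise ValueError("NaN in input vectors")
    if np.any(x < 0) or np.any(c < 0):
        raise ValueError("expression vectors must be nonnegative")
    nc = np.linalg.norm(c)
    if nc == 0:
        raise ValueError("centroid must be non-zero")
    nx_ = np.linalg.norm(x)
    if nx_ == 0:
        return 1.0
    return float(1.0 - np.dot(x, c) / (nx_ * nc))


def marker_centroids_from_reference(reference: pd.DataFrame) -> pd.DataFrame:
    """Per-type median expression centroids from reference cell profiles.

    ``reference`` holds one row per reference cell with a ``cell_type``
    column and one numeric column per gene. Precomputed centroids (one
    row per type, index = type names) are accepted verbatim when no
    ``cell_type`` column is present.
    """
    if "cell_type" in reference.columns:
        if reference.empty:
            raise ValueError("reference has no cells")
        centroids = reference.groupby("cell_type").median()
    else:
        centroids = reference.astype(float).copy()
    if centroids.empty:
        raise ValueError("no cell types in reference")
    norms = np.linalg.norm(centroids.to_numpy(float), axis=1)
    if np.any(norms == 0):
        bad = list(centroids.index[norms == 0])
        raise ValueError(f"zero-norm centroid(s): {bad}")
    return centroids


def call_cell_types(
    matrix: pd.DataFrame,
    centroids: pd.DataFrame,
    d_max: float = 0.8,
    min_rna: int = 10,
) -> pd.DataFrame:
    """Assign each cell to its nearest centroid under the two gates.

    A cell is classified iff its cosine distance to the nearest centroid
    is strictly below ``d_max`` AND its total RNA count is strictly
    greater than ``min_rna``; otherwise it is labeled "unclassified" with
    a reason code (``distance_gate``, ``count_gate``, or both).
    Gene sets are aligned by intersection (warned when partial).
    """
    if centroids.empty:
        raise ValueError("empty centroid set")
    shared = [g for g in matrix.columns if g in centroids.columns]
    if not shared:
        raise ValueError("no shared genes between matrix and centroids")
    if len(shared) < len(matrix.columns) or len(shared) < len(centroids.columns):
        warnings.warn(
            f"partial gene overlap: using {len(shared)} shared genes", stacklevel=2
        )
    X = matrix[shared].to_numpy(float)
    C = centroids[shared].to_numpy(float)
    total = matrix.sum(axis=1).to_numpy()  # totals over ALL measured genes
    xn = np.linalg.norm(X, axis=1)
    cn = np.linalg.norm(C, axis=1)
    if np.any(cn == 0):
        raise ValueError("zero-norm centroid over the shared genes")
    with np.errstate(invalid="ignore", divide="ignore"):
        dist = 1.0 - (X @ C.T) / np.outer(xn, cn)
    dist[xn == 0, :] = 1.0
    nearest = np.argmin(dist, axis=1)
    d_nearest = dist[np.arange(len(X)), nearest]
    rows = []
    for i, cid in enumerate(matrix.index):
        reasons = []
        if not d_nearest[i] < d_max:
            reasons.append("distance_gate")
        if not total[i] > min_rna:
            reasons.append("count_gate")
        assigned = not reasons
        rows.append(
            {
                "cell_id": cid,
                "cell_type": str(centroids.index[nearest[i]]) if assigned else UNCLASSIFIED,
                "cosine_distance": float(d_nearest[i]),
                "total_rna": int(total[i]),
                "reason": ";".join(reasons),
            }
        )
    return pd.DataFrame(rows)
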