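"""End-to-end orchestration: files in, QC tables out.

Wires the stage modules together over a canonical on-disk layout
(``fov{F}/r{RR}_ch{CHANNEL}.tif`` z-stacks): per-round LoG detection,
per-gene drift registration to the gene's first round, round summaries,
same-gene colocalization series, the cross-gene specificity control,
and cell typing from a nucleus label mask. All tables are written as
plain CSV; every stochastic stage takes the config seed.
"""

from __future__ import annotations

import re
import shutil
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import celltyping, colocalization, detection, registration
from .simkit import DAPI_CHANNEL, ImageStack

__all__ = [
    "AnalysisConfig",
    "QCReport",
    "reformat_rounds",
    "load_stacks",
    "run_qc",
    "run_typing",
]

CANONICAL_RE = re.compile(
    r"fov(?P<fov>\d+)/r(?P<round>\d+)_ch(?P<channel>[A-Za-z0-9]+)\.tif$"
)


@dataclass
class AnalysisConfig:
    """Shared configuration for the analysis subcommands."""

    data_dir: str
    out_dir: str
    fov: int = 0
    pixel_size_nm: float = 100.0
    z_step_nm: float = 300.0
    detection: detection.DetectionParams = field(default_factory=detection.DetectionParams)
    registration_mode: str = "spots"
    coloc_threshold_um: float = 0.5
    focus_window_px: int = 7
    d_max: float = 0.8
    min_rna: int = 10
    max_assign_dist_um: float = 5.0
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        det = doc.pop("detection", None)
        cfg = cls(**doc)
        if det:
            if "sigma_px" in det:
                det["sigma_px"] = tuple(det["sigma_px"])
            if det.get("background_annulus_px"):
                det["background_annulus_px"] = tuple(det["background_annulus_px"])
            cfg.detection = detection.DetectionParams(**det)
        return cfg


@dataclass
class QCReport:
    round_summary: pd.DataFrame
    drift: pd.DataFrame
    coloc: pd.DataFrame  # same-gene series, one block per gene
    cross_gene: pd.DataFrame | None
    spots: pd.DataFrame
    flags: list[str]


def reformat_rounds(
    raw_dir: str | Path,
    out_dir: str | Path,
    pattern: str = r"(?:fov(?P<fov>\d+)[/_])?r(?P<round>\d+)_ch(?P<channel>[A-Za-z0-9]+)\.tif$",
) -> pd.DataFrame:
    """Copy arbitrarily named acquisitions into the canonical layout.

    ``pattern`` is a regex with named groups ``fov`` (optional, default
    0), ``round`` and ``channel``, matched against each TIFF's path
    relative to ``raw_dir``. Idempotent: files already at their
    canonical destination are left in place. Raises on name collisions
    and on per-FOV round gaps (rounds must cover 1..max). Writes and
    returns a manifest (fov, round, channel, path).
    """
    raw_dir, out_dir = Path(raw_dir), Path(out_dir)
    rx = re.compile(pattern)
    rows = []
    seen: dict[tuple[int, int, str], Path] = {}
    for f in sorted(raw_dir.rglob("*.tif")):
        m = rx.search(f.relative_to(raw_dir).as_posix())
        if not m:
            continue
        fov = int(m.group("fov") or 0)
        rnd = int(m.group("round"))
        ch = m.group("channel")
        key = (fov, rnd, ch)
        if key in seen:
            raise ValueError(f"collision: fov{fov} round {rnd} channel {ch} "
                             f"from both {seen[key]} and {f}")
        seen[key] = f
        dest = out_dir / f"fov{fov}" / f"r{rnd:02d}_ch{ch}.tif"
        if f.resolve() != dest.resolve():
            dest.parent.mkdir(parents=True, exist_ok=True)
            shutil.copyfile(f, dest)
        rows.append({"fov": fov, "round": rnd, "channel": ch, "path": str(dest)})
    manifest = pd.DataFrame(rows, columns=["fov", "round", "channel", "path"])
    for fov, g in manifest[manifest["channel"] != DAPI_CHANNEL].groupby("fov"):
        rounds = set(g["round"])
        gaps = sorted(set(range(1, max(rounds) + 1)) - rounds)
        if gaps:
            raise ValueError(f"fov{fov}: missing round(s) {gaps}")
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest


def load_stacks(
    data_dir: str | Path, fov: int, pixel_size_nm: float = 100.0, z_step_nm: float = 300.0
) -> dict[tuple[int, str], ImageStack]:
    """Read every canonical TIFF of one FOV into ImageStacks."""
    fov_dir = Path(data_dir) / f"fov{fov}"
    stacks: dict[tuple[int, str], ImageStack] = {}
    for f in sorted(fov_dir.glob("r*_ch*.tif")):
        m = re.match(r"r(\d+)_ch(.+)\.tif$", f.name)
        if not m:
            continue
        stacks[(int(m.group(1)), m.group(2))] = ImageStack(
            tifffile.imread(f), pixel_size_nm, z_step_nm
        )
    if not stacks:
        raise FileNotFoundError(f"no canonical TIFFs under {fov_dir}")
    return stacks


def run_qc(config: AnalysisConfig) -> QCReport:
    """Detection -> registration -> summaries -> colocalization, persisted.

    Each gene's rounds are registered to that gene's first round; the
    colocalization series is computed against the same reference. With
    at least two genes, a cross-gene control compares the two genes'
    registered reference rounds. A single-round gene skips
    colocalization with a flag.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    flags: list[str] = []
    stacks = load_stacks(config.data_dir, config.fov, config.pixel_size_nm, config.z_step_nm)
    shape_yx = next(iter(stacks.values())).shape[1:]

    tables = {}
    for (rnd, ch), stack in stacks.items():
        if ch == DAPI_CHANNEL:
            continue
        tables[(rnd, ch)] = detection.detect_spots(stack, config.detection, rnd, ch)

    genes = sorted({ch for _, ch in tables})
    registered: dict[str, dict[int, pd.DataFrame]] = {}
    drift_rows = []
    for gene in genes:
        per_round = {r: t for (r, ch), t in tables.items() if ch == gene}
        ref_round = min(per_round)
        ests = registration.register_rounds(
            tables=per_round,
            stacks={r: stacks[(r, gene)] for r in per_round},
            reference_round=ref_round,
            mode=config.registration_mode,
            shape_yx=shape_yx,
        )
        registered[gene] = {
            e.round: registration.apply_shift(per_round[e.round], e) for e in ests
        }
        dt = registration.drift_table(ests)
        dt.insert(0, "gene", gene)
        drift_rows.append(dt)
    drift = pd.concat(drift_rows, ignore_index=True)

    all_spots = pd.concat(
        [t for g in genes for t in registered[g].values()], ignore_index=True
    )
    expected = sorted({(ch, r) for (r, ch) in tables})
    summary = detection.round_summary(all_spots, expected_rounds=expected)

    coloc_rows = []
    for gene in genes:
        per_round = registered[gene]
        if len(per_round) < 2:
            flags.append(f"{gene}:single_round_no_coloc")
            continue
        series = colocalization.colocalization_series(
            per_round, min(per_round), config.coloc_threshold_um, config.pixel_size_nm
        )
        series.insert(0, "gene", gene)
        coloc_rows.append(series)
    coloc = (
        pd.concat(coloc_rows, ignore_index=True)
        if coloc_rows
        else pd.DataFrame(columns=["gene", "round", "reference_round", "n_query",
                                   "n_matched", "percent", "threshold_um", "flags"])
    )

    cross = None
    if len(genes) >= 2:
        a, b = genes[0], genes[1]
        ta = registered[a][min(registered[a])]
        tb = registered[b][min(registered[b])]
        # channel-pair alignment estimate between the two reference rounds
        dy, dx, pr = registration.phase_correlation_shift(
            registration.spots_to_binary_map(ta, shape_yx).astype(float),
            registration.spots_to_binary_map(tb, shape_yx).astype(float),
        )
        tb = registration.apply_shift(tb, registration.DriftEstimate(0, dy, dx, pr))
        m = colocalization.cross_gene_colocalization(
            ta, tb, config.coloc_threshold_um, config.pixel_size_nm
        )
        cross = pd.DataFrame(
            [{
                "gene_a": a, "gene_b": b, "n_a": m.n_ref, "n_b": m.n_query,
                "n_matched": m.n_matched, "percent": m.percent_colocalized,
                "threshold_um": m.threshold_um, "align_peak_ratio": pr,
            }]
        )

    all_spots.to_csv(out / "spots.csv", index=False)
    drift.to_csv(out / "drift.csv", index=False)
    summary.to_csv(out / "round_summary.csv", index=False)
    coloc.to_csv(out / "coloc.csv", index=False)
    if cross is not None:
        cross.to_csv(out / "cross_gene.csv", index=False)
    return QCReport(summary, drift, coloc, cross, all_spots, flags)


def run_typing(
    config: AnalysisConfig,
    label_mask: np.ndarray,
    centroids: pd.DataFrame,
    spots: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Expression matrix, type calls, and a per-cell spatial map.

    ``spots`` defaults to the registered spot table written by
    :func:`run_qc` (``spots.csv`` under the output directory). Returns
    (matrix, assignments, spatial_map) and writes each as CSV.
    """
    out = Path(config.out_dir)
    if spots is None:
        path = out / "spots.csv"
        if not path.exists():
            raise FileNotFoundError("run_qc outputs not found; run qc first")
        spots = pd.read_csv(path)
    if centroids is None or len(centroids) == 0:
        raise ValueError("centroids are required for typing")
    matrix, spots_assigned = celltyping.assign_spots_to_cells(
        spots, label_mask, config.max_assign_dist_um, config.pixel_size_nm
    )
    calls = celltyping.call_cell_types(matrix, centroids, config.d_max, config.min_rna)
    coms = {}
    for lab in matrix.index:
        ys, xs = np.nonzero(label_mask == lab)
        coms[lab] = (float(ys.mean()), float(xs.mean())) if ys.size else (np.nan, np.nan)
    spatial = calls.assign(
        centroid_y=[coms[c][0] for c in calls["cell_id"]],
        centroid_x=[coms[c][1] for c in calls["cell_id"]],
    )[["cell_id", "centroid_y", "centroid_x", "cell_type", "cosine_distance", "total_rna", "reason"]]
    out.mkdir(parents=True, exist_ok=True)
    matrix.to_csv(out / "expression_matrix.csv")
    calls.to_csv(out / "type_assignments.csv", index=False)
    spatial.to_csv(out / "spatial_map.csv", index=False)
    spots_assigned.to_csv(out / "spots_assigned.csv", index=False)
    return matrix, calls, spatial
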