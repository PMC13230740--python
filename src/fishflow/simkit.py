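"""Synthetic multi-round smFISH data with known ground truth.

Generates desk-scale datasets that emulate the statistical structure of
sequential smFISH experiments: diffraction-limited RNA spots rendered as
3D Gaussians on a noisy background, per-round re-detection dropout,
mechanical stage drift, slow intensity decay over hybridization rounds,
signal amplification on selected rounds, incomplete-stripping residuals,
and a DAPI nucleus channel with a z-dependent defocus model.

Every stochastic choice is driven by a single seed, so the same
:class:`SimConfig` always yields bit-identical ground-truth tables and
images.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage

__all__ = [
    "SimConfig",
    "GroundTruth",
    "ImageStack",
    "generate_experiment",
    "render_spots",
    "render_dapi",
    "nucleus_label_mask",
    "default_round_plan",
    "write_dataset",
    "load_ground_truth",
]

DAPI_CHANNEL = "DAPI"


@dataclass(frozen=True)
class SimConfig:
    """Parameters of a simulated sequential smFISH experiment.

    ``genes`` maps gene name -> {cell type -> mean spot count per cell};
    master spot counts are Poisson with that mean. The default round plan
    alternates the configured genes (gene 1 on odd rounds, gene 2 on even
    rounds); an explicit ``round_plan`` of ``(gene, amplified)`` pairs
    overrides it, e.g. to emulate amplification on specific rounds only.
    """

    field_shape: tuple[int, int, int] = (9, 256, 256)  # (nz, ny, nx)
    pixel_size_nm: float = 100.0
    z_step_nm: float = 300.0
    n_rounds: int = 20
    n_cells: int = 30
    genes: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {"XPO1": {"hela": 20.0}, "KIF1C": {"hela": 20.0}}
    )
    psf_sigma_px: tuple[float, float] = (1.4, 1.5)  # (lateral, axial)
    spot_amplitude: tuple[float, float] = (np.log(150.0), 0.2)  # lognormal (mu, sigma)
    background_level: float = 100.0
    noise_sd: float = 10.0
    redetect_prob: float = 0.9
    drift_per_round_px: float | Sequence[tuple[float, float]] = 5.0
    intensity_decay_per_round: float = 0.98
    amplification_factor: float = 1.0
    amplified_rounds: tuple[int, ...] = ()
    stripping_residual_prob: float = 0.0
    localization_jitter_px: float = 0.1
    defocus_rate: float = 1.0
    nucleus_radius_px: float = 12.0
    round_plan: tuple[tuple[str, bool], ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        nz, ny, nx = self.field_shape
        if min(nz, ny, nx) <= 0:
            raise ValueError("field_shape must be positive")
        if self.n_rounds < 1:
            raise ValueError("n_rounds must be >= 1")
        if self.n_cells < 1:
            raise ValueError("need at least one cell")
        if not self.genes:
            raise ValueError("need at least one gene")
        for p, name in [
            (self.redetect_prob, "redetect_prob"),
            (self.stripping_residual_prob, "stripping_residual_prob"),
        ]:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if not 0.0 < self.intensity_decay_per_round <= 1.0:
            raise ValueError("intensity_decay_per_round must be in (0, 1]")
        if self.amplification_factor < 1.0:
            raise ValueError("amplification_factor must be >= 1")
        bad = set(self.amplified_rounds) - set(range(1, self.n_rounds + 1))
        if bad:
            raise ValueError(f"amplified_rounds outside 1..n_rounds: {sorted(bad)}")
        if self.round_plan is not None and len(self.round_plan) != self.n_rounds:
            raise ValueError("round_plan length must equal n_rounds")

    @property
    def cell_types(self) -> list[str]:
        types: list[str] = []
        for means in self.genes.values():
            for t in means:
                if t not in types:
                    types.append(t)
        return types

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["genes"] = {g: dict(m) for g, m in self.genes.items()}
        return json.dumps(d, indent=2, default=list)


@dataclass
class ImageStack:
    """A 3D intensity array (z, y, x) with physical spacing metadata."""

    data: np.ndarray
    pixel_size_nm: float = 100.0
    z_step_nm: float = 300.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3:
            raise ValueError("ImageStack data must be 3D (z, y, x)")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("ImageStack data must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def mip(self) -> np.ndarray:
        """Maximum intensity projection along z."""
        return self.data.max(axis=0)


@dataclass
class GroundTruth:
    """Synthetic truth tables against which every analysis stage is scored.

    ``cells``: cell_id, cell_type, nucleus_y, nucleus_x, nucleus_radius_px,
    focus_z. ``spots_master``: spot_id, gene, cell_id, z, y, x (drift-free
    frame). ``spots_per_round``: round, spot_id, gene, present, z, y, x
    (rendered frame: truth + drift + jitter), amplitude, residual.
    ``drift``: round, delta_y, delta_x -- the injected offset of each
    round's frame relative to the master frame (round 1 is (0, 0)).
    """

    cells: pd.DataFrame
    spots_master: pd.DataFrame
    spots_per_round: pd.DataFrame
    drift: pd.DataFrame

    def present_spots(self, round_idx: int) -> pd.DataFrame:
        spr = self.spots_per_round
        return spr[(spr["round"] == round_idx) & spr["present"]].reset_index(drop=True)


def default_round_plan(config: SimConfig) -> list[tuple[str, bool]]:
    """Alternating-gene plan: gene 1 on odd rounds, gene 2 on even, etc."""
    if config.round_plan is not None:
        return [(g, bool(a)) for g, a in config.round_plan]
    gene_names = list(config.genes)
    plan = []
    for r in range(1, config.n_rounds + 1):
        gene = gene_names[(r - 1) % len(gene_names)]
        plan.append((gene, r in config.amplified_rounds))
    return plan


def _place_nuclei(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Dart-throwing placement of non-overlapping nucleus disks."""
    _, ny, nx = config.field_shape
    r0 = config.nucleus_radius_px
    centers: list[tuple[float, float]] = []
    radii: list[float] = []
    margin = r0 * 1.2 + 2
    max_tries = 200 * config.n_cells
    tries = 0
    while len(centers) < config.n_cells and tries < max_tries:
        tries += 1
        y = rng.uniform(margin, ny - margin)
        x = rng.uniform(margin, nx - margin)
        r = r0 * rng.uniform(0.85, 1.15)
        ok = all(
            np.hypot(y - yc, x - xc) >= (r + rc) + 2 for (yc, xc), rc in zip(centers, radii)
        )
        if ok:
            centers.append((y, x))
            radii.append(r)
    if len(centers) < config.n_cells:
        raise ValueError(
            f"could only place {len(centers)}/{config.n_cells} nuclei; "
            "enlarge the field or shrink nucleus_radius_px"
        )
    types = config.cell_types
    nz = config.field_shape[0]
    return pd.DataFrame(
        {
            "cell_id": np.arange(1, config.n_cells + 1),
            "cell_type": [types[rng.integers(len(types))] for _ in centers],
            "nucleus_y": [c[0] for c in centers],
            "nucleus_x": [c[1] for c in centers],
            "nucleus_radius_px": radii,
            "focus_z": rng.integers(1, max(2, nz - 1), size=config.n_cells),
        }
    )


def _voronoi_labels(cells: pd.DataFrame, shape_yx: tuple[int, int]) -> np.ndarray:
    """Per-pixel nearest-nucleus label; the simulator's cell regions."""
    ny, nx = shape_yx
    yy, xx = np.mgrid[0:ny, 0:nx]
    best_d = np.full(shape_yx, np.inf)
    labels = np.zeros(shape_yx, dtype=np.int32)
    for _, c in cells.iterrows():
        d = (yy - c["nucleus_y"]) ** 2 + (xx - c["nucleus_x"]) ** 2
        upd = d < best_d
        best_d[upd] = d[upd]
        labels[upd] = int(c["cell_id"])
    return labels


def nucleus_label_mask(cells: pd.DataFrame, shape_yx: tuple[int, int]) -> np.ndarray:
    """Integer label mask of the nucleus disks (0 = background)."""
    ny, nx = shape_yx
    yy, xx = np.mgrid[0:ny, 0:nx]
    mask = np.zeros(shape_yx, dtype=np.int32)
    for _, c in cells.iterrows():
        disk = (yy - c["nucleus_y"]) ** 2 + (xx - c["nucleus_x"]) ** 2 <= c[
            "nucleus_radius_px"
        ] ** 2
        mask[disk] = int(c["cell_id"])
    return mask


def _sample_master_spots(
    config: SimConfig, cells: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    nz, ny, nx = config.field_shape
    sig_lat, sig_ax = config.psf_sigma_px
    margin = 2.0 * sig_lat
    labels = _voronoi_labels(cells, (ny, nx))
    # exclude a 2-sigma border so no PSF is truncated by the field edge
    valid = np.zeros((ny, nx), dtype=bool)
    m = int(np.ceil(margin))
    valid[m : ny - m, m : nx - m] = True
    z_lo = min(2.0 * sig_ax, (nz - 1) / 3.0)
    z_hi = (nz - 1) - z_lo
    rows = []
    spot_id = 0
    for _, c in cells.iterrows():
        cid = int(c["cell_id"])
        region = np.flatnonzero((labels == cid) & valid)
        if region.size == 0:
            continue
        for gene, means in config.genes.items():
            mean = float(means.get(c["cell_type"], 0.0))
            n = rng.poisson(mean)
            if n == 0:
                continue
            pix = rng.choice(region, size=n)
            ys = pix // nx + rng.uniform(-0.5, 0.5, n)
            xs = pix % nx + rng.uniform(-0.5, 0.5, n)
            zs = rng.uniform(z_lo, z_hi, n)
            for z, y, x in zip(zs, ys, xs):
                spot_id += 1
                rows.append((spot_id, gene, cid, z, y, x))
    return pd.DataFrame(rows, columns=["spot_id", "gene", "cell_id", "z", "y", "x"])


def _sample_drift(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    d = config.drift_per_round_px
    rows = [(1, 0.0, 0.0)]
    for r in range(2, config.n_rounds + 1):
        if np.isscalar(d):
            dy, dx = rng.uniform(-d, d, size=2)
        else:
            dy, dx = d[r - 1]
        rows.append((r, float(dy), float(dx)))
    return pd.DataFrame(rows, columns=["round", "delta_y", "delta_x"])


def generate_experiment(
    config: SimConfig,
    render: bool = True,
) -> tuple[dict[tuple[int, str], ImageStack], GroundTruth]:
    """Simulate a full multi-round experiment.

    Returns per-(round, channel) :class:`ImageStack` objects -- the gene
    channel of each round plus a single DAPI stack keyed ``(1, "DAPI")``
    -- and the :class:`GroundTruth` tables. Deterministic given
    ``config.seed``; with ``render=False`` only the ground-truth tables
    are produced (the stack dict is empty) and they are bit-identical to
    the rendered case.
    """
    rng = np.random.default_rng(config.seed)
    cells = _place_nuclei(config, rng)
    master = _sample_master_spots(config, cells, rng)
    drift = _sample_drift(config, rng)
    plan = default_round_plan(config)
    mu, sigma = config.spot_amplitude
    jit = config.localization_jitter_px

    rows = []
    prev_round_rows: list[tuple] = []
    for r, (gene, amplified) in enumerate(plan, start=1):
        dy = float(drift.loc[drift["round"] == r, "delta_y"].iloc[0])
        dx = float(drift.loc[drift["round"] == r, "delta_x"].iloc[0])
        sub = master[master["gene"] == gene]
        decay = config.intensity_decay_per_round ** (r - 1)
        amp_mult = config.amplification_factor if amplified else 1.0
        this_round: list[tuple] = []
        for _, s in sub.iterrows():
            present = bool(rng.random() < config.redetect_prob)
            z = s["z"] + (rng.normal(0.0, jit) if jit > 0 else 0.0)
            y = s["y"] + dy + (rng.normal(0.0, jit) if jit > 0 else 0.0)
            x = s["x"] + dx + (rng.normal(0.0, jit) if jit > 0 else 0.0)
            amp = float(rng.lognormal(mu, sigma)) * decay * amp_mult
            row = (r, int(s["spot_id"]), gene, present, z, y, x, amp, False)
            rows.append(row)
            if present:
                this_round.append(row)
        # incomplete stripping: a fraction of last round's spots bleed
        # through at 20% amplitude
        if config.stripping_residual_prob > 0:
            for prow in prev_round_rows:
                if rng.random() < config.stripping_residual_prob:
                    _, sid, pgene, _, z, y, x, amp, _ = prow
                    ddy = dy - float(drift.loc[drift["round"] == prow[0], "delta_y"].iloc[0])
                    ddx = dx - float(drift.loc[drift["round"] == prow[0], "delta_x"].iloc[0])
                    rows.append((r, sid, pgene, True, z, y + ddy, x + ddx, 0.2 * amp, True))
        prev_round_rows = this_round

    spots_per_round = pd.DataFrame(
        rows,
        columns=[
            "round",
            "spot_id",
            "gene",
            "present",
            "z",
            "y",
            "x",
            "amplitude",
            "residual",
        ],
    )
    truth = GroundTruth(cells, master, spots_per_round, drift)

    stacks: dict[tuple[int, str], ImageStack] = {}
    if not render:
        return stacks, truth
    for r, (gene, _) in enumerate(plan, start=1):
        spr = truth.spots_per_round
        rendered = spr[(spr["round"] == r) & spr["present"]]
        stacks[(r, gene)] = render_spots(
            rendered[["z", "y", "x"]].to_numpy(float),
            config.psf_sigma_px,
            rendered["amplitude"].to_numpy(float),
            config.field_shape,
            config.background_level,
            config.noise_sd,
            rng=rng,
            pixel_size_nm=config.pixel_size_nm,
            z_step_nm=config.z_step_nm,
        )
    stacks[(1, DAPI_CHANNEL)] = render_dapi(
        cells,
        config.field_shape,
        focus_plane=cells["focus_z"].to_numpy(int),
        defocus_rate=config.defocus_rate,
        noise_sd=config.noise_sd,
        rng=rng,
        pixel_size_nm=config.pixel_size_nm,
        z_step_nm=config.z_step_nm,
    )
    return stacks, truth


def render_spots(
    coords_zyx: np.ndarray,
    psf_sigma_px: tuple[float, float],
    amplitudes: np.ndarray,
    field_shape: tuple[int, int, int],
    background_level: float = 0.0,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
    pixel_size_nm: float = 100.0,
    z_step_nm: float = 300.0,
) -> ImageStack:
    """Render spots as 3D Gaussians (peak = amplitude) at subpixel positions.

    Additive Gaussian read noise of sd ``noise_sd`` sits on a constant
    background; shot noise is deliberately not modeled (the SNR of a
    rendered spot is then amplitude / noise_sd by construction).
    """
    coords_zyx = np.atleast_2d(np.asarray(coords_zyx, dtype=float))
    amplitudes = np.atleast_1d(np.asarray(amplitudes, dtype=float))
    if coords_zyx.size and np.any(amplitudes < 0):
        raise ValueError("spot amplitudes must be nonnegative")
    nz, ny, nx = field_shape
    sig_lat, sig_ax = psf_sigma_px
    img = np.full(field_shape, float(background_level), dtype=np.float64)
    wz = int(np.ceil(4 * sig_ax))
    wl = int(np.ceil(4 * sig_lat))
    for (z, y, x), a in zip(coords_zyx, amplitudes):
        z0, z1 = max(0, int(np.floor(z)) - wz), min(nz, int(np.ceil(z)) + wz + 1)
        y0, y1 = max(0, int(np.floor(y)) - wl), min(ny, int(np.ceil(y)) + wl + 1)
        x0, x1 = max(0, int(np.floor(x)) - wl), min(nx, int(np.ceil(x)) + wl + 1)
        if z0 >= z1 or y0 >= y1 or x0 >= x1:
            continue
        zz = np.arange(z0, z1, dtype=float)[:, None, None]
        yy = np.arange(y0, y1, dtype=float)[None, :, None]
        xx = np.arange(x0, x1, dtype=float)[None, None, :]
        g = a * np.exp(
            -((zz - z) ** 2) / (2 * sig_ax**2)
            - ((yy - y) ** 2) / (2 * sig_lat**2)
            - ((xx - x) ** 2) / (2 * sig_lat**2)
        )
        img[z0:z1, y0:y1, x0:x1] += g
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng()
        img += rng.normal(0.0, noise_sd, size=img.shape)
    return ImageStack(np.clip(img, 0, None), pixel_size_nm, z_step_nm)


def render_dapi(
    cells: pd.DataFrame,
    field_shape: tuple[int, int, int],
    focus_plane: int | np.ndarray,
    defocus_rate: float,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
    texture_amplitude: float = 0.6,
    nucleus_intensity: float = 300.0,
    background_level: float = 50.0,
    pixel_size_nm: float = 100.0,
    z_step_nm: float = 300.0,
) -> ImageStack:
    """Render a DAPI z-stack with a per-nucleus focus plane.

    Each nucleus is a disk with granular multiplicative texture; plane z
    is blurred with sigma = defocus_rate * |z - focus_plane(nucleus)|, so
    the plane at the nucleus's focus_plane is its sharpest.
    """
    nz, ny, nx = field_shape
    if rng is None:
        rng = np.random.default_rng()
    focus = np.broadcast_to(np.asarray(focus_plane, dtype=int), (len(cells),))
    if np.any((focus < 0) | (focus >= nz)):
        raise ValueError("focus_plane must lie within the stack")
    img = np.full(field_shape, float(background_level), dtype=np.float64)
    for (_, c), fz in zip(cells.iterrows(), focus):
        r = float(c["nucleus_radius_px"])
        cy, cx = float(c["nucleus_y"]), float(c["nucleus_x"])
        pad = int(np.ceil(r + 4 + defocus_rate * nz))
        y0, y1 = max(0, int(cy) - pad), min(ny, int(cy) + pad + 1)
        x0, x1 = max(0, int(cx) - pad), min(nx, int(cx) + pad + 1)
        yy, xx = np.mgrid[y0:y1, x0:x1]
        disk = ((yy - cy) ** 2 + (xx - cx) ** 2) <= r**2
        texture = rng.normal(0.0, 1.0, size=disk.shape)
        texture = ndimage.gaussian_filter(texture, 1.0)
        texture /= max(np.abs(texture).max(), 1e-12)
        base = nucleus_intensity * (1.0 + texture_amplitude * texture) * disk
        for z in range(nz):
            sigma = defocus_rate * abs(z - int(fz))
            plane = ndimage.gaussian_filter(base, sigma) if sigma > 0 else base
            img[z, y0:y1, x0:x1] += plane
    if noise_sd > 0:
        img += rng.normal(0.0, noise_sd, size=img.shape)
    return ImageStack(np.clip(img, 0, None), pixel_size_nm, z_step_nm)


# ---------------------------------------------------------------------------
# disk I/O: canonical layout `fov{F}/r{RR}_ch{channel}.tif` + CSV truth


def write_dataset(
    outdir: str | Path,
    stacks: Mapping[tuple[int, str], ImageStack],
    truth: GroundTruth,
    config: SimConfig,
    fov: int = 0,
) -> Path:
    outdir = Path(outdir)
    fov_dir = outdir / f"fov{fov}"
    fov_dir.mkdir(parents=True, exist_ok=True)
    for (r, channel), stack in stacks.items():
        tifffile.imwrite(fov_dir / f"r{r:02d}_ch{channel}.tif", stack.data)
    truth.cells.to_csv(outdir / "cells.csv", index=False)
    truth.spots_master.to_csv(outdir / "spots_master.csv", index=False)
    truth.spots_per_round.to_csv(outdir / "spots_rounds.csv", index=False)
    truth.drift.to_csv(outdir / "drift.csv", index=False)
    (outdir / "sim_config.json").write_text(config.to_json())
    return outdir


def load_ground_truth(outdir: str | Path) -> GroundTruth:
    outdir = Path(outdir)
    return GroundTruth(
        cells=pd.read_csv(outdir / "cells.csv"),
        spots_master=pd.read_csv(outdir / "spots_master.csv"),
        spots_per_round=pd.read_csv(outdir / "spots_rounds.csv"),
        drift=pd.read_csv(outdir / "drift.csv"),
    )
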