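"""Synthetic circFISH z-stacks with exact ground truth.

The generator emulates the computational substrate of a two-channel
circRNA smFISH experiment on adherent cells:

* elliptical nuclei placed without overlap on a 2D field (DAPI), with cell
  territories given by the nearest-nucleus partition clipped to a fixed
  dilation of the nuclei (a stand-in for unstained cell boundaries);
* per cell and RNA class (full-length linear, circular, linear fragment),
  molecule counts drawn Poisson with configurable means, each molecule
  assigned to the nucleus with a class-specific probability and placed
  uniformly in that compartment, z uniform over the stack depth;
* diffraction-limited rendering: every molecule contributes an anisotropic
  3D Gaussian (the PSF) to its channel(s). Linear molecules co-emit in both
  the PL and PC channels (the PC copy offset by a small per-molecule
  channel-registration jitter), circular molecules appear only in PC, and
  fragments only in PL; shot (Poisson) noise and Gaussian read noise are
  added on top of a constant background;
* scenario transforms: in-situ RNase R digestion as exponential decay in
  time (linear and fragment molecules with a short half-life, circles with
  a much longer one), and shRNA knockdown as class-specific thinning.

Decay uses per-molecule uniforms drawn once at sampling time, so applying
RNase R at a longer duration always yields a subset of the survivors at a
shorter one — an in-silico time course on one sample, matching how the
wet-lab control treats the same specimen for increasing durations.

Everything is a pure function of the config and its seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import tifffile
import yaml
from scipy import ndimage
from skimage.draw import ellipse as draw_ellipse

from .io import ImageStack

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "RNA_CLASSES",
    "generate_cells",
    "sample_molecules",
    "render",
    "render_multiplex",
    "apply_rnase_r",
    "apply_knockdown",
    "simulate_scene",
    "write_ground_truth",
]

RNA_CLASSES = ("linear", "circular", "fragment")

#: physical colocalization radius the classifier will use downstream
_COLOC_RADIUS_NM = 250.0


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of one synthetic experiment.

    Defaults reproduce the acquisition geometry of a 100x / cooled-CCD
    epifluorescence setup: 16 z-slices 200 nm apart, 130 nm pixels, PSF
    sigma 170 nm laterally and 350 nm axially. Per-cell means and nuclear
    fractions default to a moderately expressed gene whose linear isoform
    is mostly cytoplasmic while the circle splits evenly between
    compartments.
    """

    field_shape: tuple[int, int, int] = (16, 512, 512)
    voxel_size_nm: tuple[float, float, float] = (200.0, 130.0, 130.0)
    n_cells: int = 10
    mean_counts: Mapping[str, float] = field(
        default_factory=lambda: {"linear": 30.0, "circular": 10.0, "fragment": 3.0}
    )
    nuclear_fraction: Mapping[str, float] = field(
        default_factory=lambda: {"linear": 0.25, "circular": 0.50, "fragment": 0.25}
    )
    psf_sigma_nm: tuple[float, float] = (350.0, 170.0)  # (z, xy)
    spot_amplitude: float = 200.0
    background_level: float = 10.0
    read_noise_sd: float = 2.0
    registration_sd_nm: float = 50.0
    rng_seed: int = 0
    noise: bool = True
    count_model: str = "poisson"  # "poisson" | "fixed" | "negative_binomial"
    nb_dispersion: float = 0.0  # extra-Poisson dispersion for the NB option
    nucleus_semiaxis_px: tuple[float, float] = (32.0, 48.0)
    nucleus_aspect_max: float = 1.3
    cyto_radius_px: int = 30
    dapi_amplitude: float = 300.0
    min_molecule_separation_nm: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "field_shape", tuple(int(v) for v in self.field_shape))
        object.__setattr__(
            self, "voxel_size_nm", tuple(float(v) for v in self.voxel_size_nm)
        )
        object.__setattr__(self, "psf_sigma_nm", tuple(float(v) for v in self.psf_sigma_nm))
        object.__setattr__(self, "mean_counts", dict(self.mean_counts))
        object.__setattr__(self, "nuclear_fraction", dict(self.nuclear_fraction))
        for cls in RNA_CLASSES:
            if self.mean_counts.get(cls, 0.0) < 0:
                raise ValueError(f"mean count for {cls} must be non-negative")
            frac = self.nuclear_fraction.get(cls, 0.0)
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"nuclear fraction for {cls} must be in [0, 1]")
        if self.count_model not in ("poisson", "fixed", "negative_binomial"):
            raise ValueError(f"unknown count_model {self.count_model!r}")
        if self.psf_sigma_nm[1] >= _COLOC_RADIUS_NM:
            warnings.warn(
                f"lateral PSF sigma {self.psf_sigma_nm[1]} nm is not below the "
                f"{_COLOC_RADIUS_NM:.0f} nm colocalization radius; "
                "classification will be unreliable",
                stacklevel=2,
            )

    def rng(self, stream: int) -> np.random.Generator:
        """Independent generator for one named stage of the simulation."""
        return np.random.default_rng([int(self.rng_seed), int(stream)])

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_dict(self) -> dict:
        return asdict(self)


# rng stream ids, one per stochastic stage
_STREAM_CELLS, _STREAM_MOLECULES, _STREAM_JITTER, _STREAM_NOISE = 1, 2, 3, 4


@dataclass
class GroundTruth:
    """Molecule table plus the label maps and config that produced it."""

    molecules: pd.DataFrame
    nuclear_label_map: np.ndarray
    cell_label_map: np.ndarray
    config: SimulationConfig

    def __post_init__(self) -> None:
        if self.nuclear_label_map.shape != self.cell_label_map.shape:
            raise ValueError("label maps must share shape")
        if len(self.molecules):
            known = set(np.unique(self.cell_label_map)) - {0}
            missing = set(self.molecules["cell_id"]) - known
            if missing:
                raise ValueError(f"molecules reference unknown cells {sorted(missing)}")

    def class_counts(self) -> dict[str, int]:
        vc = self.molecules["rna_class"].value_counts()
        return {cls: int(vc.get(cls, 0)) for cls in RNA_CLASSES}


def generate_cells(config: SimulationConfig) -> tuple[np.ndarray, np.ndarray]:
    """Place non-overlapping elliptical nuclei and carve cell territories.

    Nuclei are kept far enough from the border that every territory lies
    fully inside the field, so border-clipping never biases per-cell
    statistics. Returns ``(nuclear_label_map, cell_label_map)`` as int32
    2D arrays with matching label ids and background 0.
    """
    if config.n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    rng = config.rng(_STREAM_CELLS)
    _, n_y, n_x = config.field_shape
    a_lo, a_hi = config.nucleus_semiaxis_px
    margin = a_hi + config.cyto_radius_px + 2
    if n_y - 2 * margin <= 0 or n_x - 2 * margin <= 0:
        raise ValueError(
            f"field {n_y}x{n_x} too small for nuclei of semi-axis up to "
            f"{a_hi:.0f} px plus a {config.cyto_radius_px} px cytoplasmic rim; "
            "use a larger field"
        )
    placed: list[tuple[float, float, float]] = []  # (cy, cx, major)
    params = []
    max_tries = 2000 * config.n_cells
    tries = 0
    while len(params) < config.n_cells:
        if tries >= max_tries:
            raise RuntimeError(
                f"placed only {len(params)}/{config.n_cells} nuclei after "
                f"{max_tries} attempts; use a larger field or fewer cells"
            )
        tries += 1
        b = rng.uniform(a_lo, a_hi)
        a = b * rng.uniform(1.0, config.nucleus_aspect_max)
        cy = rng.uniform(margin, n_y - margin)
        cx = rng.uniform(margin, n_x - margin)
        if any(np.hypot(cy - py, cx - px) < a + pa + 4 for py, px, pa in placed):
            continue
        placed.append((cy, cx, a))
        params.append((cy, cx, a, b, rng.uniform(0, np.pi)))

    nuclear = np.zeros((n_y, n_x), dtype=np.int32)
    for label, (cy, cx, a, b, theta) in enumerate(params, start=1):
        rr, cc = draw_ellipse(cy, cx, a, b, shape=(n_y, n_x), rotation=theta)
        nuclear[rr, cc] = label

    # nearest-nucleus partition, clipped to a fixed-radius dilation
    dist, (iy, ix) = ndimage.distance_transform_edt(
        nuclear == 0, return_indices=True
    )
    cells = nuclear[iy, ix].astype(np.int32)
    cells[dist > config.cyto_radius_px] = 0
    return nuclear, cells


def _pixels_by_label(label_map: np.ndarray) -> dict[int, np.ndarray]:
    """Map label -> (n, 2) array of (y, x) pixel coordinates."""
    flat = label_map.ravel()
    order = np.argsort(flat, kind="stable")
    sorted_labels = flat[order]
    coords = np.column_stack(np.unravel_index(order, label_map.shape))
    labels, starts = np.unique(sorted_labels, return_index=True)
    bounds = np.append(starts, flat.size)
    return {
        int(lab): coords[bounds[i] : bounds[i + 1]]
        for i, lab in enumerate(labels)
        if lab != 0
    }


def sample_molecules(
    config: SimulationConfig,
    nuclear_label_map: np.ndarray,
    cell_label_map: np.ndarray,
) -> GroundTruth:
    """Draw molecule counts, compartments and 3D positions for every cell.

    Each molecule also receives two latent uniforms, ``decay_u`` and
    ``kd_u``, consumed by :func:`apply_rnase_r` and :func:`apply_knockdown`
    so that scenario transforms of one ground truth are mutually
    consistent (longer digestion keeps a subset of shorter digestion).
    """
    rng = config.rng(_STREAM_MOLECULES)
    n_z = config.field_shape[0]
    vz, vy, vx = config.voxel_size_nm
    nuc_px = _pixels_by_label(nuclear_label_map)
    cyto_map = np.where(nuclear_label_map > 0, 0, cell_label_map)
    cyto_px = _pixels_by_label(cyto_map)
    cell_ids = sorted(set(np.unique(cell_label_map)) - {0})

    rows: list[dict] = []
    accepted_nm: list[np.ndarray] = []
    min_sep = config.min_molecule_separation_nm
    mol_id = 0
    for cell_id in cell_ids:
        for cls in RNA_CLASSES:
            mean = config.mean_counts.get(cls, 0.0)
            if config.count_model == "fixed":
                n = int(round(mean))
            elif config.count_model == "negative_binomial" and config.nb_dispersion > 0:
                # NB with mean m, variance m + d*m^2
                d = config.nb_dispersion
                r = 1.0 / d
                p = r / (r + mean) if mean > 0 else 1.0
                n = int(rng.negative_binomial(r, p)) if mean > 0 else 0
            else:
                n = int(rng.poisson(mean)) if mean > 0 else 0
            for _ in range(n):
                nuclearp = rng.random() < config.nuclear_fraction.get(cls, 0.0)
                pool = nuc_px if nuclearp else cyto_px
                pixels = pool.get(cell_id)
                if pixels is None or len(pixels) == 0:  # degenerate compartment
                    pixels = nuc_px.get(cell_id)
                    nuclearp = True
                for _attempt in range(50):
                    y_pix, x_pix = pixels[rng.integers(len(pixels))]
                    pos = np.array(
                        [
                            rng.uniform(0, n_z - 1) * vz,
                            (y_pix + rng.uniform(-0.5, 0.5)) * vy,
                            (x_pix + rng.uniform(-0.5, 0.5)) * vx,
                        ]
                    )
                    if min_sep <= 0 or not accepted_nm:
                        break
                    d = np.linalg.norm(np.asarray(accepted_nm) - pos, axis=1)
                    if d.min() >= min_sep:
                        break
                else:
                    warnings.warn(
                        "could not honor min_molecule_separation_nm; "
                        "placing molecule anyway",
                        stacklevel=2,
                    )
                if min_sep > 0:
                    accepted_nm.append(pos)
                rows.append(
                    {
                        "molecule_id": mol_id,
                        "cell_id": cell_id,
                        "rna_class": cls,
                        "z_nm": pos[0],
                        "y_nm": pos[1],
                        "x_nm": pos[2],
                        "compartment": "nuclear" if nuclearp else "cytoplasmic",
                        "decay_u": rng.random(),
                        "kd_u": rng.random(),
                    }
                )
                mol_id += 1
    columns = [
        "molecule_id", "cell_id", "rna_class", "z_nm", "y_nm", "x_nm",
        "compartment", "decay_u", "kd_u",
    ]
    molecules = pd.DataFrame(rows, columns=columns)
    return GroundTruth(molecules, nuclear_label_map, cell_label_map, config)


def _add_gaussians(
    volume: np.ndarray,
    positions_nm: np.ndarray,
    amplitude: float,
    sigma_vox: tuple[float, float, float],
    voxel_size_nm: tuple[float, float, float],
) -> None:
    """Accumulate one peak-normalized anisotropic 3D Gaussian per position."""
    if len(positions_nm) == 0:
        return
    shape = volume.shape
    half = [int(np.ceil(4 * s)) for s in sigma_vox]
    centers = positions_nm / np.asarray(voxel_size_nm)
    for cz, cy, cx in centers:
        zlo = max(int(np.floor(cz)) - half[0], 0)
        zhi = min(int(np.ceil(cz)) + half[0] + 1, shape[0])
        ylo = max(int(np.floor(cy)) - half[1], 0)
        yhi = min(int(np.ceil(cy)) + half[1] + 1, shape[1])
        xlo = max(int(np.floor(cx)) - half[2], 0)
        xhi = min(int(np.ceil(cx)) + half[2] + 1, shape[2])
        if zlo >= zhi or ylo >= yhi or xlo >= xhi:
            continue
        gz = np.exp(-0.5 * ((np.arange(zlo, zhi) - cz) / sigma_vox[0]) ** 2)
        gy = np.exp(-0.5 * ((np.arange(ylo, yhi) - cy) / sigma_vox[1]) ** 2)
        gx = np.exp(-0.5 * ((np.arange(xlo, xhi) - cx) / sigma_vox[2]) ** 2)
        volume[zlo:zhi, ylo:yhi, xlo:xhi] += (
            amplitude * gz[:, None, None] * gy[None, :, None] * gx[None, None, :]
        )


def _class_positions(molecules: pd.DataFrame, classes: tuple[str, ...]) -> np.ndarray:
    sub = molecules[molecules["rna_class"].isin(classes)]
    return sub[["z_nm", "y_nm", "x_nm"]].to_numpy(dtype=float)


def render(
    ground_truth: GroundTruth,
    config: SimulationConfig | None = None,
    channels: tuple[str, ...] = ("PL", "PC", "DAPI"),
) -> ImageStack:
    """Render PL, PC and DAPI channels from a ground truth.

    Linear molecules emit in both FISH channels (PC offset by per-molecule
    registration jitter), circles in PC only, fragments in PL only. DAPI is
    the nuclear mask extruded through z. With ``config.noise`` the rendered
    photon counts get Poisson shot noise plus Gaussian read noise, clipped
    at zero. ``channels`` can drop unneeded channels (e.g. DAPI) to save
    work.
    """
    cfg = config or ground_truth.config
    vz, vy, vx = cfg.voxel_size_nm
    sigma_vox = (
        cfg.psf_sigma_nm[0] / vz,
        cfg.psf_sigma_nm[1] / vy,
        cfg.psf_sigma_nm[1] / vx,
    )
    mols = ground_truth.molecules
    out: dict[str, np.ndarray] = {}

    if "PL" in channels:
        pl = np.zeros(cfg.field_shape, dtype=float)
        pl_pos = _class_positions(mols, ("linear", "fragment"))
        _add_gaussians(pl, pl_pos, cfg.spot_amplitude, sigma_vox, cfg.voxel_size_nm)
        out["PL"] = pl

    if "PC" in channels:
        pc = np.zeros(cfg.field_shape, dtype=float)
        jitter_rng = cfg.rng(_STREAM_JITTER)
        linear_pos = _class_positions(mols, ("linear",))
        if len(linear_pos):
            linear_pos = linear_pos + jitter_rng.normal(
                0.0, cfg.registration_sd_nm, size=linear_pos.shape
            )
        circ_pos = _class_positions(mols, ("circular",))
        pc_pos = (
            np.vstack([linear_pos, circ_pos]) if len(mols) else np.empty((0, 3))
        )
        _add_gaussians(pc, pc_pos, cfg.spot_amplitude, sigma_vox, cfg.voxel_size_nm)
        out["PC"] = pc

    if "DAPI" in channels:
        out["DAPI"] = np.broadcast_to(
            (ground_truth.nuclear_label_map > 0) * cfg.dapi_amplitude,
            cfg.field_shape,
        ).astype(float).copy()

    for vol in out.values():
        vol += cfg.background_level
    if cfg.noise:
        noise_rng = cfg.rng(_STREAM_NOISE)
        for name, vol in out.items():
            noisy = noise_rng.poisson(vol).astype(float)
            noisy += noise_rng.normal(0.0, cfg.read_noise_sd, size=vol.shape)
            out[name] = np.clip(noisy, 0.0, None)
    return ImageStack(channels=out, voxel_size_nm=cfg.voxel_size_nm)


def render_multiplex(
    ground_truths: Mapping[str, GroundTruth],
    config: SimulationConfig | None = None,
) -> ImageStack:
    """Render one channel per circRNA probe set plus a shared DAPI channel.

    Each channel shows whatever its PC probe set would bind in that ground
    truth: full-length linear plus circular molecules (after RNase R the
    linear class is empty and only circles remain). All ground truths must
    share the same cell geometry.
    """
    if not ground_truths:
        raise ValueError("need at least one ground truth")
    first = next(iter(ground_truths.values()))
    cfg = config or first.config
    vz, vy, vx = cfg.voxel_size_nm
    sigma_vox = (
        cfg.psf_sigma_nm[0] / vz,
        cfg.psf_sigma_nm[1] / vy,
        cfg.psf_sigma_nm[1] / vx,
    )
    channels: dict[str, np.ndarray] = {}
    for name, gt in ground_truths.items():
        vol = np.zeros(cfg.field_shape, dtype=float)
        pos = _class_positions(gt.molecules, ("linear", "circular"))
        _add_gaussians(vol, pos, cfg.spot_amplitude, sigma_vox, cfg.voxel_size_nm)
        channels[name] = vol
    channels["DAPI"] = np.broadcast_to(
        (first.nuclear_label_map > 0) * cfg.dapi_amplitude, cfg.field_shape
    ).astype(float).copy()
    for vol in channels.values():
        vol += cfg.background_level
    if cfg.noise:
        noise_rng = cfg.rng(_STREAM_NOISE)
        for name, vol in channels.items():
            noisy = noise_rng.poisson(vol).astype(float)
            noisy += noise_rng.normal(0.0, cfg.read_noise_sd, size=vol.shape)
            channels[name] = np.clip(noisy, 0.0, None)
    return ImageStack(channels=channels, voxel_size_nm=cfg.voxel_size_nm)


def apply_rnase_r(
    ground_truth: GroundTruth,
    t_hours: float,
    linear_half_life_h: float = 1.0,
    circular_half_life_h: float = 48.0,
) -> GroundTruth:
    """Digest the sample in silico for ``t_hours``.

    Each molecule of class ``c`` survives with probability
    ``2 ** (-t / half_life(c))``; fragments share the linear half-life
    (both have open ends). Survival is decided by the molecule's latent
    ``decay_u``, so survivors at a longer duration are a subset of
    survivors at any shorter one.
    """
    if t_hours < 0:
        raise ValueError("t_hours must be >= 0")
    if linear_half_life_h <= 0 or circular_half_life_h <= 0:
        raise ValueError("half-lives must be positive")
    mols = ground_truth.molecules
    if t_hours == 0 or len(mols) == 0:
        return replace(ground_truth, molecules=mols.copy())
    survival = {
        "linear": 2.0 ** (-t_hours / linear_half_life_h),
        "fragment": 2.0 ** (-t_hours / linear_half_life_h),
        "circular": 2.0 ** (-t_hours / circular_half_life_h),
    }
    keep = mols["decay_u"] < mols["rna_class"].map(survival)
    return replace(ground_truth, molecules=mols[keep].reset_index(drop=True))


def apply_knockdown(
    ground_truth: GroundTruth,
    target_class: str,
    efficiency: float,
) -> GroundTruth:
    """shRNA-style thinning: ``target_class`` survives with prob 1-efficiency."""
    if target_class not in ("linear", "circular"):
        raise ValueError("target_class must be 'linear' or 'circular'")
    if not 0.0 <= efficiency <= 1.0:
        raise ValueError("efficiency must be in [0, 1]")
    mols = ground_truth.molecules
    if len(mols) == 0:
        return replace(ground_truth, molecules=mols.copy())
    keep = (mols["rna_class"] != target_class) | (mols["kd_u"] >= efficiency)
    return replace(ground_truth, molecules=mols[keep].reset_index(drop=True))


def simulate_scene(config: SimulationConfig) -> tuple[GroundTruth, ImageStack]:
    """Cells + molecules + rendered stack in one call."""
    nuclear, cells = generate_cells(config)
    gt = sample_molecules(config, nuclear, cells)
    return gt, render(gt, config)


def write_ground_truth(ground_truth: GroundTruth, out_dir: str | Path) -> None:
    """Write the molecule table as CSV and the label maps as 16-bit TIFFs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ground_truth.molecules.to_csv(out / "molecules.csv", index=False)
    tifffile.imwrite(
        str(out / "nuclear_labels.tif"),
        ground_truth.nuclear_label_map.astype(np.uint16),
    )
    tifffile.imwrite(
        str(out / "cell_labels.tif"),
        ground_truth.cell_label_map.astype(np.uint16),
    )
    with open(out / "sim_config.yaml", "w") as fh:
        yaml.safe_dump(ground_truth.config.to_dict(), fh)
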