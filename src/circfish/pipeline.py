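"""End-to-end pipeline: detect -> classify -> quantify.

One config object (loadable from YAML) names the input stack, maps channel
names to roles (PL / PC / PC2... / DAPI), and carries detection and
matching parameters. The pipeline is a pure function of (inputs, config,
seed): rerunning it over the same inputs writes byte-identical tables.

Two modes fall out of the channel roles: the standard two-channel run
(one PL + one PC channel) classifies spots into linear / circular /
fragment; a PC-only run with several PC channels (the RNase-R multiplex
protocol) counts each circRNA channel independently.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .classify import classify, match_spots, multiplex_counts, DEFAULT_RADIUS_NM
from .detect import DetectionParams, detect_spots, spots_to_frame
from .io import ImageStack, read_stack
from .quantify import (
    DEFAULT_MIN_CELLS,
    SegmentationParams,
    assign_spots,
    localization_fractions,
    per_cell_counts,
    segment_nuclei,
)

log = logging.getLogger("circfish")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    stack_path: str
    channel_roles: dict[str, str]  # channel name -> {PL, PC, PC2..., DAPI}
    voxel_size_nm: tuple[float, float, float] | None = None
    sigma_nm: tuple[float, float] = (350.0, 170.0)
    threshold: float | str = "auto"
    min_separation_voxels: int = 1
    radius_nm: float = DEFAULT_RADIUS_NM
    min_cells: int = DEFAULT_MIN_CELLS
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    seed: int = 0
    out_dir: str = "circfish_out"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "segmentation" in raw:
            raw["segmentation"] = SegmentationParams(**raw["segmentation"])
        return cls(**raw)

    def fish_channels(self) -> dict[str, str]:
        return {c: r for c, r in self.channel_roles.items() if r != "DAPI"}

    def dapi_channel(self) -> str | None:
        for c, r in self.channel_roles.items():
            if r == "DAPI":
                return c
        return None


def _detect_all(
    stack: ImageStack, config: PipelineConfig
) -> dict[str, pd.DataFrame]:
    params = DetectionParams(
        sigma_nm=config.sigma_nm,
        threshold=config.threshold,
        min_separation_voxels=config.min_separation_voxels,
    )
    spots = {}
    for channel in config.fish_channels():
        found = detect_spots(
            stack[channel], params, stack.voxel_size_nm, channel=channel
        )
        spots[channel] = spots_to_frame(found)
        log.info("detect: %d spots in channel %s", len(found), channel)
    return spots


def run_pipeline(config: PipelineConfig) -> dict:
    """Run detection, classification and quantification; write all outputs.

    Returns a result dict mirroring the summary JSON written to
    ``out_dir/summary.json``. Raises on any stage failure (missing
    channels, unreadable stack, blank DAPI, ...).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "pipeline.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        log.info(
            "circfish %s | python %s | seed %d | config %s",
            __version__, sys.version.split()[0], config.seed, asdict(config),
        )
        stack = read_stack(
            config.stack_path,
            channels=list(config.channel_roles),
            voxel_size_nm=config.voxel_size_nm,
        )
        missing = set(config.channel_roles) - set(stack.channels)
        if missing:
            raise ValueError(f"channels {sorted(missing)} not present in stack")

        spot_frames = _detect_all(stack, config)
        for channel, frame in spot_frames.items():
            frame.to_csv(out / f"spots_{channel}.csv", index=False)

        roles = config.fish_channels()
        by_role = {role: ch for ch, role in roles.items()}
        result: dict = {
            "version": __version__,
            "seed": config.seed,
            "n_spots": {ch: len(f) for ch, f in spot_frames.items()},
        }

        pc_roles = sorted(r for r in by_role if r.startswith("PC"))
        if "PL" in by_role and "PC" in by_role:
            pl_df, pc_df = spot_frames[by_role["PL"]], spot_frames[by_role["PC"]]
            match = match_spots(pl_df, pc_df, radius_nm=config.radius_nm)
            classified = classify(match, pl_df, pc_df)
            classified_df = classified.to_frame()
            classified_df.to_csv(out / "classified.csv", index=False)
            result["class_counts"] = classified.counts
            log.info("classify: %s", classified.counts)
        elif pc_roles:
            counts, bleed = multiplex_counts(
                {r: spot_frames[by_role[r]] for r in pc_roles},
                radius_nm=config.radius_nm,
            )
            result["multiplex_counts"] = counts
            result["bleedthrough_warnings"] = [list(w) for w in bleed]
            classified_df = None
            log.info("multiplex counts: %s", counts)
        else:
            raise ValueError("channel_roles must define PL+PC or PC channels")

        dapi = config.dapi_channel()
        if dapi is not None and classified_df is not None:
            maps = segment_nuclei(stack[dapi], config.segmentation)
            annotated = assign_spots(classified_df, maps, stack.voxel_size_nm)
            annotated.to_csv(out / "classified_assigned.csv", index=False)
            counts = per_cell_counts(annotated, maps)
            counts.to_csv(out / "per_cell_counts.csv", index=False)
            fractions = localization_fractions(counts)
            fractions.to_csv(out / "localization_fractions.csv", index=False)
            result["n_cells"] = len(counts)
            result["mean_per_cell"] = {
                cls: float(counts[cls].mean()) for cls in ("linear", "circular", "fragment")
            }
            result["nuclear_fraction"] = {
                row["class"]: row["nuclear_fraction"]
                for _, row in fractions.iterrows()
            }
            log.info("quantify: %d cells, means %s", len(counts), result["mean_per_cell"])
        elif dapi is None and classified_df is not None:
            log.info("no DAPI channel configured; skipping per-cell quantification")

        with open(out / "summary.json", "w") as fh:
            json.dump(result, fh, indent=2, sort_keys=True)
        return result
    finally:
        log.removeHandler(handler)
        handler.close()
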