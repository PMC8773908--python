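"""Image-stack container and TIFF round-trip.

Stacks are stored channel-major, ``(C, Z, Y, X)``, one page per z-slice, with
channel names and physical voxel sizes (nm, axis order z/y/x) embedded as a
JSON TIFF description and echoed to a sidecar so that a stack written here is
fully self-describing. Voxel sizes supplied by a caller's config win over the
embedded metadata, with a logged warning on conflict.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile

log = logging.getLogger("circfish")

__all__ = ["ImageStack", "read_stack", "write_stack"]


@dataclass
class ImageStack:
    """Named 3D intensity volumes sharing one shape and voxel size."""

    channels: dict[str, np.ndarray]
    voxel_size_nm: tuple[float, float, float]

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("ImageStack needs at least one channel")
        shapes = {name: v.shape for name, v in self.channels.items()}
        if len(set(shapes.values())) != 1:
            raise ValueError(f"channel shapes differ: {shapes}")
        for name, vol in self.channels.items():
            if vol.ndim != 3:
                raise ValueError(f"channel {name!r} is not 3D: shape {vol.shape}")
            if not np.all(np.isfinite(vol)) or vol.min() < 0:
                raise ValueError(f"channel {name!r} has non-finite or negative values")
        self.voxel_size_nm = tuple(float(v) for v in self.voxel_size_nm)

    @property
    def shape(self) -> tuple[int, int, int]:
        return next(iter(self.channels.values())).shape

    def __getitem__(self, name: str) -> np.ndarray:
        return self.channels[name]


def write_stack(stack: ImageStack, path: str | Path) -> None:
    """Write all channels as one (C, Z, Y, X) float32 TIFF with JSON metadata."""
    names = list(stack.channels)
    data = np.stack([stack.channels[n] for n in names]).astype(np.float32)
    meta = {"channels": names, "voxel_size_nm": list(stack.voxel_size_nm)}
    tifffile.imwrite(str(path), data, description=json.dumps(meta))


def _embedded_metadata(tif: tifffile.TiffFile) -> dict:
    desc = tif.pages[0].description or ""
    try:
        meta = json.loads(desc)
        return meta if isinstance(meta, dict) else {}
    except (json.JSONDecodeError, TypeError):
        return {}


def read_stack(
    path: str | Path,
    channels: list[str] | None = None,
    voxel_size_nm: tuple[float, float, float] | None = None,
) -> ImageStack:
    """Read a multi-page TIFF into an ImageStack.

    A 4D file is taken as (C, Z, Y, X). A plain 3D page stack is split into
    ``len(channels)`` contiguous blocks (each fluorescence wavelength
    acquired as its own z-series); the page count must divide evenly.
    """
    path = Path(path)
    try:
        with tifffile.TiffFile(str(path)) as tif:
            data = tif.asarray()
            meta = _embedded_metadata(tif)
    except (OSError, ValueError) as exc:
        raise ValueError(f"cannot read TIFF {path}: {exc}") from exc

    meta_channels = meta.get("channels")
    if channels is None:
        channels = meta_channels
    elif meta_channels is not None:
        missing = set(channels) - set(meta_channels)
        if missing:
            raise ValueError(
                f"{path}: channels {sorted(missing)} not present in stack "
                f"(file has {meta_channels})"
            )
    if data.ndim == 2:
        data = data[None]
    if data.ndim == 3:
        if channels is None:
            channels = ["ch0"]
        n_c = len(channels)
        if data.shape[0] % n_c != 0:
            raise ValueError(
                f"{path}: {data.shape[0]} pages are not divisible by "
                f"{n_c} channels"
            )
        data = data.reshape(n_c, data.shape[0] // n_c, *data.shape[1:])
    elif data.ndim == 4:
        if channels is None:
            channels = [f"ch{i}" for i in range(data.shape[0])]
        if meta_channels is None and data.shape[0] != len(channels):
            raise ValueError(
                f"{path}: file has {data.shape[0]} channels, config names "
                f"{len(channels)}"
            )
    else:
        raise ValueError(f"{path}: unsupported dimensionality {data.ndim}")

    if data.ndim == 4 and meta_channels is not None:
        # honor the file's own channel order, whatever order the caller used
        data = data[[meta_channels.index(name) for name in channels]]

    meta_voxel = meta.get("voxel_size_nm")
    if voxel_size_nm is None:
        if meta_voxel is None:
            raise ValueError(
                f"{path}: no voxel size in TIFF metadata; supply one via config"
            )
        voxel_size_nm = tuple(meta_voxel)
    elif meta_voxel is not None and tuple(meta_voxel) != tuple(voxel_size_nm):
        log.warning(
            "%s: config voxel size %s overrides TIFF metadata %s",
            path, tuple(voxel_size_nm), tuple(meta_voxel),
        )
    return ImageStack(
        channels={name: np.asarray(data[i]) for i, name in enumerate(channels)},
        voxel_size_nm=tuple(voxel_size_nm),
    )
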