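"""Diffraction-limited spot detection in 3D z-stacks.

The detector is the standard smFISH operator: a scale-normalized
Laplacian-of-Gaussian (LoG) blob filter with anisotropic sigma matched to
the PSF, sign-flipped so bright spots give positive peaks; candidate spots
are local maxima of the response above a threshold, refined to subpixel
precision by an intensity-weighted centroid of the response in a 3x3x3
window and reported in physical nanometres (axis order z, y, x, voxel
index 0 at the first slice).

The threshold can be given absolutely or calibrated automatically from the
spot-count plateau: true smFISH spots are well separated in intensity from
the noise floor, so the number of detections is stable over a wide
threshold range, and the midpoint of the longest stable run is used.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "Spot",
    "DetectionParams",
    "blob_filter",
    "detect_spots",
    "auto_threshold",
    "spots_to_frame",
]


@dataclass(frozen=True)
class Spot:
    channel: str
    position_nm: tuple[float, float, float]  # (z, y, x)
    peak_intensity: float
    quality: float


@dataclass(frozen=True)
class DetectionParams:
    """Expected spot scale, threshold and non-max-suppression radius."""

    sigma_nm: tuple[float, float] = (350.0, 170.0)  # (z, xy)
    threshold: float | str = "auto"
    min_separation_voxels: int = 1

    def __post_init__(self) -> None:
        if self.sigma_nm[0] <= 0 or self.sigma_nm[1] <= 0:
            raise ValueError("sigma must be positive")
        if self.threshold != "auto" and float(self.threshold) <= 0:
            raise ValueError("absolute threshold must be positive")
        if self.min_separation_voxels < 1:
            raise ValueError("min_separation_voxels must be >= 1")


def _sigma_voxels(
    sigma_nm: tuple[float, float], voxel_size_nm: tuple[float, float, float]
) -> tuple[float, float, float]:
    sigma = (
        sigma_nm[0] / voxel_size_nm[0],
        sigma_nm[1] / voxel_size_nm[1],
        sigma_nm[1] / voxel_size_nm[2],
    )
    for ax, s in zip("zyx", sigma):
        if s < 0.5:
            raise ValueError(
                f"sigma along {ax} is {s:.2f} voxels (< 0.5): the spot scale "
                "is undersampled at this voxel size"
            )
    return sigma


def blob_filter(
    volume: np.ndarray,
    sigma_nm: tuple[float, float],
    voxel_size_nm: tuple[float, float, float],
) -> np.ndarray:
    """Scale-normalized anisotropic LoG response, positive on bright blobs."""
    sigma = _sigma_voxels(sigma_nm, voxel_size_nm)
    norm = float(np.prod(sigma)) ** (2.0 / 3.0)
    vol = np.asarray(volume)
    if vol.dtype != np.float32:
        vol = vol.astype(np.float64)
    return -norm * ndimage.gaussian_laplace(vol, sigma=sigma)


def _local_maxima(
    response: np.ndarray, min_separation_voxels: int
) -> np.ndarray:
    """Indices (n, 3) of local maxima, plateau ties broken lexicographically."""
    size = 2 * min_separation_voxels + 1
    footprint_max = ndimage.maximum_filter(response, size=size, mode="nearest")
    candidates = (response == footprint_max) & (response > 0)
    if not candidates.any():
        return np.empty((0, 3), dtype=int)
    # a flat plateau marks every plateau voxel: keep the lexicographically
    # first voxel of each connected plateau component
    labels, n = ndimage.label(candidates)
    if n == 0:
        return np.empty((0, 3), dtype=int)
    flat = labels.ravel()
    first = np.full(n + 1, flat.size, dtype=np.int64)
    nz = np.flatnonzero(flat)
    np.minimum.at(first, flat[nz], nz)
    idx = np.sort(first[1:])
    return np.column_stack(np.unravel_index(idx, response.shape))


def auto_threshold(
    response_volume: np.ndarray,
    min_separation_voxels: int = 1,
    n_candidates: int = 40,
    stability: float = 0.05,
) -> float:
    """Plateau-based threshold calibration on a LoG response volume.

    Candidate thresholds are log-spaced between the response's 90th
    percentile and its maximum; the spot count at each is the number of
    local maxima above it. The returned threshold is the geometric midpoint
    of the longest run over which the count changes by less than
    ``stability`` per step. Raises when the response has no usable dynamic
    range or fewer than 3 candidates yield any spots — supply an absolute
    threshold in that case.
    """
    response = np.asarray(response_volume, dtype=float)
    maxima = _local_maxima(response, min_separation_voxels)
    values = np.sort(response[tuple(maxima.T)]) if len(maxima) else np.array([])
    return _plateau_threshold(response, values, n_candidates, stability)


def _plateau_threshold(
    response: np.ndarray,
    maxima_values: np.ndarray,
    n_candidates: int = 40,
    stability: float = 0.05,
) -> float:
    hi = float(response.max())
    if hi <= 0:
        raise ValueError("cannot calibrate: response has no positive values; "
                         "supply absolute threshold")
    p90 = float(np.percentile(response, 90))
    if p90 > 0 and hi / p90 < 10.0:
        raise ValueError(
            "cannot calibrate: response dynamic range (max / 90th percentile "
            f"= {hi / p90:.1f}) is too small to separate spots from noise; "
            "supply absolute threshold"
        )
    lo = p90 if p90 > 0 else hi * 1e-3
    candidates = np.geomspace(lo, hi, n_candidates)
    values = maxima_values
    counts = values.size - np.searchsorted(values, candidates, side="left")
    if np.count_nonzero(counts) < 3:
        raise ValueError(
            "cannot calibrate: fewer than 3 candidate thresholds give any "
            "spots; supply absolute threshold"
        )
    # longest run of consecutive stable steps among non-zero counts
    best = (0, 0)  # (length, start)
    start = 0
    for i in range(len(candidates) - 1):
        stable = (
            counts[i] > 0
            and counts[i + 1] > 0
            and abs(counts[i] - counts[i + 1]) / counts[i] < stability
        )
        if not stable:
            start = i + 1
        elif i + 1 - start > best[0]:
            best = (i + 1 - start, start)
    length, start = best
    if length == 0:
        raise ValueError(
            "cannot calibrate: no stable spot-count plateau found; "
            "supply absolute threshold"
        )
    return float(np.sqrt(candidates[start] * candidates[start + length]))


def detect_spots(
    stack_channel: np.ndarray,
    params: DetectionParams,
    voxel_size_nm: tuple[float, float, float],
    channel: str = "",
) -> list[Spot]:
    """Detect spots in one channel; returns spots sorted by descending quality.

    Positions are subpixel, in nm, refined by the response-weighted centroid
    of the 3x3x3 neighborhood around each maximum.
    """
    volume = np.asarray(stack_channel, dtype=np.float64)
    if volume.size == 0 or np.ptp(volume) == 0:  # empty or featureless
        return []
    response = blob_filter(volume, params.sigma_nm, voxel_size_nm)
    maxima = _local_maxima(response, params.min_separation_voxels)
    if len(maxima) == 0:
        return []
    quality = response[tuple(maxima.T)]
    if params.threshold == "auto":
        if response.max() <= 0:  # featureless volume: nothing to calibrate on
            return []
        threshold = _plateau_threshold(response, np.sort(quality))
    else:
        threshold = float(params.threshold)
    keep = quality >= threshold
    maxima, quality = maxima[keep], quality[keep]

    voxel = np.asarray(voxel_size_nm, dtype=float)
    spots: list[Spot] = []
    shape = np.asarray(response.shape)
    for (z, y, x), q in zip(maxima, quality):
        lo = np.maximum([z - 1, y - 1, x - 1], 0)
        hi = np.minimum([z + 2, y + 2, x + 2], shape)
        win = np.clip(response[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]], 0, None)
        total = win.sum()
        if total > 0:
            grids = np.meshgrid(
                *[np.arange(l, h) for l, h in zip(lo, hi)], indexing="ij"
            )
            center = np.array([(g * win).sum() / total for g in grids])
        else:
            center = np.array([z, y, x], dtype=float)
        spots.append(
            Spot(
                channel=channel,
                position_nm=tuple(center * voxel),
                peak_intensity=float(volume[z, y, x]),
                quality=float(q),
            )
        )
    spots.sort(key=lambda s: -s.quality)
    return spots


def spots_to_frame(spots: list[Spot]) -> pd.DataFrame:
    """Tabulate spots with columns channel, z_nm, y_nm, x_nm, peak_intensity, quality."""
    return pd.DataFrame(
        {
            "channel": [s.channel for s in spots],
            "z_nm": [s.position_nm[0] for s in spots],
            "y_nm": [s.position_nm[1] for s in spots],
            "x_nm": [s.position_nm[2] for s in spots],
            "peak_intensity": [s.peak_intensity for s in spots],
            "quality": [s.quality for s in spots],
        }
    )
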