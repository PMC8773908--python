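"""Nuclear segmentation, spot-to-cell assignment and per-cell statistics.

Nuclei are segmented from a max-projected DAPI channel (Gaussian smooth,
Otsu threshold, hole filling, small-object removal, watershed split of
touching nuclei on the distance transform) and each nucleus seeds a cell
territory: the nearest-nucleus partition of the field clipped to a fixed
dilation radius. Every classified spot is assigned to the cell and
compartment (nuclear if it falls on a nuclear pixel, else cytoplasmic)
under its lateral position; spots on background are flagged unassigned.

Summaries follow standard smFISH reporting: per-cell mean counts per class
with normal-approximation 95% confidence intervals (1.96 x SEM), per-class
nuclear fractions averaged over cells that contain the class, and pooled-
variance two-sided Student's t-tests between conditions with the usual
star codes (p < 0.05 "*", p < 0.001 "***", otherwise "ns").
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from skimage.feature import peak_local_max
from skimage.filters import gaussian, threshold_otsu
from skimage.segmentation import watershed

from .simulate import RNA_CLASSES, GroundTruth

__all__ = [
    "CellLabelMap",
    "SegmentationParams",
    "SummaryStats",
    "segment_nuclei",
    "assign_spots",
    "per_cell_counts",
    "counts_from_ground_truth",
    "summarize",
    "localization_fractions",
    "star_code",
]

DEFAULT_MIN_CELLS = 100


@dataclass
class CellLabelMap:
    """Matched 2D nuclear and whole-cell label maps (background 0)."""

    nuclear_labels: np.ndarray
    cell_labels: np.ndarray

    def __post_init__(self) -> None:
        if self.nuclear_labels.shape != self.cell_labels.shape:
            raise ValueError("label maps must share shape")
        inside = self.nuclear_labels > 0
        if not np.array_equal(
            self.nuclear_labels[inside], self.cell_labels[inside]
        ):
            raise ValueError("each nucleus must lie inside its own cell region")

    @property
    def cell_ids(self) -> list[int]:
        return sorted(set(np.unique(self.cell_labels)) - {0})


@dataclass(frozen=True)
class SegmentationParams:
    smooth_sigma_px: float = 1.0
    min_area_px: int = 200
    peak_min_distance_px: int = 20
    cyto_radius_px: int = 30
    exclude_border_cells: bool = True


def segment_nuclei(
    dapi_stack: np.ndarray,
    params: SegmentationParams | None = None,
) -> CellLabelMap:
    """Segment nuclei from a DAPI channel (3D stack or 2D image).

    Raises when no nucleus is found (blank or failed staining).
    """
    params = params or SegmentationParams()
    dapi = np.asarray(dapi_stack, dtype=float)
    if dapi.ndim == 3:
        dapi = dapi.max(axis=0)
    if dapi.ndim != 2:
        raise ValueError(f"DAPI must be 2D or 3D, got shape {dapi.shape}")
    smooth = gaussian(dapi, sigma=params.smooth_sigma_px, preserve_range=True)
    if np.ptp(smooth) == 0:
        raise ValueError("no nuclei found: DAPI channel is flat")
    mask = smooth > threshold_otsu(smooth)
    mask = ndimage.binary_fill_holes(mask)
    labeled, n_obj = ndimage.label(mask)
    if n_obj:
        areas = np.bincount(labeled.ravel())
        small = np.flatnonzero(areas < params.min_area_px)
        mask &= ~np.isin(labeled, small[small > 0])
    if not mask.any():
        raise ValueError("no nuclei found after size filtering")

    distance = ndimage.distance_transform_edt(mask)
    peaks = peak_local_max(
        distance,
        min_distance=params.peak_min_distance_px,
        labels=ndimage.label(mask)[0],
        num_peaks_per_label=np.iinfo(np.int64).max,
    )
    markers = np.zeros_like(mask, dtype=np.int32)
    for i, (r, c) in enumerate(peaks, start=1):
        markers[r, c] = i
    if markers.max() == 0:
        raise ValueError("no nuclei found: no distance-transform peaks")
    nuclear = watershed(-distance, markers, mask=mask).astype(np.int32)

    dist_bg, (iy, ix) = ndimage.distance_transform_edt(
        nuclear == 0, return_indices=True
    )
    cells = nuclear[iy, ix].astype(np.int32)
    cells[dist_bg > params.cyto_radius_px] = 0

    if params.exclude_border_cells:
        border = np.zeros_like(cells, dtype=bool)
        border[0, :] = border[-1, :] = border[:, 0] = border[:, -1] = True
        for label in np.unique(cells[border]):
            if label != 0:
                cells[cells == label] = 0
                nuclear[nuclear == label] = 0
        if not nuclear.any():
            raise ValueError("no nuclei remain after border exclusion")
    return CellLabelMap(nuclear_labels=nuclear, cell_labels=cells)


def assign_spots(
    classified_spots: pd.DataFrame,
    maps: CellLabelMap,
    voxel_size_nm: tuple[float, float, float],
) -> pd.DataFrame:
    """Attach cell_id and compartment to each spot row.

    The lateral position is rounded to the nearest pixel; spots landing on
    background get cell_id 0 and ``assigned=False`` and are excluded from
    per-cell statistics downstream.
    """
    out = classified_spots.copy()
    if len(out) == 0:
        out["cell_id"] = pd.Series(dtype=int)
        out["compartment"] = pd.Series(dtype=str)
        out["assigned"] = pd.Series(dtype=bool)
        return out
    n_y, n_x = maps.cell_labels.shape
    y = np.clip(np.rint(out["y_nm"] / voxel_size_nm[1]).astype(int), 0, n_y - 1)
    x = np.clip(np.rint(out["x_nm"] / voxel_size_nm[2]).astype(int), 0, n_x - 1)
    cell_id = maps.cell_labels[y, x]
    nuclear = maps.nuclear_labels[y, x] > 0
    out["cell_id"] = cell_id
    out["compartment"] = np.where(nuclear, "nuclear", "cytoplasmic")
    out["assigned"] = cell_id > 0
    return out


def _counts_table(
    assigned: pd.DataFrame, cell_ids: list[int]
) -> pd.DataFrame:
    """Per-cell class totals and nuclear sub-totals, zero-count cells included."""
    out = pd.DataFrame(index=pd.Index(cell_ids, name="cell_id"))
    for cls in RNA_CLASSES:
        sub = assigned[assigned["class"] == cls]
        out[cls] = sub.groupby("cell_id").size().reindex(cell_ids, fill_value=0)
        nuc = sub[sub["compartment"] == "nuclear"]
        out[f"{cls}_nuclear"] = (
            nuc.groupby("cell_id").size().reindex(cell_ids, fill_value=0)
        )
    return out.reset_index()


def per_cell_counts(
    annotated_spots: pd.DataFrame, maps: CellLabelMap
) -> pd.DataFrame:
    """Tally assigned spots per cell and class.

    Returns one row per labeled cell (including cells with zero spots) with
    columns ``cell_id``, per-class totals and per-class nuclear counts.
    """
    assigned = annotated_spots[annotated_spots.get("assigned", True) == True]  # noqa: E712
    return _counts_table(assigned, maps.cell_ids)


def counts_from_ground_truth(ground_truth: GroundTruth) -> pd.DataFrame:
    """Per-cell class counts straight from a simulator molecule table."""
    mols = ground_truth.molecules.rename(columns={"rna_class": "class"})
    cell_ids = sorted(set(np.unique(ground_truth.cell_label_map)) - {0})
    return _counts_table(mols, cell_ids)


def star_code(p_value: float) -> str:
    """Figure-legend significance code."""
    if p_value < 0.001:
        return "***"
    if p_value < 0.05:
        return "*"
    return "ns"


def _mean_ci(values: np.ndarray) -> tuple[float, float]:
    """Mean and 95% CI half-width (1.96 x SEM, normal approximation)."""
    n = len(values)
    if n == 0:
        return float("nan"), float("nan")
    mean = float(np.mean(values))
    if n == 1:
        return mean, float("nan")
    half = 1.96 * float(np.std(values, ddof=1)) / np.sqrt(n)
    return mean, half


@dataclass
class SummaryStats:
    """Per-condition means with CIs plus pairwise t-test comparisons."""

    per_condition: pd.DataFrame  # condition, class, n_cells, mean, ci95_halfwidth
    comparisons: pd.DataFrame  # condition_a, condition_b, class, t, p, stars

    def summary(self) -> str:
        lines = ["Per-condition mean molecules per cell (95% CI half-width):"]
        for _, row in self.per_condition.iterrows():
            lines.append(
                f"  {row['condition']:<14} {row['class']:<9} "
                f"n={row['n_cells']:<5} {row['mean']:8.2f} ± {row['ci95_halfwidth']:.2f}"
            )
        if len(self.comparisons):
            lines.append("Pairwise Student's t-tests (pooled variance, two-sided):")
            for _, row in self.comparisons.iterrows():
                lines.append(
                    f"  {row['condition_a']} vs {row['condition_b']:<14} "
                    f"{row['class']:<9} t={row['t']:8.3f}  p={row['p']:.3g}  "
                    f"{row['stars']}"
                )
        return "\n".join(lines)


def summarize(
    counts_by_condition: Mapping[str, pd.DataFrame],
    min_cells: int = DEFAULT_MIN_CELLS,
) -> SummaryStats:
    """Average per-cell counts per condition and compare conditions pairwise.

    The comparison is the pooled-variance two-sided two-sample Student's
    t-test on per-cell counts, one test per RNA class and condition pair.
    A warning is emitted for conditions below ``min_cells`` cells; a
    condition with fewer than 2 cells is excluded from testing.
    """
    if not counts_by_condition:
        raise ValueError("need at least one condition")
    rows = []
    for cond, counts in counts_by_condition.items():
        n = len(counts)
        if n < min_cells:
            warnings.warn(
                f"condition {cond!r} has {n} cells; at least {min_cells} are "
                "recommended for stable per-cell averages",
                stacklevel=2,
            )
        for cls in RNA_CLASSES:
            mean, half = _mean_ci(counts[cls].to_numpy(dtype=float))
            rows.append(
                {
                    "condition": cond,
                    "class": cls,
                    "n_cells": n,
                    "mean": mean,
                    "ci95_halfwidth": half,
                }
            )
    per_condition = pd.DataFrame(rows)

    comp_rows = []
    names = list(counts_by_condition)
    for ai in range(len(names)):
        for bi in range(ai + 1, len(names)):
            a, b = names[ai], names[bi]
            ca, cb = counts_by_condition[a], counts_by_condition[b]
            if len(ca) < 2 or len(cb) < 2:
                warnings.warn(
                    f"skipping t-test {a} vs {b}: a condition has < 2 cells",
                    stacklevel=2,
                )
                continue
            for cls in RNA_CLASSES:
                va = ca[cls].to_numpy(dtype=float)
                vb = cb[cls].to_numpy(dtype=float)
                t, p = stats.ttest_ind(va, vb, equal_var=True)
                if np.isnan(t):  # zero variance in both samples
                    t, p = 0.0, 1.0
                comp_rows.append(
                    {
                        "condition_a": a,
                        "condition_b": b,
                        "class": cls,
                        "t": float(t),
                        "p": float(p),
                        "stars": star_code(float(p)),
                    }
                )
    comparisons = pd.DataFrame(
        comp_rows,
        columns=["condition_a", "condition_b", "class", "t", "p", "stars"],
    )
    return SummaryStats(per_condition=per_condition, comparisons=comparisons)


def localization_fractions(counts: pd.DataFrame) -> pd.DataFrame:
    """Mean nuclear fraction per class over cells containing that class.

    Returns one row per class with the number of contributing cells, the
    mean nuclear fraction with its 95% CI half-width, and the complementary
    cytoplasmic fraction. Classes absent from every cell report NaN.
    """
    rows = []
    for cls in RNA_CLASSES:
        has = counts[counts[cls] > 0]
        fractions = (
            has[f"{cls}_nuclear"] / has[cls]
        ).to_numpy(dtype=float) if len(has) else np.array([])
        mean, half = _mean_ci(fractions)
        rows.append(
            {
                "class": cls,
                "n_cells": len(has),
                "nuclear_fraction": mean,
                "ci95_halfwidth": half,
                "cytoplasmic_fraction": 1.0 - mean if np.isfinite(mean) else float("nan"),
            }
        )
    return pd.DataFrame(rows)
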