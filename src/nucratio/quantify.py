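"""Per-cell intensity statistics for the two-channel nuclear reporter.

Three statistics are computed per cell, mirroring the measurement methods
of the source workflow:

* ``ratio_3d`` — mean green / mean red over all nucleus voxels;
* ``ratio_2d`` — the same quotient restricted to the nucleus's central
  z-plane;
* ``nc_ratio`` — mean nuclear green / mean cytoplasmic green at the plane of
  a manually supplied cell outline (cytoplasm measurement is 2D by design).

``da_normalize`` divides each reporter cell's nuclear green mean by the
average over a fixed number of internal-reference (DA-class) cells from the
same embryo.  All means are unweighted over voxels ("average pixel
intensity") irrespective of voxel anisotropy.  Undefined ratios are raised
as errors at the function level and recorded as missing values in tables,
never as infinities.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import (
    EmptyMeasurementError,
    GroupingError,
    InsufficientReferenceError,
    UndefinedRatioError,
    ValidationError,
)
from .segmentation import (
    CellOutline,
    NucleusMask,
    VoxelGrid,
    cytoplasm_region,
    select_central_plane,
)

__all__ = [
    "CellMeasure",
    "nuclear_mean_intensity",
    "nuclear_ratio_3d",
    "nuclear_ratio_2d",
    "nc_ratio",
    "da_normalize",
    "render_heatmap",
    "measure_stack",
]

logger = logging.getLogger(__name__)

CELL_CLASSES = ("PL", "DA", "LEC", "VEC", "other")


@dataclass(frozen=True)
class CellMeasure:
    """All ratio statistics for one cell; None marks an undefined value."""

    embryo_id: str
    cell_id: int
    cell_class: str = "other"
    mean_green_nuc_3d: float | None = None
    mean_red_nuc_3d: float | None = None
    ratio_3d: float | None = None
    ratio_2d: float | None = None
    nc_ratio: float | None = None
    da_norm: float | None = None
    da_ref_ids: tuple[int, ...] | None = None
    volume_voxels: int | None = None
    central_plane: int | None = None


def nuclear_mean_intensity(
    grid: VoxelGrid,
    mask: NucleusMask,
    label: int,
    channel: str = "green",
    plane: int | None = None,
) -> float:
    """Unweighted arithmetic mean of one channel over a nucleus's voxels.

    With ``plane`` given, only that z-plane's pixels of the nucleus are
    averaged; a nucleus with no voxels at the requested plane raises
    :class:`EmptyMeasurementError`.
    """
    if channel not in ("green", "red"):
        raise ValidationError(f"unknown channel {channel!r}")
    support = mask.voxels(label)
    data = grid.green if channel == "green" else grid.red
    if data.shape != support.shape:
        raise ValidationError("grid and mask shapes differ")
    if plane is not None:
        sel = support[plane]
        if not sel.any():
            raise EmptyMeasurementError(f"label {label} has no voxels at plane {plane}")
        return float(data[plane][sel].mean())
    return float(data[support].mean())


def nuclear_ratio_3d(grid: VoxelGrid, mask: NucleusMask, label: int) -> float:
    """Green/red mean-intensity ratio over all voxels of one nucleus."""
    mean_red = nuclear_mean_intensity(grid, mask, label, "red")
    if mean_red <= 0:
        raise UndefinedRatioError(f"label {label}: red nuclear mean is zero")
    return nuclear_mean_intensity(grid, mask, label, "green") / mean_red


def nuclear_ratio_2d(grid: VoxelGrid, mask: NucleusMask, label: int) -> float:
    """Green/red ratio restricted to the nucleus's central z-plane."""
    plane = select_central_plane(mask, label)
    mean_red = nuclear_mean_intensity(grid, mask, label, "red", plane=plane)
    if mean_red <= 0:
        raise UndefinedRatioError(f"label {label}: red mean at plane {plane} is zero")
    return nuclear_mean_intensity(grid, mask, label, "green", plane=plane) / mean_red


def nc_ratio(grid: VoxelGrid, mask: NucleusMask, outline: CellOutline, label: int) -> float:
    """Nuclear/cytoplasmic green ratio at the outline's z-plane (2D).

    Nucleus pixels are the mask's pixels at that plane; cytoplasm pixels are
    the outline interior minus the nucleus.
    """
    region = cytoplasm_region(outline, mask)  # raises EmptyRegionError if empty
    plane = outline.z
    nuc_mean = nuclear_mean_intensity(grid, mask, label, "green", plane=plane)
    cyto_vals = grid.green[plane][region]
    cyto_mean = float(cyto_vals.mean())
    if cyto_mean <= 0:
        raise UndefinedRatioError(f"label {label}: cytoplasmic green mean is zero")
    return nuc_mean / cyto_mean


def da_normalize(
    pl_measures: Sequence[CellMeasure],
    da_measures: Sequence[CellMeasure],
    n_ref: int = 6,
) -> list[CellMeasure]:
    """Divide each reporter cell's nuclear green mean by the average of the
    first ``n_ref`` reference cells (ascending cell_id) of the same embryo.

    If fewer than ``n_ref`` but at least 3 reference cells are available the
    reference count is relaxed with a warning; below 3 the normalization is
    refused.  The reference cell ids used are recorded on every returned
    measure (``da_ref_ids``).
    """
    if n_ref < 3:
        raise InsufficientReferenceError(f"n_ref must be >= 3, got {n_ref}")
    if not pl_measures:
        return []
    embryos = {m.embryo_id for m in pl_measures} | {m.embryo_id for m in da_measures}
    if len(embryos) != 1:
        raise GroupingError(f"measures span multiple embryos: {sorted(embryos)}")
    usable = [m for m in da_measures if m.mean_green_nuc_3d is not None]
    if len(usable) < 3:
        raise InsufficientReferenceError(
            f"need >= 3 reference cells with measured green, got {len(usable)}"
        )
    if len(usable) < n_ref:
        warnings.warn(
            f"only {len(usable)} reference cells available; relaxing n_ref from {n_ref}",
            stacklevel=2,
        )
        n_ref = len(usable)
    refs = sorted(usable, key=lambda m: m.cell_id)[:n_ref]
    ref_ids = tuple(m.cell_id for m in refs)
    ref_mean = float(np.mean([m.mean_green_nuc_3d for m in refs]))
    if ref_mean <= 0:
        raise UndefinedRatioError("reference green mean is zero")
    out = []
    for m in pl_measures:
        if m.mean_green_nuc_3d is None:
            out.append(replace(m, da_norm=None, da_ref_ids=ref_ids))
        else:
            out.append(replace(m, da_norm=m.mean_green_nuc_3d / ref_mean, da_ref_ids=ref_ids))
    return out


def render_heatmap(
    grid: VoxelGrid, mask: NucleusMask, projection: str = "max"
) -> tuple[np.ndarray, dict]:
    """Maximum-intensity projection of green restricted to nucleus voxels.

    Returns the 2D image and a metadata dict recording the colour-scale
    limits.  An empty mask produces a blank image with a logged warning.
    """
    if projection != "max":
        raise ValidationError(f"unsupported projection {projection!r}")
    masked = np.where(mask.labels > 0, grid.green, 0.0)
    image = masked.max(axis=0)
    if mask.n_labels == 0:
        logger.warning("render_heatmap: empty mask, producing blank image")
        vmin = vmax = 0.0
    else:
        inside = grid.green[mask.labels > 0]
        vmin, vmax = float(inside.min()), float(inside.max())
    meta = {
        "projection": "max",
        "vmin": vmin,
        "vmax": vmax,
        "colormap": "jet",
        "note": "high values render red",
    }
    return image, meta


def measure_stack(
    grid: VoxelGrid,
    mask: NucleusMask,
    embryo_id: str = "embryo",
    classes: dict[int, str] | None = None,
    outlines: dict[int, CellOutline] | None = None,
) -> list[CellMeasure]:
    """Compute every available statistic for every labelled nucleus.

    ``classes`` maps label -> cell class; ``outlines`` maps label -> 2D cell
    outline enabling the N/C ratio.  Undefined ratios become None.
    """
    measures = []
    for label in sorted(mask.counts):
        cls = (classes or {}).get(label, "other")
        plane = select_central_plane(mask, label)
        mg = nuclear_mean_intensity(grid, mask, label, "green")
        mr = nuclear_mean_intensity(grid, mask, label, "red")
        try:
            r3 = nuclear_ratio_3d(grid, mask, label)
        except UndefinedRatioError:
            r3 = None
        try:
            r2 = nuclear_ratio_2d(grid, mask, label)
        except (UndefinedRatioError, EmptyMeasurementError):
            r2 = None
        ncr = None
        outline = (outlines or {}).get(label)
        if outline is not None:
            try:
                ncr = nc_ratio(grid, mask, outline, label)
            except Exception as exc:  # undefined N/C stays missing, not fatal
                logger.debug("nc_ratio failed for label %s: %s", label, exc)
        measures.append(
            CellMeasure(
                embryo_id=embryo_id,
                cell_id=label,
                cell_class=cls,
                mean_green_nuc_3d=mg,
                mean_red_nuc_3d=mr,
                ratio_3d=r3,
                ratio_2d=r2,
                nc_ratio=ncr,
                volume_voxels=mask.counts[label],
                central_plane=plane,
            )
        )
    return measures


def measures_to_frame(measures: Sequence[CellMeasure], frame: int = 0) -> pd.DataFrame:
    """Tidy table of measures; missing ratios become empty cells on write."""
    rows = []
    for m in measures:
        rows.append(
            {
                "embryo_id": m.embryo_id,
                "cell_id": m.cell_id,
                "class": m.cell_class,
                "frame": frame,
                "volume_voxels": m.volume_voxels,
                "mean_green_nuc_3d": m.mean_green_nuc_3d,
                "mean_red_nuc_3d": m.mean_red_nuc_3d,
                "ratio_3d": m.ratio_3d,
                "ratio_2d": m.ratio_2d,
                "nc_ratio": m.nc_ratio,
                "da_norm": m.da_norm,
                "central_plane": m.central_plane,
            }
        )
    columns = [
        "embryo_id", "cell_id", "class", "frame", "volume_voxels",
        "mean_green_nuc_3d", "mean_red_nuc_3d", "ratio_3d", "ratio_2d",
        "nc_ratio", "da_norm", "central_plane",
    ]
    return pd.DataFrame(rows, columns=columns)
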