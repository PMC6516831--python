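"""Nuclear segmentation from the red (histone-fusion) channel.

Nuclei are extracted as connected components of the thresholded red channel
(26-connectivity in 3D).  Touching nuclei are not split; the synthetic
generator never produces contact and the measured cells are well separated.
Voxel coordinates are 0-based throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import shapely
from scipy import ndimage as ndi
from shapely.geometry import Polygon
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label

from .errors import (
    EmptyRegionError,
    LabelNotFoundError,
    ParameterError,
    ValidationError,
)

__all__ = [
    "VoxelGrid",
    "NucleusMask",
    "CellOutline",
    "segment_nuclei_3d",
    "select_central_plane",
    "cytoplasm_region",
]

DEFAULT_MIN_VOLUME = 30  # voxels; excludes noise speckle at default voxel size


@dataclass
class VoxelGrid:
    """Two-channel 3D intensity stack with voxel-size metadata.

    ``green`` carries the reporter of interest (EGFP fusion), ``red`` the
    nuclear histone marker used for masking.  ``voxel_size`` is micrometres
    per voxel in (z, y, x) order.
    """

    green: np.ndarray
    red: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 0.3, 0.3)
    frame_index: int = 0

    def __post_init__(self) -> None:
        self.green = np.asarray(self.green, dtype=float)
        self.red = np.asarray(self.red, dtype=float)
        if self.green.shape != self.red.shape:
            raise ValidationError(
                f"channel shapes differ: green {self.green.shape} vs red {self.red.shape}"
            )
        if self.green.ndim != 3:
            raise ValidationError(f"expected 3D channels, got {self.green.ndim}D")
        if (self.green < 0).any() or (self.red < 0).any():
            raise ValidationError("intensities must be non-negative")
        vs = tuple(float(v) for v in self.voxel_size)
        if len(vs) != 3 or any(v <= 0 for v in vs):
            raise ValidationError(f"voxel_size must be 3 positive values, got {self.voxel_size}")
        self.voxel_size = vs
        if self.frame_index < 0:
            raise ValidationError("frame_index must be >= 0")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.green.shape


@dataclass
class NucleusMask:
    """Labelled nuclei: 0 = background, 1..N = nuclei ordered by size."""

    labels: np.ndarray
    counts: dict[int, int]
    centroids: dict[int, tuple[float, float, float]]
    threshold_used: float | None
    voxel_size: tuple[float, float, float] = (1.0, 0.3, 0.3)

    @property
    def n_labels(self) -> int:
        return len(self.counts)

    def require_label(self, label: int) -> None:
        if label not in self.counts:
            raise LabelNotFoundError(f"label {label} not present in mask")

    def voxels(self, label: int) -> np.ndarray:
        """Boolean support of one nucleus."""
        self.require_label(label)
        return self.labels == label

    def centroid_um(self, label: int) -> tuple[float, float, float]:
        self.require_label(label)
        c = self.centroids[label]
        return tuple(ci * vi for ci, vi in zip(c, self.voxel_size))


@dataclass
class CellOutline:
    """A manually drawn closed 2D cell outline at one z-plane.

    ``vertices`` are (y, x) voxel coordinates; the polygon must be simple.
    """

    label: int
    z: int
    vertices: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2 or len(self.vertices) < 3:
            raise ValidationError("outline needs >= 3 (y, x) vertices")
        if not self.polygon().is_simple:
            raise ValidationError(f"outline for label {self.label} is self-intersecting")

    def polygon(self) -> Polygon:
        # shapely uses (x, y) order
        return Polygon([(x, y) for y, x in self.vertices])


def segment_nuclei_3d(
    grid: VoxelGrid,
    method: str = "otsu",
    threshold: float | None = None,
    min_volume: int = DEFAULT_MIN_VOLUME,
) -> NucleusMask:
    """Label nuclei as 26-connected components of ``{red >= threshold}``.

    ``method='otsu'`` derives the threshold from the red channel's nonzero
    histogram; ``method='absolute'`` uses the given ``threshold``.  Components
    smaller than ``min_volume`` voxels are removed.  Labels are assigned in
    descending component size, ties broken by ascending (z, y, x) of the
    component's minimum (bounding-box) coordinate.

    An all-zero red channel under Otsu yields an empty mask with
    ``threshold_used=None`` rather than an exception.
    """
    if min_volume < 1:
        raise ParameterError(f"min_volume must be >= 1, got {min_volume}")
    red = grid.red

    if method == "absolute":
        if threshold is None:
            raise ParameterError("method='absolute' requires an explicit threshold")
        thr: float | None = float(threshold)
    elif method == "otsu":
        nonzero = red[red > 0]
        if nonzero.size == 0:
            thr = None
        elif np.unique(nonzero).size < 2:
            thr = float(nonzero[0])  # degenerate histogram: single foreground value
        else:
            thr = float(threshold_otsu(nonzero))
    else:
        raise ParameterError(f"unknown segmentation method {method!r}")

    empty = NucleusMask(
        labels=np.zeros(red.shape, dtype=np.int32),
        counts={},
        centroids={},
        threshold_used=thr,
        voxel_size=grid.voxel_size,
    )
    if thr is None:
        return empty

    binary = red >= thr
    raw = cc_label(binary, connectivity=3)
    n_raw = int(raw.max())
    if n_raw == 0:
        return empty

    objects = ndi.find_objects(raw)
    sizes = np.bincount(raw.ravel(), minlength=n_raw + 1)
    keep = []
    for lab in range(1, n_raw + 1):
        if sizes[lab] >= min_volume:
            sl = objects[lab - 1]
            bbox_min = tuple(s.start for s in sl)
            keep.append((-int(sizes[lab]), bbox_min, lab))
    keep.sort()

    labels = np.zeros(red.shape, dtype=np.int32)
    counts: dict[int, int] = {}
    centroids: dict[int, tuple[float, float, float]] = {}
    for new_lab, (neg_size, _bbox, old_lab) in enumerate(keep, start=1):
        support = raw == old_lab
        labels[support] = new_lab
        counts[new_lab] = -neg_size
        zc, yc, xc = (float(c.mean()) for c in np.nonzero(support))
        centroids[new_lab] = (zc, yc, xc)
    return NucleusMask(
        labels=labels,
        counts=counts,
        centroids=centroids,
        threshold_used=thr,
        voxel_size=grid.voxel_size,
    )


def select_central_plane(mask: NucleusMask, label: int) -> int:
    """z-plane at the rounded z-centroid of the nucleus; ties at .5 go to the
    lower index."""
    mask.require_label(label)
    zc = mask.centroids[label][0]
    return int(math.ceil(zc - 0.5))


def cytoplasm_region(outline: CellOutline, mask: NucleusMask) -> np.ndarray:
    """Pixels inside the outline at its z-plane, minus the nucleus mask there.

    A pixel belongs to the polygon iff its centre is strictly inside.  The
    result is a 2D boolean array, guaranteed disjoint from the nucleus mask.
    Raises :class:`EmptyRegionError` if nothing remains (outline entirely
    within the nucleus).
    """
    mask.require_label(outline.label)
    nz = mask.labels.shape[0]
    if not 0 <= outline.z < nz:
        raise ValidationError(f"outline plane {outline.z} outside stack of {nz} planes")

    poly = outline.polygon()
    ny, nx = mask.labels.shape[1:]
    y0 = max(int(math.floor(poly.bounds[1])), 0)
    y1 = min(int(math.ceil(poly.bounds[3])) + 1, ny)
    x0 = max(int(math.floor(poly.bounds[0])), 0)
    x1 = min(int(math.ceil(poly.bounds[2])) + 1, nx)

    inside = np.zeros((ny, nx), dtype=bool)
    if y1 > y0 and x1 > x0:
        ys, xs = np.mgrid[y0:y1, x0:x1]
        # contains() is strict-interior: boundary pixels excluded by design
        hit = shapely.contains_xy(poly, xs.ravel().astype(float), ys.ravel().astype(float))
        inside[y0:y1, x0:x1] = hit.reshape(ys.shape)

    nucleus_plane = mask.labels[outline.z] == outline.label
    region = inside & ~nucleus_plane
    if not region.any():
        raise EmptyRegionError(
            f"outline for label {outline.label} at z={outline.z} leaves no cytoplasm pixels"
        )
    return region
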