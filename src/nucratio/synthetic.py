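"""Synthetic two-channel embryo stacks with known ground truth.

Renders ellipsoidal nuclei (red = uniform histone marker, green = nuclear
reporter concentration) surrounded by a spherical-shell cytoplasm annulus
carrying only green signal, onto an anisotropic voxel grid.  Reporter-class
("PL") nuclei sit in a horizontal band; reference-class ("DA") nuclei sit in
a ventral row.  Optional Poisson shot noise, per-channel exponential
photobleaching, frame-to-frame drift and scripted cell divisions produce
time-lapses with full trajectory/parentage ground truth.

All randomness flows through ``numpy.random.default_rng(seed)``: identical
parameters and seed give bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import BoundsError, GenerationError, ParameterError
from .segmentation import VoxelGrid

__all__ = [
    "SyntheticParams",
    "GroundTruth",
    "generate_stack",
    "generate_timelapse",
    "generate_cohort_counts",
    "match_to_ground_truth",
]

NOISE_MODELS = ("none", "poisson")
COUNT_DISTRIBUTIONS = ("normal-rounded-at-0", "poisson")

GT_COLUMNS = [
    "cell_id",
    "frame",
    "cell_class",
    "z",
    "y",
    "x",
    "radius_um",
    "c_nuc",
    "c_cyto",
    "k",
    "red_level",
    "parent_id",
]


@dataclass(frozen=True)
class SyntheticParams:
    """Parameters of the synthetic embryo generator.

    ``stack_shape`` and ``voxel_size`` are (z, y, x); ``partition_range``
    is the uniform sampling interval for the per-cell nuclear/cytoplasmic
    green concentration ratio k; ``drift`` is voxels/frame in (y, x).
    ``bleach_rate`` applies to the green channel; ``bleach_rate_red``
    defaults to the same value (common-mode bleaching) and may be set to 0
    to bleach green alone.
    """

    stack_shape: tuple[int, int, int] = (24, 192, 192)
    voxel_size: tuple[float, float, float] = (1.0, 0.3, 0.3)
    n_pl: int = 6
    n_da: int = 4
    nucleus_radius: tuple[float, float] = (2.5, 0.25)  # µm (mean, sd)
    red_level: float = 100.0
    partition_range: tuple[float, float] = (0.5, 3.0)
    cyto_level: float = 40.0
    noise_model: str = "none"
    bleach_rate: float = 0.0
    bleach_rate_red: float | None = None
    drift: tuple[float, float] = (0.0, 0.0)
    division_times: tuple[tuple[int, int], ...] = ()
    n_frames: int = 1
    cyto_thickness_um: float = 2.0
    nucleus_aspect: tuple[float, float, float] = (1.0, 1.0, 1.0)
    seed: int = 0

    def validate(self) -> None:
        if len(self.stack_shape) != 3 or any(s < 1 for s in self.stack_shape):
            raise ParameterError(f"invalid stack_shape {self.stack_shape}")
        if any(v <= 0 for v in self.voxel_size):
            raise ParameterError(f"voxel_size must be positive, got {self.voxel_size}")
        if self.n_pl < 0 or self.n_da < 0:
            raise ParameterError("cell counts must be >= 0")
        if self.nucleus_radius[0] <= 0 or self.nucleus_radius[1] < 0:
            raise ParameterError(f"invalid nucleus_radius {self.nucleus_radius}")
        if self.red_level <= 0 or self.cyto_level < 0:
            raise ParameterError("red_level must be > 0 and cyto_level >= 0")
        k_min, k_max = self.partition_range
        if not (0 <= k_min <= k_max):
            raise ParameterError(f"partition_range must satisfy 0 <= k_min <= k_max, got {self.partition_range}")
        if self.noise_model not in NOISE_MODELS:
            raise ParameterError(f"unknown noise_model {self.noise_model!r}; expected one of {NOISE_MODELS}")
        if self.bleach_rate < 0 or (self.bleach_rate_red is not None and self.bleach_rate_red < 0):
            raise ParameterError("bleach rates must be >= 0")
        if self.n_frames < 1:
            raise ParameterError("n_frames must be >= 1")
        if self.cyto_thickness_um <= 0:
            raise ParameterError("cyto_thickness_um must be > 0")
        if any(a <= 0 for a in self.nucleus_aspect):
            raise ParameterError("nucleus_aspect factors must be > 0")
        for cell_id, frame in self.division_times:
            if frame >= self.n_frames:
                raise ParameterError(
                    f"division of cell {cell_id} at frame {frame} >= n_frames {self.n_frames}"
                )
            if frame < 1:
                raise ParameterError(f"division frame must be >= 1, got {frame}")

    @property
    def green_bleach(self) -> float:
        return self.bleach_rate

    @property
    def red_bleach(self) -> float:
        return self.bleach_rate if self.bleach_rate_red is None else self.bleach_rate_red


@dataclass
class GroundTruth:
    """One row per rendered cell per frame, plus stack geometry.

    Columns: cell_id, frame, cell_class, z/y/x (voxel coordinates of the
    centroid), radius_um, c_nuc, c_cyto, k (= c_nuc/c_cyto), red_level,
    parent_id (NaN for founder cells).
    """

    cells: pd.DataFrame
    stack_shape: tuple[int, int, int]
    voxel_size: tuple[float, float, float]

    def at_frame(self, frame: int) -> pd.DataFrame:
        return self.cells[self.cells["frame"] == frame].reset_index(drop=True)

    @property
    def n_cells(self) -> int:
        return self.cells["cell_id"].nunique()

    def track(self, cell_id: int) -> pd.DataFrame:
        return self.cells[self.cells["cell_id"] == cell_id].sort_values("frame")

    def validate(self) -> None:
        df = self.cells
        if len(df) == 0:
            return
        with np.errstate(divide="ignore", invalid="ignore"):
            k = df["c_nuc"] / df["c_cyto"]
        ok = np.isclose(k, df["k"], rtol=1e-12) | (df["c_cyto"] == 0)
        if not ok.all():
            raise GenerationError("ground truth violates k = c_nuc/c_cyto")
        all_ids = set(df["cell_id"])
        parents = df["parent_id"].dropna()
        if not set(parents.astype(int)).issubset(all_ids):
            raise GenerationError("daughter references a missing parent cell")
        for axis, name in enumerate("zyx"):
            vals = df[name]
            if (vals < 0).any() or (vals > self.stack_shape[axis] - 1).any():
                raise BoundsError(f"ground-truth centroid outside stack along {name}")


# ---------------------------------------------------------------------------
# cell placement


@dataclass
class _Cell:
    cell_id: int
    cell_class: str
    center_um: np.ndarray  # (z, y, x)
    radius_um: float
    c_nuc: float
    c_cyto: float
    k: float
    parent_id: int | None = None


def _extent_um(params: SyntheticParams) -> np.ndarray:
    return np.asarray(params.stack_shape, dtype=float) * np.asarray(params.voxel_size)


def _footprint_um(params: SyntheticParams, radius: float) -> np.ndarray:
    """Semi-extent (µm, per axis) that must fit inside the stack."""
    aspect = np.asarray(params.nucleus_aspect)
    return radius * aspect + params.cyto_thickness_um


def _collides(a: _Cell, b: _Cell, thickness: float) -> bool:
    d = float(np.linalg.norm(a.center_um - b.center_um))
    return d < a.radius_um + b.radius_um + 2.0 * thickness


def _sample_radius(params: SyntheticParams, rng: np.random.Generator) -> float:
    mean, sd = params.nucleus_radius
    r = float(rng.normal(mean, sd)) if sd > 0 else mean
    return float(np.clip(r, 0.5 * mean, 1.5 * mean))


def _place_cells(params: SyntheticParams, rng: np.random.Generator) -> list[_Cell]:
    """Deterministic slot-based placement with jitter and hard collision
    rejection (up to 100 re-samples per cell)."""
    extent = _extent_um(params)
    drift_um = np.array(
        [0.0, params.drift[0] * params.voxel_size[1], params.drift[1] * params.voxel_size[2]]
    )
    total_drift = np.abs(drift_um) * max(params.n_frames - 1, 0)

    cells: list[_Cell] = []
    k_min, k_max = params.partition_range

    plan = [("PL", i, params.n_pl, 0.38) for i in range(params.n_pl)]
    plan += [("DA", i, params.n_da, 0.72) for i in range(params.n_da)]

    next_id = 1
    for cls, slot, n_slots, y_frac in plan:
        radius = _sample_radius(params, rng)
        pad = _footprint_um(params, radius)
        lo = pad.copy()
        hi = extent - pad
        # keep the drifted trajectory in bounds over all frames
        lo = lo + np.maximum(-drift_um, 0.0) * max(params.n_frames - 1, 0)
        hi = hi - np.maximum(drift_um, 0.0) * max(params.n_frames - 1, 0)
        if (hi <= lo).any():
            raise BoundsError(
                f"stack {params.stack_shape} too small for a {cls} nucleus of "
                f"radius {radius:.2f} µm plus cytoplasm and drift"
            )
        slot_w = (hi[2] - lo[2]) / n_slots
        placed = False
        for _attempt in range(100):
            z = rng.uniform(lo[0], hi[0])
            y = float(np.clip(y_frac * extent[1] + rng.normal(0, 0.03 * extent[1]), lo[1], hi[1]))
            x = lo[2] + (slot + 0.5) * slot_w + rng.uniform(-0.25, 0.25) * slot_w
            cand = _Cell(
                cell_id=next_id,
                cell_class=cls,
                center_um=np.array([z, y, x]),
                radius_um=radius,
                c_nuc=0.0,
                c_cyto=0.0,
                k=0.0,
            )
            collisions = [c.cell_id for c in cells if _collides(cand, c, params.cyto_thickness_um)]
            if not collisions:
                placed = True
                break
        if not placed:
            raise GenerationError(
                f"could not place cell {next_id} ({cls}) without collision; "
                f"last collided with cells {collisions}"
            )
        k = float(rng.uniform(k_min, k_max))
        c_cyto = params.cyto_level
        cand.k = k
        cand.c_cyto = c_cyto
        cand.c_nuc = k * c_cyto
        cells.append(cand)
        next_id += 1
    return cells


# ---------------------------------------------------------------------------
# rendering


def _render(
    cells: Sequence[_Cell],
    params: SyntheticParams,
    green_scale: float = 1.0,
    red_scale: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    shape = params.stack_shape
    vs = np.asarray(params.voxel_size)
    aspect = np.asarray(params.nucleus_aspect)
    green = np.zeros(shape, dtype=float)
    red = np.zeros(shape, dtype=float)
    for cell in cells:
        semi_nuc = cell.radius_um * aspect
        semi_out = semi_nuc + params.cyto_thickness_um
        lo = np.maximum(np.floor((cell.center_um - semi_out) / vs).astype(int), 0)
        hi = np.minimum(np.ceil((cell.center_um + semi_out) / vs).astype(int) + 1, shape)
        if (hi <= lo).any():
            continue
        zz, yy, xx = np.meshgrid(
            (np.arange(lo[0], hi[0]) * vs[0] - cell.center_um[0]),
            (np.arange(lo[1], hi[1]) * vs[1] - cell.center_um[1]),
            (np.arange(lo[2], hi[2]) * vs[2] - cell.center_um[2]),
            indexing="ij",
        )
        q_nuc = (zz / semi_nuc[0]) ** 2 + (yy / semi_nuc[1]) ** 2 + (xx / semi_nuc[2]) ** 2
        q_out = (zz / semi_out[0]) ** 2 + (yy / semi_out[1]) ** 2 + (xx / semi_out[2]) ** 2
        nuc = q_nuc <= 1.0
        shell = (~nuc) & (q_out <= 1.0)
        box = (slice(lo[0], hi[0]), slice(lo[1], hi[1]), slice(lo[2], hi[2]))
        green[box][nuc] = cell.c_nuc * green_scale
        green[box][shell] = cell.c_cyto * green_scale
        red[box][nuc] = params.red_level * red_scale
    return green, red


def _apply_noise(
    green: np.ndarray, red: np.ndarray, params: SyntheticParams, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    if params.noise_model == "none":
        return green, red
    return rng.poisson(green).astype(float), rng.poisson(red).astype(float)


def _gt_rows(cells: Sequence[_Cell], frame: int, params: SyntheticParams, red_scale: float = 1.0):
    vs = params.voxel_size
    for c in cells:
        yield {
            "cell_id": c.cell_id,
            "frame": frame,
            "cell_class": c.cell_class,
            "z": c.center_um[0] / vs[0],
            "y": c.center_um[1] / vs[1],
            "x": c.center_um[2] / vs[2],
            "radius_um": c.radius_um,
            "c_nuc": c.c_nuc,
            "c_cyto": c.c_cyto,
            "k": c.k,
            "red_level": params.red_level * red_scale,
            "parent_id": c.parent_id,
        }


def _make_gt(rows: list[dict], params: SyntheticParams) -> GroundTruth:
    df = pd.DataFrame(rows, columns=GT_COLUMNS)
    gt = GroundTruth(cells=df, stack_shape=params.stack_shape, voxel_size=params.voxel_size)
    gt.validate()
    return gt


# ---------------------------------------------------------------------------
# public API


def generate_stack(params: SyntheticParams) -> tuple[VoxelGrid, GroundTruth]:
    """Render one two-channel stack and its ground truth."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    cells = _place_cells(params, rng)
    green, red = _render(cells, params)
    green, red = _apply_noise(green, red, params, rng)
    grid = VoxelGrid(green=green, red=red, voxel_size=params.voxel_size, frame_index=0)
    gt = _make_gt(list(_gt_rows(cells, 0, params)), params)
    return grid, gt


def generate_timelapse(params: SyntheticParams) -> tuple[list[VoxelGrid], GroundTruth]:
    """Render an n_frames time-lapse with drift, bleaching and divisions.

    A division listed as ``(cell_id, frame)`` removes the parent from
    ``frame`` onwards and renders two daughters (offset along x) whose
    ground-truth rows carry ``parent_id``.
    """
    params.validate()
    if params.n_frames < 2:
        raise ParameterError("generate_timelapse requires n_frames >= 2")
    division_for = {}
    for cell_id, frame in params.division_times:
        if cell_id in division_for:
            raise ParameterError(f"cell {cell_id} scheduled to divide twice")
        division_for[cell_id] = frame

    rng = np.random.default_rng(params.seed)
    base = _place_cells(params, rng)
    base_ids = {c.cell_id for c in base}
    for cid in division_for:
        if cid not in base_ids:
            raise ParameterError(f"division names unknown cell id {cid}")

    drift_um = np.array(
        [0.0, params.drift[0] * params.voxel_size[1], params.drift[1] * params.voxel_size[2]]
    )
    next_id = max(base_ids, default=0) + 1
    daughters: dict[int, tuple[int, int]] = {}  # parent -> daughter ids

    grids: list[VoxelGrid] = []
    rows: list[dict] = []
    for f in range(params.n_frames):
        frame_cells: list[_Cell] = []
        for c in base:
            center = c.center_um + drift_um * f
            div_frame = division_for.get(c.cell_id)
            if div_frame is not None and f >= div_frame:
                if c.cell_id not in daughters:
                    daughters[c.cell_id] = (next_id, next_id + 1)
                    next_id += 2
                d1, d2 = daughters[c.cell_id]
                gap = c.radius_um + 1.0
                for did, sign in ((d1, -1.0), (d2, 1.0)):
                    frame_cells.append(
                        replace(
                            c,
                            cell_id=did,
                            center_um=center + np.array([0.0, 0.0, sign * gap]),
                            parent_id=c.cell_id,
                        )
                    )
            else:
                frame_cells.append(replace(c, center_um=center))
        g_scale = math.exp(-params.green_bleach * f)
        r_scale = math.exp(-params.red_bleach * f)
        green, red = _render(frame_cells, params, green_scale=g_scale, red_scale=r_scale)
        green, red = _apply_noise(green, red, params, rng)
        grids.append(VoxelGrid(green=green, red=red, voxel_size=params.voxel_size, frame_index=f))
        scaled = [
            replace(c, c_nuc=c.c_nuc * g_scale, c_cyto=c.c_cyto * g_scale) for c in frame_cells
        ]
        rows.extend(_gt_rows(scaled, f, params, red_scale=r_scale))
    return grids, _make_gt(rows, params)


def match_to_ground_truth(mask, gt: GroundTruth, frame: int = 0, max_dist_um: float = 5.0) -> pd.DataFrame:
    """Match segmented labels to ground-truth cells by nearest centroid (µm).

    Greedy assignment by ascending distance; unmatched labels are dropped.
    Returns columns: label, cell_id, cell_class, dist_um, k, c_nuc, c_cyto,
    red_level.
    """
    truth = gt.at_frame(frame)
    vs = np.asarray(gt.voxel_size)
    pairs = []
    for lab, cent in mask.centroids.items():
        c_um = np.asarray(cent) * vs
        for _, row in truth.iterrows():
            t_um = np.array([row["z"], row["y"], row["x"]]) * vs
            d = float(np.linalg.norm(c_um - t_um))
            if d <= max_dist_um:
                pairs.append((d, lab, row))
    pairs.sort(key=lambda item: (item[0], item[1]))
    used_labels: set[int] = set()
    used_cells: set[int] = set()
    rows = []
    for d, lab, row in pairs:
        if lab in used_labels or row["cell_id"] in used_cells:
            continue
        used_labels.add(lab)
        used_cells.add(row["cell_id"])
        rows.append(
            {
                "label": lab,
                "cell_id": int(row["cell_id"]),
                "cell_class": row["cell_class"],
                "dist_um": d,
                "k": row["k"],
                "c_nuc": row["c_nuc"],
                "c_cyto": row["c_cyto"],
                "red_level": row["red_level"],
            }
        )
    return pd.DataFrame(
        rows,
        columns=["label", "cell_id", "cell_class", "dist_um", "k", "c_nuc", "c_cyto", "red_level"],
    )


def generate_cohort_counts(
    group_specs: Sequence[tuple[str, float, float, int, str]], seed: int
) -> pd.DataFrame:
    """Simulate per-embryo count tables, one row per embryo.

    Each spec is ``(label, mean, sd, n, distribution)`` with distribution
    ``normal-rounded-at-0`` (normal draw, rounded, clipped at 0) or
    ``poisson`` (sd ignored).
    """
    rng = np.random.default_rng(seed)
    rows = []
    for label, mean, sd, n, dist in group_specs:
        if n < 2:
            raise ParameterError(f"group {label!r} needs n >= 2, got {n}")
        if dist == "normal-rounded-at-0":
            draws = rng.normal(mean, sd, size=n) if sd > 0 else np.full(n, float(mean))
            counts = np.clip(np.rint(draws), 0, None).astype(int)
        elif dist == "poisson":
            counts = rng.poisson(mean, size=n).astype(int)
        else:
            raise ParameterError(
                f"unknown distribution {dist!r}; expected one of {COUNT_DISTRIBUTIONS}"
            )
        for i, c in enumerate(counts):
            rows.append({"group": label, "embryo_id": f"{label}_{i:03d}", "count": int(c)})
    return pd.DataFrame(rows, columns=["group", "embryo_id", "count"])
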