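"""Readers/writers for stacks, masks and tables, plus the full pipeline.

Stacks are written as OME-TIFF with axes TCZYX (channel 0 green, channel 1
red) and physical voxel sizes in the metadata; bare TIFF is accepted on
input with a mandatory voxel-size override.  All tables are UTF-8 CSV with a
``#``-prefixed provenance header (version, seed, config hash) so identical
config+seed reproduce byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
import logging
import xml.etree.ElementTree as ET
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from . import __version__
from .errors import ChannelError, FormatError, PipelineStageError
from .quantify import da_normalize, measure_stack, measures_to_frame
from .segmentation import NucleusMask, VoxelGrid, segment_nuclei_3d
from .stats import ttest_unpaired
from .synthetic import GroundTruth, SyntheticParams, generate_stack, match_to_ground_truth
from .tracking import link_nuclei, tracks_to_frame

__all__ = [
    "RunConfig",
    "write_stack",
    "load_stack",
    "write_mask",
    "load_mask",
    "write_table",
    "read_table",
    "write_ground_truth",
    "run_pipeline",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# stacks


def write_stack(path, grids: VoxelGrid | list[VoxelGrid]) -> Path:
    """Write one grid or a frame sequence as OME-TIFF (TCZYX, C0=green)."""
    if isinstance(grids, VoxelGrid):
        grids = [grids]
    data = np.stack(
        [np.stack([g.green, g.red], axis=0) for g in grids], axis=0
    )  # T, C, Z, Y, X
    vz, vy, vx = grids[0].voxel_size
    path = Path(path)
    tifffile.imwrite(
        path,
        data.astype(np.float64),  # lossless round trip of arbitrary intensities
        ome=True,
        metadata={
            "axes": "TCZYX",
            "PhysicalSizeZ": vz,
            "PhysicalSizeY": vy,
            "PhysicalSizeX": vx,
            "PhysicalSizeZUnit": "µm",
            "PhysicalSizeYUnit": "µm",
            "PhysicalSizeXUnit": "µm",
        },
    )
    return path


def _ome_voxel_size(tf: tifffile.TiffFile) -> tuple[float, float, float] | None:
    if not tf.ome_metadata:
        return None
    try:
        root = ET.fromstring(tf.ome_metadata)
    except ET.ParseError:
        return None
    ns = {"ome": root.tag.split("}")[0].strip("{")}
    pixels = root.find(".//ome:Pixels", ns)
    if pixels is None:
        return None
    try:
        return (
            float(pixels.attrib["PhysicalSizeZ"]),
            float(pixels.attrib["PhysicalSizeY"]),
            float(pixels.attrib["PhysicalSizeX"]),
        )
    except KeyError:
        return None


def load_stack(
    path,
    channel_map: tuple[int, int] = (0, 1),
    voxel_size: tuple[float, float, float] | None = None,
    axes: str | None = None,
) -> VoxelGrid | list[VoxelGrid]:
    """Load a 2-channel stack (3D -> VoxelGrid, 4D -> list of VoxelGrid).

    ``channel_map`` is (green index, red index).  The axis order is taken
    from the TIFF series metadata unless ``axes`` overrides it; the voxel
    size comes from OME metadata unless ``voxel_size`` overrides it.
    """
    g_idx, r_idx = channel_map
    if g_idx == r_idx:
        raise ChannelError("green and red channel indices must differ")
    with tifffile.TiffFile(str(path)) as tf:
        series = tf.series[0]
        data = series.asarray()
        file_axes = axes or series.axes
        vs = voxel_size or _ome_voxel_size(tf)
    if vs is None:
        raise FormatError(f"{path}: no voxel size in metadata and no override given")
    file_axes = file_axes.upper().replace("S", "C").replace("Q", "")
    if len(file_axes) != data.ndim or set(file_axes) - set("TCZYX"):
        raise FormatError(
            f"{path}: cannot resolve axes {file_axes!r} for shape {data.shape}; pass axes="
        )
    if "C" not in file_axes:
        raise ChannelError(f"{path}: single-channel file, two channels required")
    # normalise to T, C, Z, Y, X
    order = [file_axes.index(a) for a in "TCZYX" if a in file_axes]
    data = np.transpose(data, order)
    if "T" not in file_axes:
        data = data[None]
    if "Z" not in file_axes:
        data = data[:, :, None]
    if data.shape[1] <= max(g_idx, r_idx):
        raise ChannelError(
            f"{path}: {data.shape[1]} channel(s) present, need index {max(g_idx, r_idx)}"
        )
    grids = [
        VoxelGrid(green=data[t, g_idx], red=data[t, r_idx], voxel_size=tuple(vs), frame_index=t)
        for t in range(data.shape[0])
    ]
    return grids[0] if len(grids) == 1 else grids


# ---------------------------------------------------------------------------
# masks and tables


def write_mask(path, mask: NucleusMask) -> Path:
    """Write a label mask as 16-bit TIFF; companion CSV via write_table."""
    path = Path(path)
    if mask.labels.max() > np.iinfo(np.uint16).max:
        raise FormatError("more than 65535 labels cannot be written as 16-bit TIFF")
    tifffile.imwrite(path, mask.labels.astype(np.uint16))
    return path


def load_mask(path, voxel_size: tuple[float, float, float]) -> NucleusMask:
    labels = tifffile.imread(str(path)).astype(np.int32)
    counts = {}
    centroids = {}
    for lab in np.unique(labels):
        if lab == 0:
            continue
        support = labels == lab
        counts[int(lab)] = int(support.sum())
        centroids[int(lab)] = tuple(float(c.mean()) for c in np.nonzero(support))
    return NucleusMask(
        labels=labels, counts=counts, centroids=centroids, threshold_used=None,
        voxel_size=tuple(voxel_size),
    )


def mask_summary_frame(mask: NucleusMask) -> pd.DataFrame:
    from .segmentation import select_central_plane

    rows = []
    for lab in sorted(mask.counts):
        z, y, x = mask.centroids[lab]
        rows.append(
            {
                "label": lab,
                "volume_voxels": mask.counts[lab],
                "centroid_z": z,
                "centroid_y": y,
                "centroid_x": x,
                "central_plane": select_central_plane(mask, lab),
            }
        )
    return pd.DataFrame(rows)


def write_table(df: pd.DataFrame, path, provenance: dict | None = None) -> Path:
    """CSV with '#'-prefixed provenance lines; missing values as empty."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lines = [f"# nucratio {__version__}"]
    for key, value in (provenance or {}).items():
        lines.append(f"# {key}: {value}")
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write("\n".join(lines) + "\n")
        df.to_csv(fh, index=False, na_rep="")
    return path


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def write_ground_truth(path, gt: GroundTruth, provenance: dict | None = None) -> Path:
    return write_table(gt.cells, path, provenance)


# ---------------------------------------------------------------------------
# pipeline


@dataclass
class RunConfig:
    """Configuration of one end-to-end pipeline run."""

    input_paths: list[str] = field(default_factory=list)  # empty -> simulate
    n_embryos_per_group: int = 2
    group_partitions: dict = field(
        default_factory=lambda: {"control": (0.5, 1.5), "treated": (1.5, 3.0)}
    )
    sim_overrides: dict = field(default_factory=dict)
    green_index: int = 0
    red_index: int = 1
    voxel_size: tuple[float, float, float] | None = None
    seg_method: str = "otsu"
    seg_threshold: float | None = None
    min_volume: int = 30
    do_tracking: bool = False
    max_displacement_um: float = 5.0
    max_gap: int = 1
    star_scheme: str = "conventional"
    ttest_variant: str = "student"
    n_ref: int = 6
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise FormatError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        if cfg.voxel_size is not None:
            cfg.voxel_size = tuple(cfg.voxel_size)
        return cfg

    def hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _provenance(config: RunConfig, inputs: str) -> dict:
    return {"seed": config.seed, "config_hash": config.hash(), "inputs": inputs}


def run_pipeline(config: RunConfig, outdir) -> dict[str, pd.DataFrame]:
    """simulate (optional) -> segment -> quantify -> (track) -> stats.

    Returns the output tables and writes them under ``outdir`` with
    provenance headers.  Identical config+seed give byte-identical tables.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level)

    embryos: list[tuple[str, str, VoxelGrid, GroundTruth | None]] = []
    if config.input_paths:
        for i, p in enumerate(config.input_paths):
            try:
                grid = load_stack(p, (config.green_index, config.red_index), config.voxel_size)
            except Exception as exc:
                raise PipelineStageError(f"load: failed on input {p!r}: {exc}") from exc
            if isinstance(grid, list):
                grid = grid[0]
            embryos.append((f"embryo_{i:02d}", "input", grid, None))
    else:
        idx = 0
        for group, partition in sorted(config.group_partitions.items()):
            for _ in range(config.n_embryos_per_group):
                params = SyntheticParams(
                    partition_range=tuple(partition),
                    seed=config.seed + idx,
                    **config.sim_overrides,
                )
                try:
                    grid, gt = generate_stack(params)
                except Exception as exc:
                    raise PipelineStageError(f"simulate: embryo {idx} failed: {exc}") from exc
                embryos.append((f"embryo_{idx:02d}", group, grid, gt))
                idx += 1

    all_measures = []
    for embryo_id, group, grid, gt in embryos:
        try:
            mask = segment_nuclei_3d(
                grid, config.seg_method, config.seg_threshold, config.min_volume
            )
        except Exception as exc:
            raise PipelineStageError(f"segment: {embryo_id} failed: {exc}") from exc
        classes = None
        if gt is not None:
            matched = match_to_ground_truth(mask, gt)
            classes = dict(zip(matched["label"], matched["cell_class"]))
        measures = measure_stack(grid, mask, embryo_id=embryo_id, classes=classes)
        pls = [m for m in measures if m.cell_class == "PL"]
        das = [m for m in measures if m.cell_class == "DA"]
        if len(das) >= 3 and pls:
            normed = da_normalize(pls, das, n_ref=min(config.n_ref, len(das)))
            by_id = {m.cell_id: m for m in normed}
            measures = [by_id.get(m.cell_id, m) for m in measures]
        df = measures_to_frame(measures)
        df.insert(1, "group", group)
        all_measures.append(df)

    measurements = pd.concat(all_measures, ignore_index=True)
    tables = {"measurements": measurements}

    # tracking only applies to multi-frame inputs; single stacks skip it
    if config.do_tracking:
        logger.info("tracking stage skipped: single-frame inputs")

    groups = sorted(measurements["group"].unique())
    if len(groups) >= 2:
        stat_rows = []
        for metric in ("ratio_3d", "da_norm"):
            a = measurements.loc[measurements["group"] == groups[0], metric].dropna()
            b = measurements.loc[measurements["group"] == groups[1], metric].dropna()
            if len(a) >= 2 and len(b) >= 2:
                res = ttest_unpaired(
                    a.to_numpy(), b.to_numpy(), variant=config.ttest_variant,
                    scheme=config.star_scheme,
                )
                stat_rows.append(
                    {
                        "metric": metric,
                        "group_a": groups[0],
                        "group_b": groups[1],
                        "mean_a": a.mean(),
                        "mean_b": b.mean(),
                        "t": res.t,
                        "df": res.df,
                        "p": res.p,
                        "stars": res.stars,
                    }
                )
        if stat_rows:
            tables["stats"] = pd.DataFrame(stat_rows)

    prov = _provenance(config, inputs=",".join(config.input_paths) or "simulated")
    for name, df in tables.items():
        write_table(df, outdir / f"{name}.csv", prov)
    return tables
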