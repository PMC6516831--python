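"""Frame-to-frame nucleus linking and normalized intensity traces.

Linking is greedy mutual-nearest-centroid in physical (µm) coordinates:
candidate links are ranked by ascending distance (ties by ascending track id
then detection label) and accepted while both endpoints are free and the
distance is within ``max_displacement``.  A track that loses its match while
two fresh detections appear nearby at the next frame becomes a division
parent.  Densities are low (tens of nuclei), so determinism matters more
than assignment optimality here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import AlignmentError, ParameterError, ValidationError
from .quantify import nuclear_mean_intensity
from .segmentation import NucleusMask, VoxelGrid

__all__ = ["TrackRecord", "link_nuclei", "track_intensity_trace", "tracks_to_frame"]


@dataclass
class TrackRecord:
    """A nucleus trajectory: per-frame labels and centroids plus parentage."""

    track_id: int
    parent_track_id: int | None = None
    frames: list[int] = field(default_factory=list)
    labels: list[int] = field(default_factory=list)
    centroids_um: list[tuple[float, float, float]] = field(default_factory=list)
    child_track_ids: tuple[int, int] | None = None

    @property
    def start(self) -> int:
        return self.frames[0]

    @property
    def end(self) -> int:
        return self.frames[-1]

    @property
    def length(self) -> int:
        return len(self.frames)

    @property
    def divided(self) -> bool:
        return self.child_track_ids is not None

    def validate(self) -> None:
        if any(b <= a for a, b in zip(self.frames, self.frames[1:])):
            raise ValidationError(f"track {self.track_id}: frames not strictly increasing")


def _detections(mask: NucleusMask) -> list[tuple[int, np.ndarray]]:
    return [(lab, np.asarray(mask.centroid_um(lab))) for lab in sorted(mask.counts)]


def link_nuclei(
    masks_per_frame: list[NucleusMask],
    max_displacement: float,
    max_gap: int = 1,
) -> list[TrackRecord]:
    """Link per-frame nucleus masks into tracks (distances in µm).

    ``max_gap`` is the number of frames a track may skip and still be linked.
    Divisions: a track unmatched at frame f whose last position lies within
    ``max_displacement`` of two or more unmatched fresh detections at f
    spawns exactly two daughter tracks.
    """
    if len(masks_per_frame) == 0:
        raise ValidationError("link_nuclei requires at least one frame of masks")
    if max_displacement <= 0:
        raise ParameterError("max_displacement must be > 0")
    if max_gap < 0:
        raise ParameterError("max_gap must be >= 0")

    tracks: list[TrackRecord] = []
    open_tracks: list[TrackRecord] = []

    def new_track(frame: int, label: int, centroid: np.ndarray, parent: int | None = None):
        t = TrackRecord(track_id=len(tracks) + 1, parent_track_id=parent)
        t.frames.append(frame)
        t.labels.append(label)
        t.centroids_um.append(tuple(centroid))
        tracks.append(t)
        open_tracks.append(t)
        return t

    for lab, c in _detections(masks_per_frame[0]):
        new_track(0, lab, c)

    for f in range(1, len(masks_per_frame)):
        dets = _detections(masks_per_frame[f])
        eligible = [t for t in open_tracks if t.end >= f - 1 - max_gap]

        candidates = []
        for t in eligible:
            last = np.asarray(t.centroids_um[-1])
            for lab, c in dets:
                d = float(np.linalg.norm(last - c))
                if d <= max_displacement:
                    candidates.append((d, t.track_id, lab, t, c))
        candidates.sort(key=lambda item: (item[0], item[1], item[2]))

        matched_tracks: set[int] = set()
        matched_dets: set[int] = set()
        for d, tid, lab, t, c in candidates:
            if tid in matched_tracks or lab in matched_dets:
                continue
            matched_tracks.add(tid)
            matched_dets.add(lab)
            t.frames.append(f)
            t.labels.append(lab)
            t.centroids_um.append(tuple(c))

        leftover = [(lab, c) for lab, c in dets if lab not in matched_dets]

        # Division pass. Two shapes arise: (a) the parent went unmatched and
        # both daughters are fresh detections nearby; (b) greedy matching
        # already absorbed one daughter into the parent track, leaving the
        # other as a fresh detection near the parent's previous position.
        for t in sorted(open_tracks, key=lambda t: t.track_id):
            if t.divided or not leftover:
                continue
            if t.track_id in matched_tracks:
                if t.length < 2 or t.end != f:
                    continue
                prev = np.asarray(t.centroids_um[-2])
                near = sorted(
                    (
                        (float(np.linalg.norm(prev - c)), lab, c)
                        for lab, c in leftover
                        if float(np.linalg.norm(prev - c)) <= max_displacement
                    ),
                    key=lambda item: (item[0], item[1]),
                )
                if not near:
                    continue
                # retract the greedy link: that detection becomes daughter 1
                d1_lab = t.labels.pop()
                t.frames.pop()
                d1_c = np.asarray(t.centroids_um.pop())
                k1 = new_track(f, d1_lab, d1_c, parent=t.track_id).track_id
                _d, lab2, c2 = near[0]
                k2 = new_track(f, lab2, c2, parent=t.track_id).track_id
                leftover = [(l2, c2_) for l2, c2_ in leftover if l2 != lab2]
                t.child_track_ids = (k1, k2)
            elif t.end == f - 1:
                last = np.asarray(t.centroids_um[-1])
                near = sorted(
                    (
                        (float(np.linalg.norm(last - c)), lab, c)
                        for lab, c in leftover
                        if float(np.linalg.norm(last - c)) <= max_displacement
                    ),
                    key=lambda item: (item[0], item[1]),
                )
                if len(near) >= 2:
                    kids = []
                    for _d, lab, c in near[:2]:
                        kids.append(new_track(f, lab, c, parent=t.track_id).track_id)
                        leftover = [(l2, c2_) for l2, c2_ in leftover if l2 != lab]
                    t.child_track_ids = (kids[0], kids[1])

        for lab, c in leftover:
            new_track(f, lab, c)

        open_tracks = [t for t in tracks if not t.divided and t.end >= f - max_gap]

    for t in tracks:
        t.validate()
    return tracks


def track_intensity_trace(
    track: TrackRecord,
    grids: list[VoxelGrid],
    masks: list[NucleusMask],
) -> pd.DataFrame:
    """Per-frame nuclear mean green/red for one track, with the green trace
    normalized by the track-level mean red.

    Columns: frame, label, mean_green, mean_red, normalized_green, division
    (True on the parent's final frame when the track divided).
    """
    if track.length == 0:
        raise ValidationError("empty track")
    if len(grids) != len(masks):
        raise AlignmentError("grids and masks must align one per frame")
    n = len(grids)
    rows = []
    for frame, label in zip(track.frames, track.labels):
        if frame >= n:
            raise AlignmentError(f"track frame {frame} has no grid (only {n} provided)")
        grid, mask = grids[frame], masks[frame]
        if grid.frame_index != frame:
            raise AlignmentError(
                f"grid at position {frame} carries frame_index {grid.frame_index}"
            )
        rows.append(
            {
                "frame": frame,
                "label": label,
                "mean_green": nuclear_mean_intensity(grid, mask, label, "green"),
                "mean_red": nuclear_mean_intensity(grid, mask, label, "red"),
                "division": track.divided and frame == track.end,
            }
        )
    df = pd.DataFrame(rows)
    mean_red = df["mean_red"].mean()
    df["normalized_green"] = df["mean_green"] / mean_red if mean_red > 0 else np.nan
    return df


def tracks_to_frame(
    tracks: list[TrackRecord],
    grids: list[VoxelGrid] | None = None,
    masks: list[NucleusMask] | None = None,
) -> pd.DataFrame:
    """Long-format track table (one row per frame per track); intensity
    columns are filled when grids and masks are supplied."""
    rows = []
    for t in tracks:
        trace = None
        if grids is not None and masks is not None:
            trace = track_intensity_trace(t, grids, masks).set_index("frame")
        for i, frame in enumerate(t.frames):
            z, y, x = t.centroids_um[i]
            row = {
                "track_id": t.track_id,
                "parent_track_id": t.parent_track_id,
                "frame": frame,
                "cell_label": t.labels[i],
                "z_um": z,
                "y_um": y,
                "x_um": x,
            }
            if trace is not None:
                row["mean_green"] = trace.loc[frame, "mean_green"]
                row["mean_red"] = trace.loc[frame, "mean_red"]
                row["normalized_green"] = trace.loc[frame, "normalized_green"]
            rows.append(row)
    return pd.DataFrame(rows)
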