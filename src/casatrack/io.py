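"""Readers and writers for the pipeline's file contracts.

Videos: multi-page TIFF (preferred) or AVI, single channel.
Detections CSV: ``frame,x_px,y_px,score``.
Tracks CSV: ``track_id,frame,x_px,y_px,x_um,y_um,interpolated``.
"""

from __future__ import annotations

from pathlib import Path
from typing import List, Sequence, Union

import numpy as np
import pandas as pd
import tifffile

from .core import CasatrackError, Detection, KinematicsRecord, Track
from .detection import FrameStack

PathLike = Union[str, Path]


class IOError_(CasatrackError):
    """Unreadable or malformed input file."""


def read_video(path: PathLike, frame_rate: float) -> FrameStack:
    """Load a grayscale video (multi-page TIFF or AVI) as a FrameStack."""
    path = Path(path)
    if not path.exists():
        raise IOError_(f"video not found: {path}")
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        frames = tifffile.imread(str(path))
    else:
        import imageio.v3 as iio
        frames = np.asarray(iio.imread(str(path)))
    if frames.ndim == 2:
        frames = frames[None]
    if frames.ndim == 4:  # RGB(A) -> luminance
        frames = frames[..., :3].mean(axis=-1)
    if frames.ndim != 3 or len(frames) == 0:
        raise IOError_(f"{path}: no frames")
    return FrameStack(frames=np.asarray(frames, dtype=np.float64),
                      frame_rate=frame_rate)


def write_video(stack: FrameStack, path: PathLike) -> None:
    tifffile.imwrite(str(path), np.asarray(stack.frames, dtype=np.float32))


def write_detections_csv(detections_by_frame: Sequence[Sequence[Detection]],
                         path: PathLike) -> None:
    rows = [{"frame": d.frame_index, "x_px": d.x, "y_px": d.y, "score": d.score}
            for dets in detections_by_frame for d in dets]
    pd.DataFrame(rows, columns=["frame", "x_px", "y_px", "score"]).to_csv(
        path, index=False)


def read_detections_csv(path: PathLike) -> List[List[Detection]]:
    """Read a detections CSV into per-frame lists (index = frame)."""
    path = Path(path)
    if not path.exists():
        raise IOError_(f"detections file not found: {path}")
    df = pd.read_csv(path)
    required = {"frame", "x_px", "y_px"}
    if not required <= set(df.columns):
        raise IOError_(f"{path}: missing column(s) {required - set(df.columns)}")
    if len(df) == 0:
        return []
    bad = df[df[["frame", "x_px", "y_px"]].isna().any(axis=1)]
    if len(bad):
        raise IOError_(f"{path}: malformed row at line {int(bad.index[0]) + 2}")
    n_frames = int(df["frame"].max()) + 1
    out: List[List[Detection]] = [[] for _ in range(n_frames)]
    for row in df.itertuples(index=False):
        out[int(row.frame)].append(Detection(
            frame_index=int(row.frame), x=float(row.x_px), y=float(row.y_px),
            score=float(getattr(row, "score", 0.0) or 0.0)))
    return out


def write_tracks_csv(tracks: Sequence[Track], um_per_pixel: float,
                     path: PathLike) -> None:
    rows = []
    for t in tracks:
        for f, (x, y), interp in zip(t.frames, t.xy, t.interpolated):
            rows.append({"track_id": t.track_id, "frame": int(f),
                         "x_px": x, "y_px": y,
                         "x_um": x * um_per_pixel, "y_um": y * um_per_pixel,
                         "interpolated": int(interp)})
    pd.DataFrame(rows, columns=["track_id", "frame", "x_px", "y_px",
                                "x_um", "y_um", "interpolated"]).to_csv(
        path, index=False)


def read_tracks_csv(path: PathLike) -> List[Track]:
    path = Path(path)
    if not path.exists():
        raise IOError_(f"tracks file not found: {path}")
    df = pd.read_csv(path)
    tracks = []
    for tid, grp in df.groupby("track_id", sort=True):
        grp = grp.sort_values("frame")
        tracks.append(Track(
            track_id=int(tid), frames=grp["frame"].to_numpy(),
            xy=grp[["x_px", "y_px"]].to_numpy(),
            interpolated=grp["interpolated"].to_numpy().astype(bool)
            if "interpolated" in grp else None))
    return tracks


def write_kinematics_csv(records: Sequence[KinematicsRecord],
                         path: PathLike) -> None:
    rows = [{"track_id": r.track_id, "n_points": r.n_points,
             "vsl_um_s": r.vsl, "vcl_um_s": r.vcl, "lin_pct": r.lin,
             "class": r.motility_class} for r in records]
    pd.DataFrame(rows, columns=["track_id", "n_points", "vsl_um_s",
                                "vcl_um_s", "lin_pct", "class"]).to_csv(
        path, index=False)


def write_rejects_csv(rejects: Sequence, path: PathLike) -> None:
    rows = [{"track_id": r.track_id, "n_points": r.n_points,
             "vsl_um_s": r.vsl, "vcl_um_s": r.vcl, "lin_pct": r.lin,
             "reason": reason} for r, reason in rejects]
    pd.DataFrame(rows, columns=["track_id", "n_points", "vsl_um_s",
                                "vcl_um_s", "lin_pct", "reason"]).to_csv(
        path, index=False)


def write_circles_csv(records: Sequence[KinematicsRecord], fits: Sequence,
                      path: PathLike) -> None:
    rows = []
    for rec, fit in zip(records, fits):
        rows.append({"track_id": rec.track_id, "class": rec.motility_class,
                     "radius_um": fit.radius if fit else np.nan,
                     "rms_residual_um": fit.rms_residual if fit else np.nan,
                     "turning_angle_rad": fit.turning_angle if fit else np.nan,
                     "is_circular": int(rec.is_circular)})
    pd.DataFrame(rows, columns=["track_id", "class", "radius_um",
                                "rms_residual_um", "turning_angle_rad",
                                "is_circular"]).to_csv(path, index=False)


def write_ground_truth_csv(ground_truth, path: PathLike) -> None:
    rows = []
    for i, spec in enumerate(ground_truth.specs):
        for k, f in enumerate(ground_truth.frames):
            rows.append({"swimmer_id": i, "frame": int(f),
                         "x_um": ground_truth.xy_um[i, k, 0],
                         "y_um": ground_truth.xy_um[i, k, 1],
                         "motion_kind": spec.motion_kind,
                         "class_label": spec.class_label,
                         "vcl_um_s": spec.vcl_um_s,
                         "circle_radius_um": spec.circle_radius_um or np.nan})
    pd.DataFrame(rows).to_csv(path, index=False)
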