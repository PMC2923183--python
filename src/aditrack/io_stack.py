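"""Image-stack and trajectory I/O.

Conventions shared by every module:

* pixel coordinates are 0-based ``(row, col)`` with row 0 at the image top;
* stacks are 3D float arrays indexed ``(frame, row, col)``, normalized to
  ``[0, 1]``;
* physical coordinates (µm) are derived only at export/statistics time via
  ``pixel_size_um``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "ImageStack",
    "load_stack",
    "write_stack",
    "write_trajectories",
    "read_trajectories",
]

TRAJECTORY_COLUMNS = ["target_id", "frame", "row", "col", "x_um", "y_um"]


@dataclass
class ImageStack:
    """A normalized 2D fluorescence time series.

    Parameters
    ----------
    frames : ndarray, shape (M, H, W)
        Intensity values in ``[0, 1]``.
    pixel_size_um : float
        Physical size of one pixel, µm.
    frame_interval_s : float
        Acquisition interval between consecutive frames, s.
    """

    frames: np.ndarray
    pixel_size_um: float = 1.0
    frame_interval_s: float = 1.0

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames, dtype=np.float64)
        if frames.ndim != 3:
            raise ValueError(f"frames must be 3D (frame, row, col); got ndim={frames.ndim}")
        if frames.shape[0] < 1:
            raise ValueError("stack must contain at least one frame")
        if self.pixel_size_um <= 0 or self.frame_interval_s <= 0:
            raise ValueError("pixel_size_um and frame_interval_s must be positive")
        self.frames = frames

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def height(self) -> int:
        return self.frames.shape[1]

    @property
    def width(self) -> int:
        return self.frames.shape[2]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.frames.shape


def _normalize(frames: np.ndarray) -> np.ndarray:
    """Rescale raw pixel data to [0, 1].

    Integer types divide by the dtype maximum so a given threshold means the
    same fraction of full scale in every frame; float input is min-max
    normalized over the whole stack (not per frame) so one threshold value
    stays meaningful across frames.
    """
    if np.issubdtype(frames.dtype, np.integer):
        info = np.iinfo(frames.dtype)
        return frames.astype(np.float64) / float(info.max)
    frames = frames.astype(np.float64)
    lo, hi = float(frames.min()), float(frames.max())
    if hi == lo:
        return np.zeros_like(frames)
    return (frames - lo) / (hi - lo)


def load_stack(path: str | os.PathLike, pixel_size_um: float = 1.0,
               frame_interval_s: float = 1.0) -> ImageStack:
    """Load a multi-page TIFF, or a directory of same-shape single-page TIFFs.

    Frames are ordered by page index (multi-page) or lexicographic filename
    (directory).  Intensities are normalized to ``[0, 1]`` (see
    :func:`_normalize`).

    Raises
    ------
    FileNotFoundError
        If *path* does not exist or a directory holds no TIFF files.
    ValueError
        If frames disagree in shape.
    """
    path = Path(path)
    if path.is_dir():
        names = sorted(p for p in path.iterdir()
                       if p.suffix.lower() in (".tif", ".tiff"))
        if not names:
            raise FileNotFoundError(f"no TIFF files in directory {path}")
        pages = [tifffile.imread(p) for p in names]
        shapes = {p.shape for p in pages}
        if len(shapes) > 1:
            raise ValueError(f"inconsistent frame shapes in {path}: {sorted(shapes)}")
        raw = np.stack(pages, axis=0)
    elif path.exists():
        raw = tifffile.imread(path)
        if raw.ndim == 2:
            raw = raw[None]
        if raw.ndim != 3:
            raise ValueError(f"expected 2D pages in {path}; got array of ndim {raw.ndim}")
    else:
        raise FileNotFoundError(str(path))
    return ImageStack(_normalize(raw), pixel_size_um=pixel_size_um,
                      frame_interval_s=frame_interval_s)


def write_stack(stack_or_array: "ImageStack | np.ndarray", path: str | os.PathLike) -> None:
    """Write a stack as a multi-page TIFF, preserving dtype for raw arrays."""
    if isinstance(stack_or_array, ImageStack):
        data = stack_or_array.frames.astype(np.float32)
    else:
        data = np.asarray(stack_or_array)
    tifffile.imwrite(os.fspath(path), data, photometric="minisblack")


def write_trajectories(trajs, path: str | os.PathLike,
                       pixel_size_um: float | None = None) -> None:
    """Serialize a :class:`~aditrack.linking.TrajectorySet` to CSV.

    Columns: ``target_id,frame,row,col,x_um,y_um`` with
    ``x_um = col * pixel_size_um`` and ``y_um = row * pixel_size_um``;
    rows sorted by ``(target_id, frame)``.
    """
    if pixel_size_um is None:
        pixel_size_um = getattr(trajs, "pixel_size_um", 1.0) or 1.0
    records = []
    for traj in trajs.trajectories:
        for frame, row, col in traj.samples:
            records.append((traj.target_id, frame, row, col,
                            col * pixel_size_um, row * pixel_size_um))
    df = pd.DataFrame(records, columns=TRAJECTORY_COLUMNS)
    df = df.sort_values(["target_id", "frame"], kind="stable")
    df.to_csv(path, index=False)


def read_trajectories(path: str | os.PathLike):
    """Reparse a trajectory CSV written by :func:`write_trajectories`."""
    from aditrack.linking import Trajectory, TrajectorySet

    df = pd.read_csv(path)
    missing = [c for c in TRAJECTORY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trajectory CSV missing columns: {missing}")
    trajectories = []
    for tid, group in df.groupby("target_id", sort=True):
        group = group.sort_values("frame")
        samples = [(int(f), int(r), int(c))
                   for f, r, c in zip(group["frame"], group["row"], group["col"])]
        trajectories.append(Trajectory(target_id=int(tid), samples=samples))
    return TrajectorySet(trajectories=trajectories)
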