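"""Phases D and G: time-color-coded trajectory rendering.

All trajectories are painted on a single RGB image with the passage time of
each pixel coded by the colormap (later times overwrite earlier ones at
shared pixels); per-target labels take a start-time color from red to blue.
Overlay mode exports one frame per time point with the cumulative trace.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = ["RenderSpec", "render_trajectory_image", "render_overlay_frames",
           "save_png", "save_frame_sequence"]

MAGENTA = np.array([1.0, 0.0, 1.0])


@dataclass
class RenderSpec:
    colormap: str = "green-levels"  # or "jet"
    show_seed_pixels: bool = True
    show_labels: bool = True
    background: str = "first-frame"  # or "black"

    def __post_init__(self) -> None:
        if self.colormap not in ("green-levels", "jet"):
            raise ValueError("colormap must be 'green-levels' or 'jet'")
        if self.background not in ("first-frame", "black"):
            raise ValueError("background must be 'first-frame' or 'black'")


def _time_color(frac: np.ndarray | float, colormap: str) -> np.ndarray:
    """Map time fraction in [0,1] to RGB; monotone in time for both maps."""
    frac = np.atleast_1d(np.clip(frac, 0.0, 1.0))
    if colormap == "green-levels":
        # dark to light green
        rgb = np.zeros(frac.shape + (3,))
        rgb[..., 1] = 0.25 + 0.75 * frac
    else:  # jet
        import matplotlib
        matplotlib.use("Agg")
        from matplotlib import cm
        rgb = cm.jet(frac)[..., :3]
    return rgb


def _label_color(frac: float) -> tuple[float, float, float]:
    """Start-time label color: red at t=0 fading linearly to blue at t=M-1."""
    return (1.0 - frac, 0.0, frac)


def _background(stack, spec: RenderSpec) -> np.ndarray:
    frames = stack.frames if hasattr(stack, "frames") else np.asarray(stack)
    h, w = frames.shape[1:]
    if spec.background == "black":
        return np.zeros((h, w, 3))
    return np.repeat(frames[0][..., None], 3, axis=2)


def _paint_label(img: np.ndarray, text: str, pos: tuple[int, int],
                 color: tuple[float, float, float]) -> None:
    """Rasterize *text* near *pos* with PIL; shift +1 px diagonally until the
    anchor pixel is free of previously painted labels."""
    from PIL import Image, ImageDraw

    h, w = img.shape[:2]
    r, c = pos
    occupied = getattr(_paint_label, "_anchors", None)
    if occupied is None:
        occupied = set()
    while (r, c) in occupied and r < h - 1 and c < w - 1:
        r += 1
        c += 1
    occupied.add((r, c))
    _paint_label._anchors = occupied
    mask_img = Image.new("L", (w, h), 0)
    draw = ImageDraw.Draw(mask_img)
    draw.text((c, r), text, fill=255)
    mask = np.asarray(mask_img) > 128
    img[mask] = color


def render_trajectory_image(trajs, stack, spec: RenderSpec | None = None) -> np.ndarray:
    """Single 2D RGB image of all trajectories, time coded by color.

    Every sample (t, p) paints pixel p with colormap(t/(M-1)); later passage
    times overwrite earlier ones.  Frame-0 seed pixels are painted magenta
    when enabled; each trajectory is labeled with its target_id at its first
    sample, colored red->blue by start time.
    """
    spec = spec or RenderSpec()
    frames = stack.frames if hasattr(stack, "frames") else np.asarray(stack)
    M = frames.shape[0]
    img = _background(stack, spec)
    denom = max(M - 1, 1)

    # overwrite rule: paint in increasing time order across all trajectories
    events = []
    for traj in trajs.trajectories:
        for t, r, c in traj.samples:
            events.append((t, r, c))
    for t, r, c in sorted(events):
        img[r, c] = _time_color(t / denom, spec.colormap)[0]

    if spec.show_seed_pixels:
        for traj in trajs.trajectories:
            t0, r0, c0 = traj.samples[0]
            if t0 == 0:
                img[r0, c0] = MAGENTA

    if spec.show_labels:
        _paint_label._anchors = set()
        for traj in trajs.trajectories:
            t0, r0, c0 = traj.samples[0]
            _paint_label(img, str(traj.target_id), (r0, c0),
                         _label_color(t0 / denom))
    return np.clip(img, 0.0, 1.0)


def render_overlay_frames(stack, traj, spec: RenderSpec | None = None) -> list[np.ndarray]:
    """Cumulative-trace overlay: frame j shows the original image with the
    trajectory's samples up to time j painted per colormap."""
    spec = spec or RenderSpec()
    frames = stack.frames if hasattr(stack, "frames") else np.asarray(stack)
    M = frames.shape[0]
    if traj.samples and not (0 <= traj.samples[0][0] and traj.samples[-1][0] < M):
        raise ValueError("trajectory frames outside stack range")
    denom = max(M - 1, 1)
    out = []
    for j in range(M):
        img = np.repeat(frames[j][..., None], 3, axis=2)
        for t, r, c in traj.samples:
            if t <= j:
                img[r, c] = _time_color(t / denom, spec.colormap)[0]
        out.append(np.clip(img, 0.0, 1.0))
    return out


def save_png(img: np.ndarray, path: str | os.PathLike) -> None:
    import imageio.v3 as iio

    iio.imwrite(os.fspath(path), (np.clip(img, 0, 1) * 255).astype(np.uint8))


def save_frame_sequence(frames: list[np.ndarray], directory: str | os.PathLike,
                        prefix: str = "frame") -> list[Path]:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    width = max(4, len(str(len(frames) - 1)))
    for j, img in enumerate(frames):
        p = directory / f"{prefix}_{j:0{width}d}.png"
        save_png(img, p)
        paths.append(p)
    return paths
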