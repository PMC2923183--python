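"""Phase A: four-filter segmentation.

Each frame is reduced to a binary map holding exactly one marked pixel per
discerned target: minimum filter (suppresses high-frequency background),
value-preserving threshold (one T for the whole stack, found iteratively on a
user-selected region of frame 0), mean filter, and maximum-based peak picking.
Works for point-like spots (3x3 masks) through cell-scale blobs (11x11 masks).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.ndimage as ndi
from skimage import measure

__all__ = [
    "SegmentationParams",
    "DetectionStack",
    "minimum_filter",
    "find_threshold",
    "apply_threshold",
    "mean_max_reduce",
    "segment_stack",
]

THRESHOLD_STEP = 1.0 / 1024.0  # grid step of the iterative threshold search


@dataclass
class SegmentationParams:
    """Knobs of the phase-A chain.

    ``m_m``/``m_b`` are filter half-widths: mask matrices are
    ``(2m+1) x (2m+1)``.  ``threshold`` is either an explicit value in
    ``[0, 1)`` or ``"auto"``, in which case ``roi`` (``row0, col0, row1,
    col1``, half-open) and ``expected_count`` drive the iterative search on
    frame 0.
    """

    m_m: int = 1
    m_b: int = 1
    threshold: float | str = "auto"
    roi: tuple[int, int, int, int] | None = None
    expected_count: int | None = None
    min_blob_px: int = 3

    def __post_init__(self) -> None:
        if self.m_m < 1 or self.m_b < 1:
            raise ValueError("filter half-widths m_m and m_b must be >= 1")
        if self.min_blob_px < 1:
            raise ValueError("min_blob_px must be >= 1")
        if not (self.threshold == "auto"
                or (isinstance(self.threshold, (int, float)) and 0 <= self.threshold < 1)):
            raise ValueError("threshold must be 'auto' or a float in [0, 1)")


@dataclass
class DetectionStack:
    """Per-frame binary single-pixel target maps (one mark per target)."""

    maps: np.ndarray  # bool, shape (M, H, W)
    border_margin: int = 0

    def __post_init__(self) -> None:
        self.maps = np.asarray(self.maps, dtype=bool)
        if self.maps.ndim != 3:
            raise ValueError("maps must be 3D (frame, row, col)")

    @property
    def n_frames(self) -> int:
        return self.maps.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.maps.shape

    def positions(self, frame: int) -> list[tuple[int, int]]:
        """Marked (row, col) pixels of one frame, lexicographically ordered."""
        rows, cols = np.nonzero(self.maps[frame])
        return list(zip(rows.tolist(), cols.tolist()))


def minimum_filter(frame: np.ndarray, m_m: int = 1) -> np.ndarray:
    """Minimum over the (2*m_m+1)^2 window centered at each pixel.

    The outer frame of ``m_m`` pixels, where the window leaves the image, is
    excluded from the analysis and set to 0.
    """
    frame = np.asarray(frame, dtype=np.float64)
    if frame.ndim != 2:
        raise ValueError("frame must be 2D")
    h, w = frame.shape
    if 2 * m_m >= h or 2 * m_m >= w:
        raise ValueError(f"m_m={m_m} leaves no interior in a {h}x{w} frame")
    out = ndi.minimum_filter(frame, size=2 * m_m + 1, mode="nearest")
    out[:m_m, :] = 0.0
    out[-m_m:, :] = 0.0
    out[:, :m_m] = 0.0
    out[:, -m_m:] = 0.0
    return out


def apply_threshold(frame: np.ndarray, T: float) -> np.ndarray:
    """Value-preserving threshold: keep intensities >= T, zero the rest.

    Keeping graded values (rather than binarizing) gives the subsequent mean
    filter a graded input, so peak picking does not depend solely on the
    plateau tie-break.
    """
    if not (0 <= T < 1):
        raise ValueError(f"threshold must be in [0, 1); got {T}")
    frame = np.asarray(frame, dtype=np.float64)
    return np.where(frame >= T, frame, 0.0)


def _count_blobs(frame: np.ndarray, T: float, min_blob_px: int) -> int:
    """8-connected components of area >= min_blob_px after thresholding."""
    # blobs are the nonzero pixels of the value-preserving threshold output
    mask = (frame >= T) & (frame > 0)
    labels, n = measure.label(mask, connectivity=2, return_num=True)
    if n == 0:
        return 0
    areas = np.bincount(labels.ravel())[1:]
    return int(np.sum(areas >= min_blob_px))


def find_threshold(frame: np.ndarray, roi: tuple[int, int, int, int],
                   expected_count: int, min_blob_px: int = 3,
                   step: float = THRESHOLD_STEP) -> float:
    """Iterative threshold search on a (minimum-filtered) frame.

    Starting from T=0 and increasing by *step*, return the smallest T at which
    the number of 8-connected components with area >= ``min_blob_px`` inside
    *roi* equals ``expected_count``.

    Raises
    ------
    ValueError
        If no grid threshold yields the expected count; the message reports
        the range of counts that were achievable.
    """
    if expected_count < 1:
        raise ValueError("expected_count must be >= 1")
    r0, c0, r1, c1 = roi
    sub = np.asarray(frame, dtype=np.float64)[r0:r1, c0:c1]
    if sub.size == 0:
        raise ValueError(f"empty roi {roi}")
    counts = []
    grid = np.arange(0.0, 1.0, step)
    for T in grid:
        n = _count_blobs(sub, float(T), min_blob_px)
        counts.append(n)
        if n == expected_count:
            return float(T)
        if n == 0 and T > sub.max():
            break  # nothing survives any higher threshold
    raise ValueError(
        f"no threshold on the grid yields {expected_count} blobs; "
        f"achievable counts ranged over [{min(counts)}, {max(counts)}]")


def mean_max_reduce(frame: np.ndarray, m_b: int = 1) -> np.ndarray:
    """Mean filter then maximum-based reduction to single-pixel marks.

    A pixel is marked iff its mean-filtered value is positive and equals the
    maximum of the mean-filtered image over the same (2*m_b+1)^2 window.
    Plateau ties (8-connected marked sets with equal smoothed value) keep only
    the lexicographically smallest (row, col), so each target yields exactly
    one pixel.
    """
    frame = np.asarray(frame, dtype=np.float64)
    size = 2 * m_b + 1
    smooth = ndi.uniform_filter(frame, size=size, mode="constant", cval=0.0)
    # uniform_filter's running sum leaves ~1e-17 residue on empty regions;
    # restrict strictly to windows that actually contain a positive pixel
    support = ndi.maximum_filter(frame > 0, size=size, mode="constant", cval=False)
    smooth = np.where(support, smooth, 0.0)
    # quantize away the running-sum roundoff (~1e-16) so plateaus — windows
    # fully covering one blob — compare exactly equal and the deterministic
    # tie-break below applies, instead of roundoff picking a random pixel
    smooth = np.round(smooth, 9)
    local_max = ndi.maximum_filter(smooth, size=size, mode="constant", cval=0.0)
    marked = (smooth > 0) & (smooth >= local_max)
    if not marked.any():
        return np.zeros_like(marked)
    # adjacent marked pixels necessarily share the same smoothed value
    # (each lies in the other's max window), so one survivor per component
    labels, n = measure.label(marked, connectivity=2, return_num=True)
    out = np.zeros_like(marked)
    for comp in range(1, n + 1):
        rows, cols = np.nonzero(labels == comp)
        order = np.lexsort((cols, rows))
        out[rows[order[0]], cols[order[0]]] = True
    return out


def segment_stack(stack, params: SegmentationParams) -> DetectionStack:
    """Run the full phase-A chain on every frame of *stack*.

    Per frame: minimum filter -> threshold (one T for the whole stack; "auto"
    resolves T on frame 0 inside ``params.roi``) -> mean/max reduction.
    Marks closer than ``m_m + m_b`` to the image edge are removed, since both
    filter windows are invalid there.
    """
    frames = stack.frames if hasattr(stack, "frames") else np.asarray(stack, dtype=np.float64)
    filtered0 = minimum_filter(frames[0], params.m_m)
    if params.threshold == "auto":
        if params.roi is None or params.expected_count is None:
            raise ValueError("auto threshold requires roi and expected_count")
        T = find_threshold(filtered0, params.roi, params.expected_count,
                           min_blob_px=params.min_blob_px)
    else:
        T = float(params.threshold)

    margin = params.m_m + params.m_b
    maps = np.zeros(frames.shape, dtype=bool)
    for j in range(frames.shape[0]):
        filtered = filtered0 if j == 0 else minimum_filter(frames[j], params.m_m)
        maps[j] = mean_max_reduce(apply_threshold(filtered, T), params.m_b)
        maps[j, :margin, :] = False
        maps[j, -margin:, :] = False
        maps[j, :, :margin] = False
        maps[j, :, -margin:] = False
    return DetectionStack(maps=maps, border_margin=margin)
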