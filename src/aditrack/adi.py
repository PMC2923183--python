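"""Phase B: passage-time bookkeeping from the binary detection stack.

Frame-to-frame differences of the segmented maps record, per pixel, the
frames at which a target *newly* arrives there (its "passage times").  A
pixel may be revisited, so each pixel stores an increasing list of passage
times; frame-0 occupancy is kept separately as the seed set.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["PassageMap", "build_passage_map"]


@dataclass
class PassageMap:
    """Per-pixel ordered passage times plus the frame-0 seed pixels."""

    passages: dict[tuple[int, int], list[int]]
    seeds0: set[tuple[int, int]]
    n_frames: int
    threshold_S: float = 0.0

    def first_passage_after(self, pixel: tuple[int, int], t: int) -> int | None:
        """Smallest stored passage time strictly greater than *t*, or None."""
        times = self.passages.get(pixel)
        if not times:
            return None
        i = bisect_right(times, t)
        return times[i] if i < len(times) else None

    @property
    def n_events(self) -> int:
        return sum(len(v) for v in self.passages.values())

    def to_frame(self) -> pd.DataFrame:
        """Debug dump: one (row, col, frame) record per passage event."""
        records = [(r, c, t) for (r, c), ts in sorted(self.passages.items()) for t in ts]
        return pd.DataFrame(records, columns=["row", "col", "frame"])


def build_passage_map(det, S: float = 0.0) -> PassageMap:
    """Accumulate frame differences of a binary detection stack.

    For each frame j >= 1 and pixel p, a passage event (p, j) is stored when
    |det_j(p) - det_{j-1}(p)| > S and det_j(p) = 1, i.e. on new occupancy.
    On binary maps any S in [0, 1) gives the same result.  Departures (1 -> 0)
    carry no linkable position and are dropped.
    """
    if not (0 <= S < 1):
        raise ValueError(f"S must be in [0, 1); got {S}")
    maps = det.maps if hasattr(det, "maps") else np.asarray(det, dtype=bool)
    if maps.shape[0] < 2:
        raise ValueError("passage map needs at least 2 frames")
    passages: dict[tuple[int, int], list[int]] = {}
    diff = np.abs(maps[1:].astype(np.int8) - maps[:-1].astype(np.int8))
    arrivals = (diff > S) & maps[1:]
    frames_idx, rows, cols = np.nonzero(arrivals)
    for f, r, c in sorted(zip(frames_idx.tolist(), rows.tolist(), cols.tolist())):
        passages.setdefault((r, c), []).append(f + 1)
    seeds0 = set(zip(*[a.tolist() for a in np.nonzero(maps[0])]))
    return PassageMap(passages=passages, seeds0=seeds0,
                      n_frames=maps.shape[0], threshold_S=S)
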