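"""Phases C and H: shell-search trajectory linking on the passage map.

From each seed pixel the tracker repeatedly jumps to the neighboring pixel
(concentric Chebyshev shells up to ``shell_radius``) holding the smallest
passage time later than the current one.  Multi-start mode re-seeds the
search on every ``incrementostep``-th frame so loop and crossing segments a
single start misses are still recovered as sub-trajectories; duplicates
across restarts are deliberately kept.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from aditrack.adi import PassageMap

__all__ = [
    "Trajectory",
    "LinkingParams",
    "TrajectorySet",
    "next_position",
    "track_from_frame",
    "track_all",
]


@dataclass
class Trajectory:
    """One linked target track: ordered (frame, row, col) samples."""

    target_id: int
    samples: list[tuple[int, int, int]]

    def __post_init__(self) -> None:
        frames = [s[0] for s in self.samples]
        if any(b <= a for a, b in zip(frames, frames[1:])):
            raise ValueError("trajectory frames must be strictly increasing")

    @property
    def start_frame(self) -> int:
        return self.samples[0][0]

    def __len__(self) -> int:
        return len(self.samples)


@dataclass
class LinkingParams:
    shell_radius: int = 3
    incrementostep: int = 0  # 0 = single start from frame 0
    min_length: int = 3

    def __post_init__(self) -> None:
        if self.shell_radius < 1:
            raise ValueError("shell_radius must be >= 1")
        if self.incrementostep < 0:
            raise ValueError("incrementostep must be >= 0")
        if self.min_length < 1:
            raise ValueError("min_length must be >= 1")


@dataclass
class TrajectorySet:
    trajectories: list[Trajectory] = field(default_factory=list)
    params: LinkingParams | None = None
    stack_shape: tuple[int, int, int] | None = None
    pixel_size_um: float = 1.0
    frame_interval_s: float = 1.0

    def __post_init__(self) -> None:
        ids = [t.target_id for t in self.trajectories]
        if len(ids) != len(set(ids)):
            raise ValueError("target_ids must be unique")

    def __len__(self) -> int:
        return len(self.trajectories)

    def __iter__(self):
        return iter(self.trajectories)

    def get(self, target_id: int) -> Trajectory:
        for t in self.trajectories:
            if t.target_id == target_id:
                return t
        raise KeyError(f"no trajectory with target_id {target_id}")


def next_position(pmap: PassageMap, pos: tuple[int, int], t: int,
                  shell_radius: int = 3):
    """Best next hop from *pos* after time *t*, or None.

    Candidates are pixels at Chebyshev distance 1..shell_radius from *pos*
    (the current pixel itself is excluded) holding some passage time j > t.
    The winner minimizes (j, Chebyshev distance, (row, col)): the earliest
    later passage dominates; distance and lexicographic order break ties.
    """
    r0, c0 = pos
    best = None  # (j, dist, row, col)
    for dr in range(-shell_radius, shell_radius + 1):
        for dc in range(-shell_radius, shell_radius + 1):
            if dr == 0 and dc == 0:
                continue
            q = (r0 + dr, c0 + dc)
            j = pmap.first_passage_after(q, t)
            if j is None:
                continue
            key = (j, max(abs(dr), abs(dc)), q[0], q[1])
            if best is None or key < best:
                best = key
    if best is None:
        return None
    return (best[2], best[3]), best[0]


def track_from_frame(pmap: PassageMap, det, start: int,
                     params: LinkingParams | None = None,
                     id_offset: int = 0) -> list[Trajectory]:
    """Follow every target segmented on frame *start* to the end of the stack.

    Each seed yields one trajectory whose first sample is (start, seed);
    subsequent samples are the chained ``next_position`` hops.  Trajectories
    shorter than ``params.min_length`` samples are discarded.
    """
    params = params or LinkingParams()
    if not (0 <= start < pmap.n_frames):
        raise ValueError(f"start frame {start} outside [0, {pmap.n_frames - 1}]")
    if start == 0:
        seeds = sorted(pmap.seeds0)
    else:
        rows, cols = np.nonzero(det.maps[start])
        seeds = sorted(zip(rows.tolist(), cols.tolist()))
    out = []
    tid = id_offset
    for seed in seeds:
        samples = [(start, seed[0], seed[1])]
        pos, t = seed, start
        while True:
            hop = next_position(pmap, pos, t, params.shell_radius)
            if hop is None:
                break
            pos, t = hop
            samples.append((t, pos[0], pos[1]))
        if len(samples) >= params.min_length:
            out.append(Trajectory(target_id=tid, samples=samples))
            tid += 1
    return out


def track_all(det, params: LinkingParams | None = None,
              pmap: PassageMap | None = None,
              pixel_size_um: float = 1.0,
              frame_interval_s: float = 1.0) -> TrajectorySet:
    """Track from frame 0 and, in multi-start mode, from every
    ``incrementostep``-th frame, on one shared passage map.

    All sub-trajectories are retained with distinct target ids and no
    deduplication: the same physical target legitimately appears once per
    restart that re-segments it.
    """
    from aditrack.adi import build_passage_map

    params = params or LinkingParams()
    if pmap is None:
        pmap = build_passage_map(det)
    M = pmap.n_frames
    if params.incrementostep == 0 or params.incrementostep >= M:
        starts = [0]
    else:
        starts = list(range(0, M, params.incrementostep))
    trajectories: list[Trajectory] = []
    for start in starts:
        subs = track_from_frame(pmap, det, start, params,
                                id_offset=len(trajectories))
        trajectories.extend(subs)
    return TrajectorySet(trajectories=trajectories, params=params,
                         stack_shape=det.maps.shape,
                         pixel_size_um=pixel_size_um,
                         frame_interval_s=frame_interval_s)
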