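"""Phases E, F, I, K: crossing detection and paragon splicing.

Sub-trajectories that share a space-time window (dx, dy, dt) are grouped;
each group's samples are merged into a time-ordered "paragon" table carrying
per-row position differences, which is then cut into continuous segments
wherever a step exceeds ``threshold_paragon``.  Final merging of segments is
user-driven: :func:`merge_segments` validates an ordered choice of segments
but nothing is merged automatically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from aditrack.linking import Trajectory, TrajectorySet

__all__ = [
    "CrossingSet",
    "ParagonTable",
    "find_crossings",
    "build_paragon",
    "split_paragon",
    "merge_segments",
]

PARAGON_COLUMNS = ["frame", "row", "col", "target_id", "d_row", "d_col"]


@dataclass
class CrossingSet:
    """Witnessed crossings and the connected components they induce."""

    pairs: set[tuple]  # (tid_a, tid_b, frame, (ra, ca), (rb, cb)), tid_a < tid_b
    groups: list[set[int]]  # connected components over all target ids

    def group_of(self, target_id: int) -> set[int]:
        for g in self.groups:
            if target_id in g:
                return g
        raise KeyError(f"target_id {target_id} not in any group")


@dataclass
class ParagonTable:
    """Time-ordered union of crossing sub-trajectories with step differences."""

    rows: list[tuple[int, int, int, int, int, int]]  # PARAGON_COLUMNS order
    source_group: int = 0

    def __len__(self) -> int:
        return len(self.rows)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=PARAGON_COLUMNS)

    def positions(self) -> list[tuple[int, int, int]]:
        """(frame, row, col) triples, table order."""
        return [(f, r, c) for f, r, c, *_ in self.rows]


def _union_find_groups(ids: list[int], edges: set[tuple[int, int]]) -> list[set[int]]:
    parent = {i: i for i in ids}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in edges:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
    comps: dict[int, set[int]] = {}
    for i in ids:
        comps.setdefault(find(i), set()).add(i)
    return sorted(comps.values(), key=lambda s: min(s))


def find_crossings(trajs: TrajectorySet, dx: int = 3, dy: int = 3,
                   dt: int = 1) -> CrossingSet:
    """Pairs of trajectories sharing a hyper-volume dx*dy*dt.

    Trajectories a != b cross iff some samples (t_a, p_a) of a and (t_b, p_b)
    of b satisfy |t_a - t_b| <= dt, |row difference| <= dy and
    |col difference| <= dx.  Groups are the connected components of the
    crossing graph (singletons included).
    """
    if dx < 0 or dy < 0 or dt < 0:
        raise ValueError("dx, dy, dt must be >= 0")
    tlist = trajs.trajectories
    pairs: set[tuple] = set()
    edges: set[tuple[int, int]] = set()
    # samples sorted by frame per trajectory allow an early frame-window cut
    sorted_samples = {t.target_id: sorted(t.samples) for t in tlist}
    for i in range(len(tlist)):
        for k in range(i + 1, len(tlist)):
            a, b = tlist[i], tlist[k]
            sa, sb = sorted_samples[a.target_id], sorted_samples[b.target_id]
            hit = None
            bi = 0
            for ta, ra, ca in sa:
                while bi < len(sb) and sb[bi][0] < ta - dt:
                    bi += 1
                for tb, rb, cb in sb[bi:]:
                    if tb > ta + dt:
                        break
                    if abs(ra - rb) <= dy and abs(ca - cb) <= dx:
                        hit = (ta if ta <= tb else tb, (ra, ca), (rb, cb))
                        break
                if hit:
                    break
            if hit:
                lo, hi = sorted((a.target_id, b.target_id))
                pairs.add((lo, hi, hit[0], hit[1], hit[2]))
                edges.add((lo, hi))
    groups = _union_find_groups([t.target_id for t in tlist], edges)
    return CrossingSet(pairs=pairs, groups=groups)


def build_paragon(trajs: TrajectorySet, group: set[int],
                  source_group: int = 0) -> ParagonTable:
    """Merge a crossing group's samples into one time-ordered table.

    Samples are sorted by (frame, target_id); exact duplicate
    (frame, row, col, target_id) rows are removed; d_row/d_col hold the
    differences from the previous row (0 on the first row).
    """
    if not group:
        raise ValueError("group must be nonempty")
    raw = []
    for tid in sorted(group):
        traj = trajs.get(tid)
        for f, r, c in traj.samples:
            raw.append((f, tid, r, c))
    raw.sort()
    rows: list[tuple[int, int, int, int, int, int]] = []
    seen = set()
    prev = None
    for f, tid, r, c in raw:
        key = (f, r, c, tid)
        if key in seen:
            continue
        seen.add(key)
        if prev is None:
            d_row = d_col = 0
        else:
            d_row, d_col = r - prev[1], c - prev[2]
        rows.append((f, r, c, tid, d_row, d_col))
        prev = (f, r, c)
    return ParagonTable(rows=rows, source_group=source_group)


def _rebase(rows: list[tuple]) -> list[tuple]:
    """Zero the first row's differences of a segment."""
    if not rows:
        return rows
    f, r, c, tid, _, _ = rows[0]
    return [(f, r, c, tid, 0, 0)] + list(rows[1:])


def split_paragon(tbl: ParagonTable, threshold_paragon: int = 3) -> list[ParagonTable]:
    """Cut the paragon table into continuous segments.

    A cut is placed before every row whose step exceeds the threshold
    (max(|d_row|, |d_col|) > threshold_paragon), where the frame decreases,
    or where the frame repeats with a different position reported by a
    different target.  Each segment is re-based (first-row differences
    zeroed) and returned in time order.
    """
    if threshold_paragon < 1:
        raise ValueError("threshold_paragon must be >= 1")
    segments: list[ParagonTable] = []
    current: list[tuple] = []
    prev = None
    for row in tbl.rows:
        f, r, c, tid, d_row, d_col = row
        cut = False
        if prev is not None:
            pf, pr, pc, ptid = prev
            if max(abs(r - pr), abs(c - pc)) > threshold_paragon:
                cut = True
            elif f < pf:
                cut = True
            elif f == pf and (r, c) != (pr, pc) and tid != ptid:
                cut = True
        if cut and current:
            segments.append(ParagonTable(rows=_rebase(current),
                                         source_group=tbl.source_group))
            current = []
        current.append(row)
        prev = (f, r, c, tid)
    if current:
        segments.append(ParagonTable(rows=_rebase(current),
                                     source_group=tbl.source_group))
    # recompute in-segment differences so each segment is self-consistent
    fixed = []
    for seg in segments:
        rows = []
        p = None
        for f, r, c, tid, _, _ in seg.rows:
            if p is None:
                rows.append((f, r, c, tid, 0, 0))
            else:
                rows.append((f, r, c, tid, r - p[0], c - p[1]))
            p = (r, c)
        fixed.append(ParagonTable(rows=rows, source_group=seg.source_group))
    return fixed


def merge_segments(segments: list[ParagonTable], order: list[int],
                   threshold_paragon: int = 3) -> ParagonTable:
    """User-driven splice: concatenate segments in the given order.

    Validates that frames increase monotonically across each junction and
    that the junction step is <= threshold_paragon; raises ValueError
    otherwise.  Never called automatically.
    """
    if not order:
        raise ValueError("order must list at least one segment")
    chosen = [segments[i] for i in order]
    rows: list[tuple] = []
    for seg in chosen:
        if rows and seg.rows:
            pf, pr, pc = rows[-1][0], rows[-1][1], rows[-1][2]
            f, r, c = seg.rows[0][0], seg.rows[0][1], seg.rows[0][2]
            if f <= pf:
                raise ValueError(
                    f"junction frame {f} does not advance past {pf}")
            if max(abs(r - pr), abs(c - pc)) > threshold_paragon:
                raise ValueError(
                    f"junction step ({r - pr}, {c - pc}) exceeds "
                    f"threshold_paragon={threshold_paragon}")
        rows.extend(seg.rows)
    # rebuild differences over the merged table
    out = []
    p = None
    for f, r, c, tid, _, _ in rows:
        if p is None:
            out.append((f, r, c, tid, 0, 0))
        else:
            out.append((f, r, c, tid, r - p[0], c - p[1]))
        p = (r, c)
    return ParagonTable(rows=out, source_group=chosen[0].source_group)
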