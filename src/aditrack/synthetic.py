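"""Ground-truth scene simulation and rendering.

Emulates the two data regimes the tracker targets — point-like diffusing
emitters at low SNR and larger cell-like blobs doing persistent walks — plus
the pathological linking scenarios (loops, crossings, a missed detection at
a loop junction).  Every stage of the pipeline is testable against the exact
ground truth kept here.  All randomness flows from a single scene seed.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from aditrack.segmentation import DetectionStack
from aditrack.io_stack import ImageStack

__all__ = [
    "GroundTruthScene",
    "RenderParams",
    "MatchReport",
    "simulate_brownian",
    "simulate_persistent_walk",
    "simulate_loops_crossings",
    "render_scene",
    "ideal_detections",
    "match_detections",
    "write_truth",
]


@dataclass
class GroundTruthScene:
    """Exact particle tracks behind a simulated stack.

    ``positions[i, j]`` is the float (row, col) of particle i at frame j;
    ``visible[i, j]`` is False on detection dropouts.  Tracks are complete
    over frames 0..M-1.
    """

    positions: np.ndarray  # (n_particles, M, 2) float
    visible: np.ndarray  # (n_particles, M) bool
    height: int
    width: int
    pixel_size_um: float = 1.0
    frame_interval_s: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.float64)
        self.visible = np.asarray(self.visible, dtype=bool)
        if self.positions.ndim != 3 or self.positions.shape[2] != 2:
            raise ValueError("positions must have shape (n_particles, M, 2)")
        if self.visible.shape != self.positions.shape[:2]:
            raise ValueError("visible must have shape (n_particles, M)")
        if self.positions.size and (
                self.positions[..., 0].min() < 0 or self.positions[..., 1].min() < 0
                or self.positions[..., 0].max() > self.height - 1
                or self.positions[..., 1].max() > self.width - 1):
            raise ValueError("positions out of frame bounds")

    @property
    def n_particles(self) -> int:
        return self.positions.shape[0]

    @property
    def n_frames(self) -> int:
        return self.positions.shape[1]

    def particles(self) -> list[list[tuple[int, float, float, bool]]]:
        """List form: per particle, (frame, row, col, visible) tuples."""
        return [[(j, float(p[j, 0]), float(p[j, 1]), bool(v[j]))
                 for j in range(self.n_frames)]
                for p, v in zip(self.positions, self.visible)]

    def pixel_positions(self) -> np.ndarray:
        """Rounded integer pixel positions, shape (n_particles, M, 2)."""
        return np.rint(self.positions).astype(int)


@dataclass
class RenderParams:
    """Photometry of the rendered stack.

    Point-like targets use an isotropic Gaussian of ``spot_sigma_px``;
    cell-like targets a uniform disc of ``blob_radius_px`` (set exactly one).
    Noise is shot-like (Poisson at ``poisson_gain`` expected counts per unit
    intensity) plus Gaussian read noise.
    """

    spot_sigma_px: float | np.ndarray | None = 1.5
    blob_radius_px: float | np.ndarray | None = None
    amplitude: float | np.ndarray = 0.6
    background_level: float = 0.1
    background_gradient: float = 0.0  # peak-to-peak of a linear ramp
    poisson_gain: float = 0.0  # 0 disables shot noise
    read_noise_sigma: float = 0.0

    def __post_init__(self) -> None:
        if (self.spot_sigma_px is None) == (self.blob_radius_px is None):
            raise ValueError("set exactly one of spot_sigma_px / blob_radius_px")
        if np.min(self.amplitude) <= self.background_level:
            raise ValueError("amplitude must exceed background_level")
        if self.background_level < 0:
            raise ValueError("background_level must be >= 0")


def _reflect(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Reflect coordinates into [lo, hi] (keeps particle count fixed)."""
    span = hi - lo
    y = np.mod(x - lo, 2 * span)
    y = np.where(y > span, 2 * span - y, y)
    return y + lo


def _initial_positions(rng, n: int, height: int, width: int, margin: float,
                       min_separation: float) -> np.ndarray:
    """Uniform starts, optionally rejection-sampled to a minimum spacing."""
    pos = np.empty((n, 2))
    placed = 0
    attempts = 0
    while placed < n:
        cand = np.array([rng.uniform(margin, height - 1 - margin),
                         rng.uniform(margin, width - 1 - margin)])
        if min_separation > 0 and placed:
            d = np.abs(pos[:placed] - cand).max(axis=1)
            if d.min() < min_separation:
                attempts += 1
                if attempts > 20000:
                    raise ValueError("cannot place particles at requested separation")
                continue
        pos[placed] = cand
        placed += 1
    return pos


def simulate_brownian(n_particles: int, D: float, n_frames: int = 100,
                      height: int = 256, width: int = 256,
                      pixel_size_um: float = 1.0, frame_interval_s: float = 1.0,
                      dropout_prob: float = 0.0, seed: int = 0,
                      margin: float = 6.0, min_separation: float = 0.0) -> GroundTruthScene:
    """Free Brownian walkers: per-axis steps ~ N(0, 2*D*frame_interval).

    Positions reflect off a *margin*-inset boundary; each frame's position is
    visible with probability 1 - dropout_prob (frame 0 always visible so the
    seed set is well defined).
    """
    if D <= 0:
        raise ValueError("D must be positive")
    rng = np.random.default_rng(seed)
    step_px = np.sqrt(2.0 * D * frame_interval_s) / pixel_size_um
    pos0 = _initial_positions(rng, n_particles, height, width, margin, min_separation)
    steps = rng.normal(0.0, step_px, size=(n_particles, n_frames - 1, 2))
    raw = np.concatenate([pos0[:, None, :], pos0[:, None, :] + np.cumsum(steps, axis=1)], axis=1)
    positions = np.empty_like(raw)
    positions[..., 0] = _reflect(raw[..., 0], margin, height - 1 - margin)
    positions[..., 1] = _reflect(raw[..., 1], margin, width - 1 - margin)
    visible = rng.random((n_particles, n_frames)) >= dropout_prob
    visible[:, 0] = True
    return GroundTruthScene(positions=positions, visible=visible,
                            height=height, width=width,
                            pixel_size_um=pixel_size_um,
                            frame_interval_s=frame_interval_s, seed=seed)


def simulate_persistent_walk(n_particles: int, speed_px: float = 1.5,
                             turn_sigma: float = 0.4, n_frames: int = 60,
                             height: int = 256, width: int = 256,
                             pixel_size_um: float = 1.0, frame_interval_s: float = 1.0,
                             dropout_prob: float = 0.0, loop_prob: float = 0.02,
                             seed: int = 0, margin: float = 12.0,
                             min_separation: float = 0.0) -> GroundTruthScene:
    """Cell-like persistent random walk with occasional tight loops.

    Heading diffuses by ``turn_sigma`` rad/frame; with probability
    ``loop_prob`` per frame a particle enters a full turn executed over the
    following frames (constant extra curvature), producing loop-shaped tracks.
    """
    rng = np.random.default_rng(seed)
    pos = _initial_positions(rng, n_particles, height, width, margin, min_separation)
    heading = rng.uniform(0, 2 * np.pi, n_particles)
    loop_left = np.zeros(n_particles, dtype=int)
    positions = np.empty((n_particles, n_frames, 2))
    positions[:, 0] = pos
    loop_steps = 12
    for j in range(1, n_frames):
        entering = (rng.random(n_particles) < loop_prob) & (loop_left == 0)
        loop_left[entering] = loop_steps
        curvature = np.where(loop_left > 0, 2 * np.pi / loop_steps, 0.0)
        loop_left = np.maximum(loop_left - 1, 0)
        heading = heading + curvature + rng.normal(0, turn_sigma, n_particles) * (curvature == 0)
        pos = pos + speed_px * np.stack([np.sin(heading), np.cos(heading)], axis=1)
        pos[:, 0] = _reflect(pos[:, 0], margin, height - 1 - margin)
        pos[:, 1] = _reflect(pos[:, 1], margin, width - 1 - margin)
        positions[:, j] = pos
    visible = rng.random((n_particles, n_frames)) >= dropout_prob
    visible[:, 0] = True
    return GroundTruthScene(positions=positions, visible=visible,
                            height=height, width=width,
                            pixel_size_um=pixel_size_um,
                            frame_interval_s=frame_interval_s, seed=seed)


def simulate_loops_crossings(scenario: str, n_frames: int = 40,
                             height: int = 64, width: int = 64,
                             loop_radius: float = 7.0, step_px: float = 3.0,
                             seed: int = 0, pixel_size_um: float = 1.0,
                             frame_interval_s: float = 1.0) -> GroundTruthScene:
    """Deterministic pathological scenes for the linking/entanglement tests.

    ``loop``: one track that runs straight, executes a closed circular loop
    returning to the junction pixel, then exits.  ``loop_with_missed_junction``
    additionally hides the first in-loop position (the detection dropout that
    makes a single-start tracker detour past the loop).  ``crossing_pair``:
    two straight tracks intersecting mid-stack.
    """
    if scenario not in ("loop", "crossing_pair", "loop_with_missed_junction"):
        raise ValueError(f"unknown scenario {scenario!r}")
    if scenario == "crossing_pair":
        t_cross = n_frames // 2
        r_c, c_c = height // 2, width // 2
        # shrink the step if the straight tracks would leave the frame
        reach = max(t_cross, n_frames - 1 - t_cross)
        max_step = (min(height, width) // 2 - 2) / reach
        step = min(step_px, max_step)
        track_a = np.array([[r_c, c_c + step * (j - t_cross)] for j in range(n_frames)])
        track_b = np.array([[r_c + step * (j - t_cross), c_c] for j in range(n_frames)])
        positions = np.stack([track_a, track_b])
        visible = np.ones((2, n_frames), dtype=bool)
        return GroundTruthScene(positions=positions, visible=visible,
                                height=height, width=width,
                                pixel_size_um=pixel_size_um,
                                frame_interval_s=frame_interval_s, seed=seed)

    # loop geometry: straight approach -> closed circle back to the junction
    # A -> straight exit; chord per frame stays within the linking shell.
    n_loop = max(int(np.ceil(2 * np.pi * loop_radius / step_px)), 8)
    junction = np.array([height / 2.0, width / 4.0])
    n_approach = int(junction[1] // step_px)
    center = junction - np.array([loop_radius, 0.0])
    track = []
    for j in range(n_approach):
        track.append(junction - np.array([0.0, step_px * (n_approach - j)]))
    t_junction = len(track)
    track.append(junction.copy())
    # junction sits at angle 0 on the circle; one full revolution closes it
    for s in range(1, n_loop + 1):
        theta = 2 * np.pi * s / n_loop
        row = center[0] + loop_radius * np.cos(theta)
        col = center[1] + loop_radius * np.sin(theta)
        track.append(np.array([row, col]))
    t_closure = len(track) - 1  # back at the junction
    while len(track) < n_frames:
        nxt = track[-1] + np.array([0.0, step_px])  # exit rightward ...
        if nxt[1] > width - 2:
            nxt = track[-1] + np.array([step_px, 0.0])  # ... turning at borders
        if nxt[0] > height - 2:
            nxt = track[-1] + np.array([0.0, -step_px])
        track.append(nxt)
    positions = np.array(track[:n_frames])[None, :, :]
    visible = np.ones((1, n_frames), dtype=bool)
    if scenario == "loop_with_missed_junction":
        visible[0, t_junction + 1] = False  # first in-loop position missed
    scene = GroundTruthScene(positions=positions, visible=visible,
                             height=height, width=width,
                             pixel_size_um=pixel_size_um,
                             frame_interval_s=frame_interval_s, seed=seed)
    scene.t_junction = t_junction
    scene.t_closure = t_closure
    scene.loop_frames = list(range(t_junction + 1, t_closure + 1))
    return scene


def render_scene(scene: GroundTruthScene, rp: RenderParams | None = None) -> ImageStack:
    """Draw the scene: Gaussian spots or uniform discs at subpixel positions,
    plus graded background and shot/read noise, clipped to [0, 1]."""
    rp = rp or RenderParams()
    M, H, W = scene.n_frames, scene.height, scene.width
    rng = np.random.default_rng(np.random.SeedSequence([scene.seed, 7919]))
    amp = np.broadcast_to(np.asarray(rp.amplitude, dtype=float), (scene.n_particles,))
    ramp = np.zeros((H, W))
    if rp.background_gradient:
        ramp = rp.background_gradient * (np.arange(W) / max(W - 1, 1))[None, :] * np.ones((H, 1))
    frames = np.empty((M, H, W))
    if rp.spot_sigma_px is not None:
        sigma = np.broadcast_to(np.asarray(rp.spot_sigma_px, dtype=float),
                                (scene.n_particles,))
        half = np.ceil(4 * sigma).astype(int)
    else:
        radius = np.broadcast_to(np.asarray(rp.blob_radius_px, dtype=float),
                                 (scene.n_particles,))
        half = np.ceil(radius + 1).astype(int)
    for j in range(M):
        img = np.full((H, W), rp.background_level) + ramp
        for i in range(scene.n_particles):
            if not scene.visible[i, j]:
                continue
            r0, c0 = scene.positions[i, j]
            rlo, rhi = max(int(r0) - half[i], 0), min(int(r0) + half[i] + 2, H)
            clo, chi = max(int(c0) - half[i], 0), min(int(c0) + half[i] + 2, W)
            rr, cc = np.meshgrid(np.arange(rlo, rhi), np.arange(clo, chi), indexing="ij")
            if rp.spot_sigma_px is not None:
                prof = amp[i] * np.exp(-((rr - r0) ** 2 + (cc - c0) ** 2)
                                       / (2.0 * sigma[i] ** 2))
                img[rlo:rhi, clo:chi] += prof
            else:
                disc = (rr - r0) ** 2 + (cc - c0) ** 2 <= radius[i] ** 2
                img[rlo:rhi, clo:chi] = np.where(disc, rp.background_level + ramp[rlo:rhi, clo:chi] + amp[i],
                                                 img[rlo:rhi, clo:chi])
        if rp.poisson_gain > 0:
            img = rng.poisson(np.maximum(img, 0) * rp.poisson_gain) / rp.poisson_gain
        if rp.read_noise_sigma > 0:
            img = img + rng.normal(0, rp.read_noise_sigma, img.shape)
        frames[j] = np.clip(img, 0.0, 1.0)
    return ImageStack(frames, pixel_size_um=scene.pixel_size_um,
                      frame_interval_s=scene.frame_interval_s)


def ideal_detections(scene: GroundTruthScene) -> DetectionStack:
    """Noise-free single-pixel detection maps: each visible particle marks its
    rounded position.  Lets linking be tested independently of segmentation."""
    maps = np.zeros((scene.n_frames, scene.height, scene.width), dtype=bool)
    pix = scene.pixel_positions()
    for i in range(scene.n_particles):
        for j in range(scene.n_frames):
            if scene.visible[i, j]:
                maps[j, pix[i, j, 0], pix[i, j, 1]] = True
    return DetectionStack(maps=maps, border_margin=0)


@dataclass
class MatchReport:
    """Greedy one-to-one trajectory-to-truth matching summary."""

    recall: float
    n_truth: int
    n_matched: int
    assignments: list[tuple[int, int, float]]  # (particle, target_id, fraction)
    coverage: dict[int, float]  # particle -> matched-trajectory span / M


def match_detections(scene: GroundTruthScene, trajs, tol_px: float = 3.0,
                     min_frac: float = 0.5, ref_frame: int = 0) -> MatchReport:
    """Match trajectories to ground-truth tracks and compute recall.

    For each (trajectory, particle) pair the score is the fraction of the
    trajectory's samples lying within ``tol_px`` (Chebyshev) of the particle's
    true position at the same frame.  Pairs are assigned greedily one-to-one
    in decreasing score order; assignments below ``min_frac`` are rejected.
    Recall = matched particles / particles visible at ``ref_frame``
    (matching is id-agnostic).
    """
    if tol_px < 1:
        raise ValueError("tol_px must be >= 1")
    scores = []
    for traj in trajs.trajectories:
        samples = np.array(traj.samples)
        frames = samples[:, 0]
        pts = samples[:, 1:]
        true_pos = scene.positions[:, frames, :]  # (n_particles, len, 2)
        dist = np.abs(true_pos - pts[None, :, :]).max(axis=2)
        frac = (dist <= tol_px).mean(axis=1)
        for i in range(scene.n_particles):
            if frac[i] >= min_frac:
                scores.append((frac[i], traj.target_id, i))
    scores.sort(key=lambda s: (-s[0], s[1], s[2]))
    used_traj: set[int] = set()
    used_particle: set[int] = set()
    assignments = []
    coverage: dict[int, float] = {}
    M = scene.n_frames
    for frac, tid, pid in scores:
        if tid in used_traj or pid in used_particle:
            continue
        used_traj.add(tid)
        used_particle.add(pid)
        assignments.append((pid, tid, float(frac)))
        traj = trajs.get(tid)
        span = traj.samples[-1][0] - traj.samples[0][0] + 1
        coverage[pid] = span / M
    eligible = [i for i in range(scene.n_particles) if scene.visible[i, ref_frame]]
    n_truth = len(eligible)
    n_matched = sum(1 for i in eligible if i in used_particle)
    recall = n_matched / n_truth if n_truth else 0.0
    return MatchReport(recall=recall, n_truth=n_truth, n_matched=n_matched,
                       assignments=assignments, coverage=coverage)


def write_truth(scene: GroundTruthScene, path: str | os.PathLike) -> None:
    """Truth CSV: particle_id,frame,row,col,visible (float subpixel rows/cols)."""
    records = []
    for i in range(scene.n_particles):
        for j in range(scene.n_frames):
            records.append((i, j, scene.positions[i, j, 0],
                            scene.positions[i, j, 1], int(scene.visible[i, j])))
    pd.DataFrame(records, columns=["particle_id", "frame", "row", "col", "visible"]
                 ).to_csv(path, index=False)
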