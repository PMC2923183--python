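import numpy as np
import pytest

from aditrack.linking import Trajectory, TrajectorySet


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_trajectory_set(rng, n_traj=5, n_samples=8, size=64):
    """Random (but valid) trajectory set: strictly increasing frames."""
    trajs = []
    for tid in range(n_traj):
        frames = np.sort(rng.choice(np.arange(50), size=n_samples, replace=False))
        rows = rng.integers(0, size, n_samples)
        cols = rng.integers(0, size, n_samples)
        samples = [(int(f), int(r), int(c)) for f, r, c in zip(frames, rows, cols)]
        trajs.append(Trajectory(target_id=tid, samples=samples))
    return TrajectorySet(trajectories=trajs, pixel_size_um=0.5, frame_interval_s=2.0)


@pytest.fixture
def random_trajectories(rng):
    return make_trajectory_set(rng)
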