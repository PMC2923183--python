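import numpy as np
import pytest

from aditrack.io_stack import ImageStack
from aditrack.segmentation import (
    THRESHOLD_STEP,
    DetectionStack,
    SegmentationParams,
    apply_threshold,
    find_threshold,
    mean_max_reduce,
    minimum_filter,
    segment_stack,
)


# ---------------------------------------------------------------- oracles


def brute_min_filter(frame, m):
    """Independent sliding-window minimum with zeroed border."""
    h, w = frame.shape
    out = np.zeros_like(frame)
    for r in range(m, h - m):
        for c in range(m, w - m):
            out[r, c] = frame[max(r - m, 0):r + m + 1, max(c - m, 0):c + m + 1].min()
    return out


def brute_mean(frame, m):
    h, w = frame.shape
    out = np.zeros_like(frame, dtype=float)
    size = (2 * m + 1) ** 2
    padded = np.zeros((h + 2 * m, w + 2 * m))
    padded[m:m + h, m:m + w] = frame
    for r in range(h):
        for c in range(w):
            out[r, c] = padded[r:r + 2 * m + 1, c:c + 2 * m + 1].sum() / size
    return out


def brute_local_max_marks(frame, m):
    """Brute-force mean filter + windowed-max marking + lexicographic dedup."""
    s = np.round(brute_mean(frame, m), 9)
    h, w = s.shape
    marked = np.zeros((h, w), dtype=bool)
    for r in range(h):
        for c in range(w):
            if s[r, c] <= 0:
                continue
            win = s[max(r - m, 0):r + m + 1, max(c - m, 0):c + m + 1]
            if s[r, c] >= win.max():
                marked[r, c] = True
    # dedup 8-connected equal-value plateaus, keep lexicographic min
    from skimage import measure

    labels, n = measure.label(marked, connectivity=2, return_num=True)
    out = np.zeros_like(marked)
    for comp in range(1, n + 1):
        rows, cols = np.nonzero(labels == comp)
        k = np.lexsort((cols, rows))[0]
        out[rows[k], cols[k]] = True
    return out


# ---------------------------------------------------------------- minimum


class TestMinimumFilter:
    def test_constant_frame_invariant(self):
        frame = np.full((9, 9), 0.4)
        out = minimum_filter(frame, 1)
        assert np.all(out[1:-1, 1:-1] == 0.4)
        assert np.all(out[0] == 0) and np.all(out[:, 0] == 0)

    def test_isolated_spike_suppressed(self):
        frame = np.zeros((9, 9))
        frame[4, 4] = 1.0
        assert np.all(minimum_filter(frame, 1) == 0.0)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(100):
            frame = rng.random((9, 9))
            np.testing.assert_allclose(minimum_filter(frame, 1),
                                       brute_min_filter(frame, 1))

    def test_no_interior_error(self):
        with pytest.raises(ValueError):
            minimum_filter(np.zeros((5, 5)), 3)


# ---------------------------------------------------------------- threshold


class TestApplyThreshold:
    def test_zero_threshold_identity(self, rng):
        frame = rng.random((8, 8))
        np.testing.assert_array_equal(apply_threshold(frame, 0.0), frame)

    def test_above_max_all_zero(self, rng):
        frame = rng.random((8, 8)) * 0.5
        assert np.all(apply_threshold(frame, 0.9) == 0.0)

    def test_elementwise_oracle(self, rng):
        for _ in range(100):
            frame = rng.random((6, 6))
            out = apply_threshold(frame, 0.5)
            expected = np.array([[v if v >= 0.5 else 0.0 for v in row]
                                 for row in frame])
            np.testing.assert_array_equal(out, expected)

    def test_idempotent(self, rng):
        frame = rng.random((8, 8))
        once = apply_threshold(frame, 0.37)
        np.testing.assert_array_equal(apply_threshold(once, 0.37), once)

    def test_invalid_threshold(self):
        with pytest.raises(ValueError):
            apply_threshold(np.zeros((4, 4)), 1.0)


def _plateau_frame(amplitudes, size=24, bg=0.1):
    """Disjoint 3x3 plateaus at given amplitudes on constant background."""
    frame = np.full((size, size), bg)
    anchors = [(3, 3), (3, 15), (15, 3), (15, 15), (9, 9)]
    for (r, c), a in zip(anchors, amplitudes):
        frame[r:r + 3, c:c + 3] = a
    return frame


class TestFindThreshold:
    def test_three_plateaus(self):
        frame = _plateau_frame([0.9, 0.9, 0.9])
        T = find_threshold(frame, (0, 0, 24, 24), expected_count=3)
        assert 0.1 < T <= 0.9
        from skimage import measure

        n = measure.label(apply_threshold(frame, T) > 0, connectivity=2,
                          return_num=True)[1]
        assert n == 3

    def test_infeasible_count_errors(self):
        frame = _plateau_frame([0.9, 0.9, 0.9])
        with pytest.raises(ValueError, match="achievable"):
            find_threshold(frame, (0, 0, 24, 24), expected_count=50)

    def test_matches_exhaustive_scan(self, rng):
        from skimage import measure

        for _ in range(25):
            amps = rng.uniform(0.3, 0.95, 5)
            frame = _plateau_frame(amps, bg=rng.uniform(0.02, 0.15))
            want = int(rng.integers(1, 6))
            roi = (0, 0, 24, 24)

            def count(T):
                mask = (frame >= T) & (frame > 0)
                labels, n = measure.label(mask, connectivity=2, return_num=True)
                if n == 0:
                    return 0
                areas = np.bincount(labels.ravel())[1:]
                return int((areas >= 3).sum())

            grid = np.arange(0.0, 1.0, THRESHOLD_STEP)
            matches = [T for T in grid if count(float(T)) == want]
            if matches:
                assert find_threshold(frame, roi, want) == pytest.approx(matches[0])
            else:
                with pytest.raises(ValueError):
                    find_threshold(frame, roi, want)


# ---------------------------------------------------------------- mean/max


class TestMeanMaxReduce:
    def test_all_zero(self):
        assert mean_max_reduce(np.zeros((9, 9)), 1).sum() == 0

    def test_single_block_center(self):
        frame = np.zeros((9, 9))
        frame[3:6, 3:6] = 1.0
        marks = mean_max_reduce(frame, 1)
        assert marks.sum() == 1
        # the 3x3 mean field has its unique maximum at the block center
        assert marks[4, 4]

    def test_two_blocks_two_marks(self):
        frame = np.zeros((20, 20))
        frame[2:5, 2:5] = 1.0
        frame[12:15, 12:15] = 0.8
        marks = mean_max_reduce(frame, 1)
        assert marks.sum() == 2
        assert marks[3, 3] and marks[13, 13]

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(100):
            frame = np.zeros((12, 12))
            # sparse random blobs
            for _ in range(rng.integers(1, 4)):
                r, c = rng.integers(1, 9, 2)
                frame[r:r + 3, c:c + 3] = rng.uniform(0.3, 1.0)
            m = int(rng.integers(1, 3))
            np.testing.assert_array_equal(mean_max_reduce(frame, m),
                                          brute_local_max_marks(frame, m))

    def test_single_pixel_guarantee(self, rng):
        """Marked pixels are farther than m_b apart unless values differ."""
        for seed in range(20):
            r = np.random.default_rng(seed)
            frame = np.where(r.random((16, 16)) > 0.7, r.random((16, 16)), 0.0)
            m = 2
            marks = np.argwhere(mean_max_reduce(frame, m))
            import scipy.ndimage as ndi

            smooth = np.round(np.where(
                ndi.maximum_filter(frame > 0, size=2 * m + 1, mode="constant"),
                ndi.uniform_filter(frame, size=2 * m + 1, mode="constant"), 0.0), 9)
            for i in range(len(marks)):
                for j in range(i + 1, len(marks)):
                    d = np.abs(marks[i] - marks[j]).max()
                    if d <= m:
                        assert smooth[tuple(marks[i])] != smooth[tuple(marks[j])]


# ---------------------------------------------------------------- stack


class TestSegmentStack:
    def test_all_zero_stack(self):
        stack = ImageStack(np.zeros((3, 16, 16)))
        det = segment_stack(stack, SegmentationParams(threshold=0.5))
        assert det.maps.sum() == 0
        assert det.border_margin == 2

    def test_moving_spot_one_mark_per_frame(self):
        frames = np.zeros((5, 24, 24))
        for j in range(5):
            frames[j, 8:11, 4 + 2 * j:7 + 2 * j] = 1.0
        det = segment_stack(ImageStack(frames), SegmentationParams(threshold=0.5))
        marks = []
        for j in range(5):
            pos = det.positions(j)
            assert len(pos) == 1
            marks.append(pos[0])
        # marks trace the spot: one per frame, moving 2 px right per frame,
        # with a constant sub-window offset from the block center (9, 5+2j)
        # (the eroded block is an exact plateau; ties break lexicographically)
        offsets = {(r - 9, c - (5 + 2 * j)) for j, (r, c) in enumerate(marks)}
        assert len(offsets) == 1
        (dr, dc), = offsets
        assert abs(dr) <= 1 and abs(dc) <= 1

    def test_auto_requires_roi(self):
        stack = ImageStack(np.zeros((2, 16, 16)))
        with pytest.raises(ValueError, match="auto"):
            segment_stack(stack, SegmentationParams(threshold="auto"))

    def test_border_margin_respected(self):
        frames = np.zeros((2, 16, 16))
        frames[:, 1:3, 1:3] = 1.0  # target hugging the border
        det = segment_stack(ImageStack(frames), SegmentationParams(threshold=0.5))
        margin = det.border_margin
        assert det.maps[:, :margin, :].sum() == 0
        assert det.maps[:, :, :margin].sum() == 0

    def test_component_count_monotone_once_separated(self):
        """Above per-blob separation, raising T never increases the count."""
        from skimage import measure

        frame = _plateau_frame([0.5, 0.7, 0.9])
        counts = []
        for T in np.arange(0.2, 1.0, 0.05):
            mask = apply_threshold(frame, float(T)) > 0
            counts.append(measure.label(mask, connectivity=2, return_num=True)[1])
        assert all(b <= a for a, b in zip(counts, counts[1:]))

    def test_detectionstack_positions_sorted(self):
        maps = np.zeros((1, 8, 8), dtype=bool)
        maps[0, 5, 2] = maps[0, 1, 6] = True
        det = DetectionStack(maps=maps)
        assert det.positions(0) == [(1, 6), (5, 2)]
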