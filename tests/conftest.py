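import numpy as np
import pytest

from luregait import (
    DisplayRecording,
    EventTrack,
    MovementEvent,
    Side,
)


def make_track(side: Side, starts, duration: int = 10) -> EventTrack:
    return EventTrack(
        side, [MovementEvent(side, s, s + duration) for s in sorted(starts)]
    )


def make_recording(left_starts, right_starts, duration=10, fps=120.0,
                   rid="rec", **meta) -> DisplayRecording:
    all_frames = list(left_starts) + list(right_starts) or [0]
    start = 0
    length = max(all_frames) + duration + 1
    return DisplayRecording(
        recording_id=rid,
        left=make_track(Side.LEFT, left_starts, duration),
        right=make_track(Side.RIGHT, right_starts, duration),
        fps=fps,
        analysis_start_frame=start,
        analysis_length_frames=max(length, 1),
        **meta,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240524)


def random_tracks(rng, max_events=12, max_frame=300, duration=5):
    """Random strictly-increasing-start tracks for matcher property tests."""
    n_l = int(rng.integers(0, max_events + 1))
    n_r = int(rng.integers(0, max_events + 1))
    ls = sorted(rng.choice(max_frame, size=n_l, replace=False)) if n_l else []
    rs = sorted(rng.choice(max_frame, size=n_r, replace=False)) if n_r else []
    return (make_track(Side.LEFT, ls, duration),
            make_track(Side.RIGHT, rs, duration))


def max_matching_oracle(left_starts, right_starts, tol):
    """Exhaustive maximum one-to-one matching with |Δstart| ≤ tol.

    Bitmask recursion over right events; independent of the greedy path.
    """
    from functools import lru_cache

    L, R = list(left_starts), list(right_starts)

    @lru_cache(maxsize=None)
    def best(i, used):
        if i == len(L):
            return 0
        score = best(i + 1, used)
        for j, r in enumerate(R):
            if not used & (1 << j) and abs(L[i] - r) <= tol:
                score = max(score, 1 + best(i + 1, used | (1 << j)))
        return score

    return best(0, 0)
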