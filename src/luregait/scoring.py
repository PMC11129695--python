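"""Synchrony classification, per-recording display summaries, gait diagrams.

Left and right flap movements are classified as synchronized when their start
frames differ by at most a tolerance (default 4 frames, i.e. 33 ms at
120 fps).  The proportion synchronized is

    n_sync / (n_sync + n_left_only + n_right_only),

the number of matched bilateral movements over the number of distinct
movements.  Matching is one-to-one and greedy in chronological order: each
left movement takes the earliest still-unmatched right movement within the
tolerance.  For this interval structure the greedy pairing attains the
maximum possible number of matches (a standard exchange argument: yielding
the earliest feasible partner can never exclude a later left event that the
alternative partner could not also serve).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .events import DisplayRecording, EventTrack, Side, frames_to_seconds

logger = logging.getLogger("luregait")

#: Movements synchronized when start frames differ by at most this (frames).
DEFAULT_TOLERANCE_FRAMES = 4


@dataclass
class SyncScore:
    """Output of the bilateral synchrony classifier for one recording."""

    pairs: list[tuple[int, int]]
    n_sync: int
    n_left_only: int
    n_right_only: int
    proportion_sync: float | None
    tolerance_frames: int = DEFAULT_TOLERANCE_FRAMES

    @property
    def n_movements(self) -> int:
        """Distinct movements: matched pairs count once."""
        return self.n_sync + self.n_left_only + self.n_right_only


def classify_synchrony(
    left: EventTrack,
    right: EventTrack,
    tolerance_frames: int = DEFAULT_TOLERANCE_FRAMES,
) -> SyncScore:
    """Match left and right movements whose starts differ by ≤ tolerance.

    Returns a :class:`SyncScore`; ``proportion_sync`` is ``None`` when both
    tracks are empty (no display, as opposed to a never-synchronized one).
    """
    if left.side == right.side:
        raise ValueError("classify_synchrony needs one left and one right track")
    if left.side == Side.RIGHT:
        left, right = right, left
    if tolerance_frames < 0:
        raise ValueError("tolerance_frames must be non-negative")

    right_starts = right.start_frames
    matched_right: set[int] = set()
    pairs: list[tuple[int, int]] = []
    for i, ls in enumerate(left.start_frames):
        for j, rs in enumerate(right_starts):
            if j in matched_right:
                continue
            if rs > ls + tolerance_frames:
                break  # right starts are increasing; no later candidate fits
            if abs(rs - ls) <= tolerance_frames:
                matched_right.add(j)
                pairs.append((i, j))
                break

    n_sync = len(pairs)
    n_left_only = len(left) - n_sync
    n_right_only = len(right) - n_sync
    total = n_sync + n_left_only + n_right_only
    if total == 0:
        logger.warning("both tracks empty: proportion synchronized undefined")
        proportion = None
    else:
        proportion = n_sync / total
    return SyncScore(
        pairs=pairs, n_sync=n_sync, n_left_only=n_left_only,
        n_right_only=n_right_only, proportion_sync=proportion,
        tolerance_frames=tolerance_frames,
    )


def movement_intervals(track: EventTrack, fps: float) -> np.ndarray:
    """Start-to-start times between consecutive movements on one side (s).

    Empty when the track has fewer than two movements.
    """
    starts = np.asarray(track.start_frames, dtype=float)
    if starts.size < 2:
        return np.empty(0)
    return np.array([frames_to_seconds(d, fps) for d in np.diff(starts)])


def movement_durations(track: EventTrack, fps: float) -> np.ndarray:
    """Start-to-end time of each movement on one side (s)."""
    return np.array(
        [frames_to_seconds(ev.end_frame - ev.start_frame, fps) for ev in track.events]
    )


@dataclass
class DisplaySummary:
    """Per-recording interval/duration/synchrony summary statistics.

    Interval and duration statistics are in seconds, per side.  SD fields are
    ``None`` (absent, not zero) when a side has fewer than two intervals.
    """

    recording_id: str
    mean_interval_left: float | None
    mean_interval_right: float | None
    sd_interval_left: float | None
    sd_interval_right: float | None
    mean_duration_left: float | None
    mean_duration_right: float | None
    n_movements_left: int
    n_movements_right: int
    proportion_sync: float | None
    water_temp: float | None = None
    tolerance_frames: int = DEFAULT_TOLERANCE_FRAMES

    def metric(self, name: str, side: str = "left") -> float | None:
        """Look up a named summary metric (``side`` is left|right|pooled)."""
        if name == "proportion_sync":
            return self.proportion_sync
        per_side = {
            "mean_interval": (self.mean_interval_left, self.mean_interval_right),
            "interval_sd": (self.sd_interval_left, self.sd_interval_right),
            "mean_duration": (self.mean_duration_left, self.mean_duration_right),
        }
        if name not in per_side:
            raise KeyError(f"unknown metric {name!r}")
        lv, rv = per_side[name]
        if side == "left":
            return lv
        if side == "right":
            return rv
        if side == "pooled":
            vals = [v for v in (lv, rv) if v is not None]
            return float(np.mean(vals)) if vals else None
        raise ValueError(f"side must be left|right|pooled, got {side!r}")


def _mean_sd(values: np.ndarray) -> tuple[float | None, float | None]:
    if values.size == 0:
        return None, None
    mean = float(np.mean(values))
    sd = float(np.std(values, ddof=1)) if values.size >= 2 else None
    return mean, sd


def summarize_display(
    recording: DisplayRecording,
    tolerance_frames: int = DEFAULT_TOLERANCE_FRAMES,
) -> DisplaySummary:
    """Compute the per-individual summary used in the group comparisons."""
    score = classify_synchrony(recording.left, recording.right, tolerance_frames)
    out: dict = {"recording_id": recording.recording_id,
                 "proportion_sync": score.proportion_sync,
                 "water_temp": recording.water_temp,
                 "tolerance_frames": tolerance_frames}
    for side, label in ((recording.left, "left"), (recording.right, "right")):
        ivals = movement_intervals(side, recording.fps)
        durs = movement_durations(side, recording.fps)
        mean_i, sd_i = _mean_sd(ivals)
        if ivals.size < 2:
            logger.info(
                "recording %s %s side: %d interval(s); SD not defined",
                recording.recording_id, label, ivals.size,
            )
        out[f"mean_interval_{label}"] = mean_i
        out[f"sd_interval_{label}"] = sd_i
        out[f"mean_duration_{label}"] = float(np.mean(durs)) if durs.size else None
        out[f"n_movements_{label}"] = len(side)
    return DisplaySummary(**out)


# ---------------------------------------------------------------------------
# Gait diagrams
# ---------------------------------------------------------------------------

@dataclass
class GaitDiagram:
    """Plottable segments of one recording's display timeline.

    Synchronized movements sit on the center line (span = union of the paired
    left/right events); left-only movements above, right-only below.  Segment
    times are in seconds from the start of the analysis window.
    """

    recording_id: str
    center_segments: list[tuple[float, float]] = field(default_factory=list)
    upper_segments: list[tuple[float, float]] = field(default_factory=list)
    lower_segments: list[tuple[float, float]] = field(default_factory=list)
    fps: float = 120.0
    window_seconds: float = 0.0

    @property
    def n_segments(self) -> int:
        return (len(self.center_segments) + len(self.upper_segments)
                + len(self.lower_segments))


def gait_diagram(
    recording: DisplayRecording,
    tolerance_frames: int = DEFAULT_TOLERANCE_FRAMES,
) -> GaitDiagram:
    """Build the gait-diagram geometry for one recording."""
    score = classify_synchrony(recording.left, recording.right, tolerance_frames)
    t0 = recording.analysis_start_frame
    fps = recording.fps

    def span(start: int, end: int) -> tuple[float, float]:
        return (frames_to_seconds(start - t0, fps), frames_to_seconds(end - t0, fps))

    center, upper, lower = [], [], []
    matched_left = {i for i, _ in score.pairs}
    matched_right = {j for _, j in score.pairs}
    for i, j in score.pairs:
        le, re = recording.left.events[i], recording.right.events[j]
        center.append(span(min(le.start_frame, re.start_frame),
                           max(le.end_frame, re.end_frame)))
    for i, ev in enumerate(recording.left.events):
        if i not in matched_left:
            upper.append(span(ev.start_frame, ev.end_frame))
    for j, ev in enumerate(recording.right.events):
        if j not in matched_right:
            lower.append(span(ev.start_frame, ev.end_frame))
    return GaitDiagram(
        recording_id=recording.recording_id,
        center_segments=center, upper_segments=upper, lower_segments=lower,
        fps=fps,
        window_seconds=frames_to_seconds(recording.analysis_length_frames, fps),
    )


def render_gait_diagram(
    diagram: GaitDiagram,
    out_dir: str | Path,
    formats: tuple[str, ...] = ("svg", "png"),
) -> list[Path]:
    """Render a gait diagram to ``<recording_id>_gait.<ext>`` files.

    The x axis is labeled both in seconds and in frame number at the
    recording's frame rate.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(10, 2.2))
    lw = 6
    for (a, b) in diagram.center_segments:
        ax.hlines(0.0, a, b, colors="red", linewidth=lw)
    for (a, b) in diagram.upper_segments:
        ax.hlines(0.6, a, b, colors="black", linewidth=lw)
    for (a, b) in diagram.lower_segments:
        ax.hlines(-0.6, a, b, colors="black", linewidth=lw)
    ax.set_ylim(-1.2, 1.2)
    xmax = diagram.window_seconds or max(
        (b for _, b in diagram.center_segments + diagram.upper_segments
         + diagram.lower_segments), default=1.0)
    ax.set_xlim(0, xmax)
    ax.set_yticks([-0.6, 0.0, 0.6])
    ax.set_yticklabels(["right only", "synchronized", "left only"])
    ax.set_xlabel("time (s)")
    sec = ax.secondary_xaxis(
        "top",
        functions=(lambda s: s * diagram.fps, lambda f: f / diagram.fps),
    )
    sec.set_xlabel(f"frame ({diagram.fps:g} fps)")
    ax.set_title(diagram.recording_id)
    fig.tight_layout()

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for ext in formats:
        p = out_dir / f"{diagram.recording_id}_gait.{ext}"
        fig.savefig(p)
        paths.append(p)
    plt.close(fig)
    return paths
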