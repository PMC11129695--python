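"""Domain types and delimited-text I/O for frame-annotated lure-movement data.

A display recording is a pair of per-side event tracks scored from video:
each movement is the closed frame interval [start_frame, end_frame], where
the start is the first frame with visible mantle contraction and the end is
the frame where the lure returns to rest.  Frames are 0-based.  Recordings
carry the acquisition metadata (species, lure morph, frames per second,
analysis window, water temperature, site, date) needed by the downstream
scoring and group-comparison stages.
"""

from __future__ import annotations

import datetime as _dt
import enum
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

logger = logging.getLogger("luregait")

#: Default acquisition rate of the field recordings (frames per second).
DEFAULT_FPS = 120.0
#: Default first analyzed frame (skips camera-setup disturbance).
DEFAULT_ANALYSIS_START = 5000
#: Default length of the analyzed window, in frames (2.8 min at 120 fps).
DEFAULT_ANALYSIS_LENGTH = 20000

EVENT_COLUMNS = ["recording_id", "side", "start_frame", "end_frame"]
METADATA_COLUMNS = [
    "recording_id", "species", "morph", "site", "date",
    "water_temp_c", "fps", "analysis_start_frame", "analysis_length_frames",
]


class Side(str, enum.Enum):
    LEFT = "left"
    RIGHT = "right"


class Morph(str, enum.Enum):
    """Primary lure phenotype, or ``none`` for monomorphic congeners."""

    DARTER = "darter"
    LEECH = "leech"
    NONE = "none"


class EventValidationError(ValueError):
    """Raised when movement-event data violates a structural invariant."""


@dataclass(frozen=True)
class MovementEvent:
    """One scored lure movement: a closed frame interval on one side."""

    side: Side
    start_frame: int
    end_frame: int

    def __post_init__(self) -> None:
        if self.start_frame < 0 or self.end_frame < 0:
            raise EventValidationError(
                f"negative frame in event ({self.start_frame}, {self.end_frame})"
            )
        if self.end_frame < self.start_frame:
            raise EventValidationError(
                f"end_frame {self.end_frame} precedes start_frame {self.start_frame}"
            )

    @property
    def n_frames(self) -> int:
        """Number of frames the movement occupies (closed interval)."""
        return self.end_frame - self.start_frame + 1


@dataclass
class EventTrack:
    """Ordered movements of one mantle-lure flap (one side)."""

    side: Side
    events: list[MovementEvent] = field(default_factory=list)

    def __post_init__(self) -> None:
        for ev in self.events:
            if ev.side != self.side:
                raise EventValidationError(
                    f"event on side {ev.side.value!r} in a {self.side.value!r} track"
                )
        starts = [ev.start_frame for ev in self.events]
        if any(b <= a for a, b in zip(starts, starts[1:])):
            raise EventValidationError(
                f"{self.side.value} track start frames are not strictly increasing"
            )
        # Overlapping movement bodies are physically odd but not forbidden.
        n_overlap = sum(
            nxt.start_frame <= prev.end_frame
            for prev, nxt in zip(self.events, self.events[1:])
        )
        if n_overlap:
            logger.warning(
                "%s track: %d movement(s) start before the previous movement ends",
                self.side.value, n_overlap,
            )

    def __len__(self) -> int:
        return len(self.events)

    @property
    def start_frames(self) -> list[int]:
        return [ev.start_frame for ev in self.events]


@dataclass
class DisplayRecording:
    """One individual's scored display: left + right tracks plus metadata."""

    recording_id: str
    left: EventTrack
    right: EventTrack
    species: str = ""
    morph: Morph = Morph.NONE
    site: str = ""
    date: _dt.date | None = None
    water_temp: float | None = None
    fps: float = DEFAULT_FPS
    analysis_start_frame: int = DEFAULT_ANALYSIS_START
    analysis_length_frames: int = DEFAULT_ANALYSIS_LENGTH

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise EventValidationError(f"fps must be positive, got {self.fps}")
        if self.analysis_length_frames <= 0:
            raise EventValidationError(
                f"analysis_length_frames must be positive, got {self.analysis_length_frames}"
            )
        if self.left.side != Side.LEFT or self.right.side != Side.RIGHT:
            raise EventValidationError("left/right tracks assigned to wrong slots")
        lo = self.analysis_start_frame
        hi = lo + self.analysis_length_frames
        for track in (self.left, self.right):
            for ev in track.events:
                if not (lo <= ev.start_frame and ev.end_frame < hi):
                    raise EventValidationError(
                        f"recording {self.recording_id!r}: event "
                        f"({ev.side.value}, {ev.start_frame}, {ev.end_frame}) "
                        f"outside analysis window [{lo}, {hi})"
                    )

    def track(self, side: Side) -> EventTrack:
        return self.left if side == Side.LEFT else self.right


def frames_to_seconds(frames: float, fps: float = DEFAULT_FPS) -> float:
    """Convert a frame count to seconds at the given frame rate."""
    if fps <= 0:
        raise ValueError(f"fps must be positive, got {fps}")
    return frames / fps


def _parse_metadata_row(row: pd.Series) -> dict:
    out: dict = {}
    out["species"] = str(row.get("species", "") or "")
    morph = row.get("morph", "none")
    out["morph"] = Morph(str(morph).strip().lower()) if pd.notna(morph) else Morph.NONE
    out["site"] = str(row.get("site", "") or "")
    date = row.get("date")
    out["date"] = (
        _dt.date.fromisoformat(str(date)) if pd.notna(date) and str(date) else None
    )
    temp = row.get("water_temp_c")
    out["water_temp"] = float(temp) if pd.notna(temp) else None
    out["fps"] = float(row.get("fps", DEFAULT_FPS) or DEFAULT_FPS)
    start = row.get("analysis_start_frame")
    out["analysis_start_frame"] = (
        int(start) if pd.notna(start) else DEFAULT_ANALYSIS_START
    )
    length = row.get("analysis_length_frames")
    out["analysis_length_frames"] = (
        int(length) if pd.notna(length) else DEFAULT_ANALYSIS_LENGTH
    )
    return out


def read_events(
    path: str | Path,
    metadata: str | Path | None = None,
    sep: str = ",",
) -> list[DisplayRecording]:
    """Read an events table (and optional metadata table) into recordings.

    The events file has columns ``recording_id, side, start_frame, end_frame``;
    the metadata file is keyed by ``recording_id``.  Events are sorted by start
    frame within each side.  Malformed rows, events outside the analysis
    window, and duplicate (recording_id, side, start_frame) triples raise
    :class:`EventValidationError` naming the offending row or event.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise EventValidationError(f"{path}: missing columns {missing}")
    if df.empty:
        return []

    meta_by_id: dict[str, dict] = {}
    if metadata is not None:
        mdf = pd.read_csv(metadata, sep=sep)
        if "recording_id" not in mdf.columns:
            raise EventValidationError(f"{metadata}: missing column 'recording_id'")
        for _, row in mdf.iterrows():
            meta_by_id[str(row["recording_id"])] = _parse_metadata_row(row)

    parsed: list[tuple[str, Side, int, int]] = []
    for idx, row in df.iterrows():
        line_no = int(idx) + 2  # 1-based, after the header line
        rid = row["recording_id"].strip()
        try:
            side = Side(row["side"].strip().lower())
            start = int(row["start_frame"])
            end = int(row["end_frame"])
        except (ValueError, KeyError) as exc:
            raise EventValidationError(f"{path} line {line_no}: {exc}") from exc
        if not rid:
            raise EventValidationError(f"{path} line {line_no}: empty recording_id")
        if end < start:
            raise EventValidationError(
                f"{path} line {line_no}: end_frame {end} < start_frame {start}"
            )
        parsed.append((rid, side, start, end))

    seen: set[tuple[str, Side, int]] = set()
    for rid, side, start, _ in parsed:
        key = (rid, side, start)
        if key in seen:
            raise EventValidationError(
                f"{path}: duplicate event ({rid!r}, {side.value}, start {start})"
            )
        seen.add(key)

    recordings: list[DisplayRecording] = []
    for rid in dict.fromkeys(r for r, *_ in parsed):  # preserve file order
        tracks = {}
        for side in Side:
            rows = sorted(
                (p for p in parsed if p[0] == rid and p[1] == side),
                key=lambda p: p[2],
            )
            tracks[side] = EventTrack(
                side=side,
                events=[MovementEvent(side, s, e) for _, _, s, e in rows],
            )
        meta = meta_by_id.get(rid, {})
        recordings.append(
            DisplayRecording(
                recording_id=rid, left=tracks[Side.LEFT], right=tracks[Side.RIGHT],
                **meta,
            )
        )
    return recordings


def write_events(
    recordings: Iterable[DisplayRecording],
    path: str | Path,
    metadata_path: str | Path | None = None,
    sep: str = ",",
) -> None:
    """Write recordings back to the events (and optionally metadata) schema."""
    rows = []
    meta_rows = []
    for rec in recordings:
        for side in Side:
            for ev in rec.track(side).events:
                rows.append(
                    {"recording_id": rec.recording_id, "side": side.value,
                     "start_frame": ev.start_frame, "end_frame": ev.end_frame}
                )
        meta_rows.append(
            {"recording_id": rec.recording_id, "species": rec.species,
             "morph": rec.morph.value, "site": rec.site,
             "date": rec.date.isoformat() if rec.date else "",
             "water_temp_c": "" if rec.water_temp is None else rec.water_temp,
             "fps": rec.fps, "analysis_start_frame": rec.analysis_start_frame,
             "analysis_length_frames": rec.analysis_length_frames}
        )
    pd.DataFrame(rows, columns=EVENT_COLUMNS).to_csv(path, sep=sep, index=False)
    if metadata_path is not None:
        pd.DataFrame(meta_rows, columns=METADATA_COLUMNS).to_csv(
            metadata_path, sep=sep, index=False
        )


def events_dataframe(recordings: Sequence[DisplayRecording]) -> pd.DataFrame:
    """Flatten recordings to a tidy events table (one row per movement)."""
    rows = [
        {"recording_id": rec.recording_id, "side": side.value,
         "start_frame": ev.start_frame, "end_frame": ev.end_frame}
        for rec in recordings for side in Side for ev in rec.track(side).events
    ]
    return pd.DataFrame(rows, columns=EVENT_COLUMNS)
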