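"""Stimulus schedules, 1-fps frame sampling and labeling, and per-session DISC.

A recording session follows a block schedule: a blank (neutral) screen, a
happy image-viewing block, a blank, a sad block, and a final blank.  Frames
are sampled at 1 frame per second and labeled with the block active at their
timestamp.  Within each happy/sad block every frame is compared (via DISC)
against the block's first frame — the baseline of maximum temporal proximity,
which minimizes misalignment from slow head drift.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .core import (
    LABELS,
    DiscError,
    DisplacementField,
    GrayFrame,
    GridSpec,
    compute_field,
)

logger = logging.getLogger(__name__)


class ScheduleError(ValueError):
    """The recording does not cover the stimulus schedule."""


@dataclass(frozen=True)
class StimulusSchedule:
    """Ordered blocks of (label, duration in seconds).

    The default mirrors a slideshow of ten 10-s happy images and ten 10-s sad
    images with 10-s blank (neutral) screens at the start, between the sets,
    and at the end; at 1 fps it yields 100 happy, 100 sad, and 30 neutral
    frames.
    """

    blocks: tuple[tuple[str, float], ...] = (
        ("neutral", 10.0),
        ("happy", 100.0),
        ("neutral", 10.0),
        ("sad", 100.0),
        ("neutral", 10.0),
    )

    def __post_init__(self) -> None:
        for label, dur in self.blocks:
            if label not in LABELS:
                raise ValueError(f"unknown label {label!r}")
            if dur <= 0:
                raise ValueError("block durations must be positive")

    @property
    def total_duration(self) -> float:
        return float(sum(d for _, d in self.blocks))

    def block_bounds(self) -> list[tuple[str, float, float]]:
        """(label, start, end) per block; intervals are half-open [start, end)."""
        out = []
        t = 0.0
        for label, dur in self.blocks:
            out.append((label, t, t + dur))
            t += dur
        return out

    def block_at(self, time: float) -> int:
        """Index of the block whose [start, end) interval contains ``time``."""
        for i, (_, start, end) in enumerate(self.block_bounds()):
            if start <= time < end:
                return i
        raise ScheduleError(f"time {time} s lies outside the schedule")

    def frame_counts(self, rate: float = 1.0) -> dict[str, int]:
        """Number of frames per label when sampled at ``rate`` frames/s."""
        counts = {label: 0 for label in LABELS}
        n = int(np.ceil(self.total_duration * rate))
        bounds = self.block_bounds()
        for k in range(n):
            t = k / rate
            for label, start, end in bounds:
                if start <= t < end:
                    counts[label] += 1
                    break
        return counts


def default_schedule() -> StimulusSchedule:
    return StimulusSchedule()


@dataclass
class Session:
    """One participant's labeled frame sequence and its displacement fields.

    ``block_ids[i]`` is the schedule block of frame i; ``baselines`` maps a
    block id to the session position of its baseline frame; ``fields`` maps a
    frame position to its DisplacementField against that baseline.
    """

    participant_id: str
    frames: list[GrayFrame]
    block_ids: list[int]
    schedule: StimulusSchedule
    baselines: dict[int, int] = field(default_factory=dict)
    fields: dict[int, DisplacementField] = field(default_factory=dict)
    failures: dict[int, str] = field(default_factory=dict)

    @property
    def labels(self) -> list[str]:
        return [f.label for f in self.frames]

    def label_counts(self) -> dict[str, int]:
        counts = {label: 0 for label in LABELS}
        for f in self.frames:
            counts[f.label] += 1
        return counts

    def block_positions(self, block_id: int) -> list[int]:
        return [i for i, b in enumerate(self.block_ids) if b == block_id]


def sample_and_label(
    frames: Sequence[GrayFrame],
    schedule: StimulusSchedule,
    source_fps: float = 1.0,
    rate: float = 1.0,
    participant_id: str = "",
) -> Session:
    """Sample frames at ``rate`` frames/s and tag each with its block label.

    Frame i of the source is taken to occur at time ``i / source_fps`` from
    schedule start; sample k (at time ``k / rate``) maps to the first source
    frame at or after that time.  Raises :class:`ScheduleError`, listing the
    uncovered blocks, if the recording is shorter than the schedule.
    """
    if not frames:
        raise ScheduleError("no frames supplied")
    timestamps = np.arange(len(frames)) / source_fps
    recording_end = timestamps[-1] + 1.0 / source_fps
    bounds = schedule.block_bounds()
    if recording_end < schedule.total_duration:
        missing = [
            f"{label}@{start:g}s" for label, start, _ in bounds if start >= recording_end
        ] or ["final block tail"]
        raise ScheduleError(
            f"recording ({recording_end:g} s) shorter than schedule "
            f"({schedule.total_duration:g} s); uncovered: {', '.join(missing)}"
        )
    n_samples = int(np.ceil(schedule.total_duration * rate))
    sampled: list[GrayFrame] = []
    block_ids: list[int] = []
    for k in range(n_samples):
        t = k / rate
        src = int(np.searchsorted(timestamps, t, side="left"))
        src = min(src, len(frames) - 1)
        b = schedule.block_at(t)
        label = bounds[b][0]
        sampled.append(frames[src].with_label(label, frame_index=k))
        block_ids.append(b)
    return Session(
        participant_id=participant_id or (frames[0].participant_id or ""),
        frames=sampled,
        block_ids=block_ids,
        schedule=schedule,
    )


def select_baselines(session: Session) -> dict[int, int]:
    """Baseline frame position per block: the block's first frame.

    Happy and sad blocks are referenced to their own first frame; all neutral
    blocks are referenced to the first frame of the *first* neutral block so
    neutral frames also yield feature fields.  Raises on empty blocks.
    """
    bounds = session.schedule.block_bounds()
    first_neutral: int | None = None
    baselines: dict[int, int] = {}
    for b, (label, _, _) in enumerate(bounds):
        positions = session.block_positions(b)
        if not positions:
            raise ScheduleError(f"block {b} ({label}) has no frames")
        if label == "neutral":
            if first_neutral is None:
                first_neutral = positions[0]
            baselines[b] = first_neutral
        else:
            baselines[b] = positions[0]
    session.baselines = baselines
    return baselines


def compute_session_fields(
    session: Session,
    grid: GridSpec,
    subpixel: bool = True,
) -> Session:
    """Populate ``session.fields`` with one field per frame vs its baseline.

    Baseline frames are compared against themselves and yield the zero field.
    Per-frame DISC failures are recorded in ``session.failures`` without
    aborting the rest of the session.
    """
    if not session.baselines:
        select_baselines(session)
    for i, frame in enumerate(session.frames):
        base_pos = session.baselines[session.block_ids[i]]
        ref = session.frames[base_pos]
        try:
            session.fields[i] = compute_field(ref, frame, grid, subpixel=subpixel)
        except DiscError as exc:  # pragma: no cover - defensive per-frame guard
            session.failures[i] = str(exc)
            logger.warning("frame %d of %s failed: %s", i, session.participant_id, exc)
    return session
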