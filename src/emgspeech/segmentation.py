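"""Selection of 1-second fluent and disfluent analysis windows.

Fluent windows must not touch any annotated disfluency (optionally with a
guard margin) and consecutive windows must be separated by a minimum gap,
so adjacent samples are never selected.  The default strategy packs windows
greedily left to right (earliest feasible start), which for fixed-length
windows is also a maximum packing; a seeded random strategy is available.

Disfluent windows are placed one per annotated event, centred on the event
midpoint (events longer than the window start at the event onset), clamped
to the recording extent so the event always intersects the window.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .signal_io import EMGRecording, EventAnnotation

__all__ = [
    "WINDOW_S",
    "Segment",
    "SegmentationPolicy",
    "extract_fluent_segments",
    "extract_disfluent_segments",
    "count_eligible_fluent",
]

log = logging.getLogger(__name__)

#: Analysis window length in seconds (fixed by the sampling protocol).
WINDOW_S = 1.0

_EPS = 1e-9


@dataclass(frozen=True)
class Segment:
    """A 1-s analysis window within a recording."""

    recording: EMGRecording
    start_s: float
    label: str  # "fluent" | "disfluent"
    dtype: str | None = None
    context: str | None = None
    duration_s: float = WINDOW_S

    def __post_init__(self) -> None:
        if self.start_s < -_EPS:
            raise ValueError("segment start must be non-negative")
        if self.start_s + self.duration_s > self.recording.duration_s + _EPS:
            raise ValueError("segment extends past the end of the recording")
        if self.label not in ("fluent", "disfluent"):
            raise ValueError(f"label must be fluent or disfluent, got {self.label!r}")
        if self.label == "disfluent" and self.dtype is None:
            raise ValueError("disfluent segments must carry a disfluency type")

    @property
    def start_index(self) -> int:
        return int(math.floor(self.start_s * self.recording.fs))

    @property
    def n_samples(self) -> int:
        return int(round(self.recording.fs * self.duration_s))

    def slice(self, values: np.ndarray | None = None) -> np.ndarray:
        """Sample window from ``values`` (default: the recording itself)."""
        if values is None:
            values = self.recording.values
        i0 = min(self.start_index, len(values) - self.n_samples)
        i0 = max(i0, 0)
        return values[i0:i0 + self.n_samples]


@dataclass(frozen=True)
class SegmentationPolicy:
    """Window-selection rules.

    n_fluent_target : fluent windows requested per participant (default 40)
    min_gap_s : minimum gap between the end of one fluent window and the
        start of the next (default 0.5 s)
    guard_s : exclusion margin around disfluency intervals for fluent windows
    strategy : "greedy" (earliest feasible start) or "random" (seeded)
    """

    n_fluent_target: int = 40
    min_gap_s: float = 0.5
    guard_s: float = 0.0
    seed: int = 0
    strategy: str = "greedy"

    def __post_init__(self) -> None:
        if self.n_fluent_target < 0:
            raise ValueError("n_fluent_target must be >= 0")
        if self.min_gap_s < 0 or self.guard_s < 0:
            raise ValueError("min_gap_s and guard_s must be >= 0")
        if self.strategy not in ("greedy", "random"):
            raise ValueError("strategy must be 'greedy' or 'random'")


def _expanded_intervals(annotations: Sequence[EventAnnotation], guard_s: float
                        ) -> list[tuple[float, float]]:
    return [(max(0.0, a.onset_s - guard_s), a.offset_s + guard_s) for a in annotations]


def _blocking_end(t: float, intervals: Sequence[tuple[float, float]]) -> float | None:
    """Latest end among intervals overlapping the window [t, t+1)."""
    end = None
    for a, b in intervals:
        if a < t + WINDOW_S - _EPS and t < b - _EPS:
            end = b if end is None else max(end, b)
    return end


def _greedy_starts(duration_s: float, intervals: Sequence[tuple[float, float]],
                   min_gap_s: float, limit: int | None = None) -> list[float]:
    starts: list[float] = []
    t = 0.0
    while t + WINDOW_S <= duration_s + _EPS and (limit is None or len(starts) < limit):
        end = _blocking_end(t, intervals)
        if end is None:
            starts.append(t)
            t += WINDOW_S + min_gap_s
        else:
            t = end  # next feasible start cannot precede the blocking interval's end
    return starts


def _random_starts(duration_s: float, intervals: Sequence[tuple[float, float]],
                   policy: SegmentationPolicy, grid_s: float = 0.01) -> list[float]:
    rng = np.random.default_rng(policy.seed)
    n_grid = int(math.floor((duration_s - WINDOW_S) / grid_s + _EPS)) + 1
    if n_grid <= 0:
        return []
    candidates = rng.permutation(n_grid) * grid_s
    chosen: list[float] = []
    for t in candidates:
        if len(chosen) >= policy.n_fluent_target:
            break
        if _blocking_end(t, intervals) is not None:
            continue
        if any(t < c + WINDOW_S + policy.min_gap_s - _EPS
               and c < t + WINDOW_S + policy.min_gap_s - _EPS for c in chosen):
            continue
        chosen.append(float(t))
    return sorted(chosen)


def _context_at(t_mid: float, context_blocks: Sequence[tuple[float, float, str]] | None
                ) -> str | None:
    if not context_blocks:
        return None
    for a, b, ctx in context_blocks:
        if a - _EPS <= t_mid < b - _EPS:
            return ctx
    a, b, ctx = context_blocks[-1]
    if abs(t_mid - b) <= _EPS:
        return ctx
    return None


def extract_fluent_segments(
    recording: EMGRecording,
    annotations: Sequence[EventAnnotation],
    policy: SegmentationPolicy = SegmentationPolicy(),
    context_blocks: Sequence[tuple[float, float, str]] | None = None,
) -> list[Segment]:
    """Fluent 1-s windows avoiding all disfluency intervals.

    Returns up to ``policy.n_fluent_target`` windows; if fewer are eligible a
    warning is logged and all eligible windows are returned.
    """
    intervals = _expanded_intervals(annotations, policy.guard_s)
    if policy.strategy == "random":
        starts = _random_starts(recording.duration_s, intervals, policy)
    else:
        starts = _greedy_starts(recording.duration_s, intervals, policy.min_gap_s,
                                limit=policy.n_fluent_target)
    if len(starts) < policy.n_fluent_target:
        log.warning(
            "participant %s: only %d of %d requested fluent windows are eligible",
            recording.participant_id, len(starts), policy.n_fluent_target,
        )
    return [
        Segment(recording, s, "fluent",
                context=_context_at(s + WINDOW_S / 2, context_blocks))
        for s in starts
    ]


def extract_disfluent_segments(
    recording: EMGRecording,
    annotations: Sequence[EventAnnotation],
    policy: SegmentationPolicy = SegmentationPolicy(),
) -> list[Segment]:
    """One 1-s window per annotated disfluency, intersecting the event."""
    duration = recording.duration_s
    segments: list[Segment] = []
    for ann in sorted(annotations, key=lambda a: (a.onset_s, a.offset_s)):
        if ann.onset_s >= duration - _EPS or ann.offset_s <= _EPS:
            log.warning("annotation (%g, %g) lies outside the recording; skipped",
                        ann.onset_s, ann.offset_s)
            continue
        if ann.offset_s - ann.onset_s >= WINDOW_S:
            start = ann.onset_s
        else:
            start = (ann.onset_s + ann.offset_s) / 2.0 - WINDOW_S / 2.0
        start = min(max(start, 0.0), duration - WINDOW_S)
        segments.append(Segment(recording, start, "disfluent",
                                dtype=ann.dtype, context=ann.context))
    return segments


def count_eligible_fluent(
    recording_duration_s: float,
    annotations: Sequence[EventAnnotation],
    policy: SegmentationPolicy = SegmentationPolicy(),
) -> int:
    """Size of the maximal greedy packing of eligible fluent windows."""
    if recording_duration_s < 0:
        raise ValueError("duration must be >= 0")
    intervals = _expanded_intervals(annotations, policy.guard_s)
    return len(_greedy_starts(recording_duration_s, intervals, policy.min_gap_s))
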