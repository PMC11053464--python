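"""Reading and writing recordings, annotations and study manifests.

All on-disk formats are plain text so that a study is diff-able and
inspectable:

* signal files: one amplitude (mV) per line, ``#`` comment lines and an
  optional non-numeric header line allowed;
* annotations: CSV with header ``onset_s,offset_s,type,context``;
* manifest: JSON listing, per participant, the group label and one signal
  file per muscle plus the annotation file.

Times are seconds from recording start; annotation intervals are half-open
``[onset, offset)``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MUSCLES",
    "GROUPS",
    "DISFLUENCY_TYPES",
    "CONTEXTS",
    "EMGRecording",
    "EventAnnotation",
    "StudyManifest",
    "read_recording",
    "write_recording",
    "read_annotations",
    "write_annotations",
    "read_signal",
    "write_signal",
]

#: The five recorded muscles: depressor anguli oris, orbicularis oris,
#: masseter, sternocleidomastoid, zygomaticus major.
MUSCLES = ("DAO", "OO", "M", "S", "ZM")
GROUPS = ("A", "B")
DISFLUENCY_TYPES = ("repetition", "prolongation", "block")
CONTEXTS = ("personal_data", "reading", "call", "exposition")


@dataclass
class EMGRecording:
    """One muscle channel for one participant (amplitudes in mV)."""

    participant_id: str
    group: str
    muscle: str
    fs: float
    values: np.ndarray
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if self.values.ndim != 1 or self.values.size < 1:
            raise ValueError("values must be a non-empty 1-D array")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("recording contains non-finite samples")
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")
        if self.muscle not in MUSCLES:
            raise ValueError(f"muscle must be one of {MUSCLES}, got {self.muscle!r}")

    @property
    def duration_s(self) -> float:
        return self.values.size / self.fs

    def with_values(self, values: np.ndarray) -> "EMGRecording":
        return replace(self, values=np.asarray(values, dtype=float))


@dataclass(frozen=True)
class EventAnnotation:
    """A disfluency interval ``[onset_s, offset_s)`` with type and context."""

    onset_s: float
    offset_s: float
    dtype: str
    context: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.onset_s < self.offset_s:
            raise ValueError(
                f"require 0 <= onset < offset, got ({self.onset_s}, {self.offset_s})"
            )
        if self.dtype not in DISFLUENCY_TYPES:
            raise ValueError(f"type must be one of {DISFLUENCY_TYPES}, got {self.dtype!r}")
        if self.context not in CONTEXTS:
            raise ValueError(f"context must be one of {CONTEXTS}, got {self.context!r}")


# ---------------------------------------------------------------------------
# signal files


def read_signal(path: str | Path) -> np.ndarray:
    """Read a one-column delimited signal file into a float array.

    ``#`` lines are comments; a single leading non-numeric line is treated as
    a header.  Non-finite or non-numeric data lines raise with the line
    number named.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"signal file not found: {path}")
    values: list[float] = []
    first_data_line = True
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            try:
                v = float(line)
            except ValueError:
                if first_data_line:
                    first_data_line = False  # optional header
                    continue
                raise ValueError(f"{path}: non-numeric value on line {lineno}: {line!r}")
            first_data_line = False
            if not math.isfinite(v):
                raise ValueError(f"{path}: non-finite value on line {lineno}: {line!r}")
            values.append(v)
    if not values:
        raise ValueError(f"{path}: no samples found")
    return np.asarray(values, dtype=float)


def write_signal(values: np.ndarray, path: str | Path, *, overwrite: bool = False,
                 header: Sequence[str] = ()) -> None:
    """Write a float array as one mV value per line (12 significant digits)."""
    path = Path(path)
    if path.exists() and not overwrite:
        raise FileExistsError(f"refusing to overwrite {path} (pass overwrite=True)")
    path.parent.mkdir(parents=True, exist_ok=True)
    arr = np.asarray(values, dtype=float)
    with open(path, "w") as fh:
        for line in header:
            fh.write(f"# {line}\n")
        np.savetxt(fh, arr, fmt="%.12e")


def read_recording(
    path: str | Path,
    *,
    participant_id: str,
    group: str,
    muscle: str,
    fs: float,
    t0: float = 0.0,
) -> EMGRecording:
    """Read a signal file and wrap it with its identity metadata."""
    values = read_signal(path)
    return EMGRecording(participant_id, group, muscle, fs, values, t0)


def write_recording(recording: EMGRecording, path: str | Path, *, overwrite: bool = False) -> None:
    header = (
        f"participant={recording.participant_id} group={recording.group} "
        f"muscle={recording.muscle} fs_hz={recording.fs:g} t0_s={recording.t0:g} unit=mV",
    )
    write_signal(recording.values, path, overwrite=overwrite, header=header)


# ---------------------------------------------------------------------------
# annotations

_ANNOT_COLUMNS = ["onset_s", "offset_s", "type", "context"]


def read_annotations(path: str | Path) -> list[EventAnnotation]:
    """Read a disfluency-annotation CSV, returning events sorted by onset."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"annotation file not found: {path}")
    if path.stat().st_size == 0:
        return []
    df = pd.read_csv(path)
    missing = [c for c in _ANNOT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing annotation columns {missing}")
    if df.empty:
        return []
    events = []
    for row_number, row in enumerate(df.itertuples(index=False), start=2):
        try:
            events.append(
                EventAnnotation(float(row.onset_s), float(row.offset_s),
                                str(row.type), str(row.context))
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}: invalid annotation on row {row_number}: {exc}") from exc
    return sorted(events, key=lambda e: (e.onset_s, e.offset_s))


def write_annotations(events: Sequence[EventAnnotation], path: str | Path,
                      *, overwrite: bool = False) -> None:
    path = Path(path)
    if path.exists() and not overwrite:
        raise FileExistsError(f"refusing to overwrite {path} (pass overwrite=True)")
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(
        [(e.onset_s, e.offset_s, e.dtype, e.context) for e in events],
        columns=_ANNOT_COLUMNS,
    )
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# study manifest


@dataclass
class StudyManifest:
    """Index of a study on disk: who was recorded, where each file lives.

    ``context_blocks`` lists the session phases as ``[start_s, end_s, context]``
    triples shared by all participants (one common time base; the five muscle
    sensors record simultaneously).
    """

    fs: float
    participants: list[dict] = field(default_factory=list)
    context_blocks: list[list] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        payload = {
            "fs": self.fs,
            "context_blocks": self.context_blocks,
            "participants": self.participants,
        }
        path.write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "StudyManifest":
        data = json.loads(Path(path).read_text())
        return cls(
            fs=float(data["fs"]),
            participants=list(data["participants"]),
            context_blocks=[list(b) for b in data.get("context_blocks", [])],
        )

    def validate(self, base_dir: str | Path) -> None:
        """Check invariants: unique existing paths, valid groups/muscles."""
        base = Path(base_dir)
        seen: set[str] = set()
        if self.fs <= 0:
            raise ValueError("manifest fs must be positive")
        for entry in self.participants:
            pid = entry.get("participant_id")
            group = entry.get("group")
            if group not in GROUPS:
                raise ValueError(f"participant {pid}: group must be one of {GROUPS}")
            signals: Mapping[str, str] = entry.get("signals", {})
            for muscle, rel in signals.items():
                if muscle not in MUSCLES:
                    raise ValueError(f"participant {pid}: unknown muscle {muscle!r}")
                if rel in seen:
                    raise ValueError(f"duplicate path in manifest: {rel}")
                seen.add(rel)
                if not (base / rel).exists():
                    raise FileNotFoundError(f"participant {pid}: missing signal file {rel}")
            ann = entry.get("annotations")
            if ann is None:
                raise ValueError(f"participant {pid}: no annotation file listed")
            if ann in seen:
                raise ValueError(f"duplicate path in manifest: {ann}")
            seen.add(ann)
            if not (base / ann).exists():
                raise FileNotFoundError(f"participant {pid}: missing annotation file {ann}")
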