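"""Reading, writing, and annotating CASAS-style sensor event logs.

The plain-text dialect is whitespace separated::

    2010-11-04 05:40:51 M004 ON Bed_to_Toilet begin

with the trailing activity/marker pair optional.  Activity names never
contain whitespace (use underscores).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path
from typing import Iterator, Sequence

ON_VALUES = frozenset({"ON", "OPEN"})
OFF_VALUES = frozenset({"OFF", "CLOSE"})
ALLOWED_VALUES = ON_VALUES | OFF_VALUES
MARKERS = ("begin", "end")
TIME_FORMAT = "%Y-%m-%d %H:%M:%S"

_SENSOR_RE = re.compile(r"^([A-Za-z]+)0*([0-9]+)$")


@dataclass(frozen=True)
class Annotation:
    """Activity marker attached to a sensor event."""

    activity: str
    marker: str  # "begin" or "end"

    def __post_init__(self) -> None:
        if not self.activity:
            raise ValueError("annotation requires a non-empty activity name")
        if self.marker not in MARKERS:
            raise ValueError(f"annotation marker must be one of {MARKERS}, got {self.marker!r}")


@dataclass(frozen=True)
class SensorEvent:
    """A single timestamped sensor reading (second resolution)."""

    timestamp: datetime
    sensor_id: str
    value: str
    annotation: Annotation | None = None

    def __post_init__(self) -> None:
        if not self.sensor_id:
            raise ValueError("sensor_id must be non-empty")
        if self.value not in ALLOWED_VALUES:
            raise ValueError(f"value must be one of {sorted(ALLOWED_VALUES)}, got {self.value!r}")

    @property
    def is_on(self) -> bool:
        return self.value in ON_VALUES


@dataclass
class EventLog:
    """An ordered sequence of sensor events with non-decreasing timestamps."""

    events: list[SensorEvent] = field(default_factory=list)

    def __post_init__(self) -> None:
        for a, b in zip(self.events, self.events[1:]):
            if b.timestamp < a.timestamp:
                raise ValueError("EventLog timestamps must be non-decreasing")

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self) -> Iterator[SensorEvent]:
        return iter(self.events)

    def __getitem__(self, idx):
        return self.events[idx]

    def __eq__(self, other) -> bool:
        return isinstance(other, EventLog) and self.events == other.events

    @property
    def start(self) -> datetime:
        return self.events[0].timestamp

    @property
    def end(self) -> datetime:
        return self.events[-1].timestamp


@dataclass(frozen=True)
class ActivityInstance:
    """One matched begin/end annotation pair and the events it spans."""

    activity: str
    start: datetime
    end: datetime
    event_indices: range

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError("instance end precedes start")


class SensorRegistry:
    """Ordered set of sensor ids with a stable, 0-based id<->index mapping.

    Lookups tolerate zero-padding differences, so ``M3`` and ``M003``
    resolve to the same slot.
    """

    def __init__(self, sensor_ids: Sequence[str]):
        ids = list(sensor_ids)
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sensor ids in registry")
        self.sensor_ids: tuple[str, ...] = tuple(ids)
        self._index: dict[str, int] = {s: i for i, s in enumerate(ids)}
        self._norm_index: dict[tuple[str, int], int] = {}
        for i, s in enumerate(ids):
            key = self._norm_key(s)
            if key is not None:
                if key in self._norm_index:
                    raise ValueError(f"sensor ids {ids[self._norm_index[key]]!r} and {s!r} collide")
                self._norm_index[key] = i

    @staticmethod
    def _norm_key(sensor_id: str) -> tuple[str, int] | None:
        m = _SENSOR_RE.match(sensor_id)
        if m is None:
            return None
        return (m.group(1).upper(), int(m.group(2)))

    def __len__(self) -> int:
        return len(self.sensor_ids)

    def __contains__(self, sensor_id: str) -> bool:
        try:
            self.index(sensor_id)
        except KeyError:
            return False
        return True

    def index(self, sensor_id: str) -> int:
        """Return the 0-based index of *sensor_id* (padding-insensitive)."""
        if sensor_id in self._index:
            return self._index[sensor_id]
        key = self._norm_key(sensor_id)
        if key is not None and key in self._norm_index:
            return self._norm_index[key]
        raise KeyError(f"unknown sensor id {sensor_id!r}")

    def name(self, index: int) -> str:
        return self.sensor_ids[index]


def default_registry() -> SensorRegistry:
    """The 34-sensor registry (31 motion + 3 door) used throughout.

    Motion sensors come first so that e.g. M003 sits at 1-based position 3.
    """
    ids = [f"M{i:03d}" for i in range(1, 32)] + [f"D{i:03d}" for i in range(1, 4)]
    return SensorRegistry(ids)


def _parse_line(line: str, lineno: int) -> SensorEvent:
    tokens = line.split()
    if len(tokens) not in (4, 6):
        raise ValueError(f"line {lineno}: expected 4 or 6 whitespace-separated fields, got {len(tokens)}")
    try:
        ts = datetime.fromisoformat(tokens[0] + " " + tokens[1]).replace(microsecond=0)
    except ValueError as exc:
        raise ValueError(f"line {lineno}: bad timestamp {tokens[0]} {tokens[1]}: {exc}") from None
    annotation = None
    if len(tokens) == 6:
        if tokens[5] not in MARKERS:
            raise ValueError(f"line {lineno}: annotation marker must be begin|end, got {tokens[5]!r}")
        annotation = Annotation(tokens[4], tokens[5])
    try:
        return SensorEvent(ts, tokens[2], tokens[3], annotation)
    except ValueError as exc:
        raise ValueError(f"line {lineno}: {exc}") from None


def read_casas_log(path: str | Path, strict: bool = False) -> EventLog:
    """Parse a CASAS plain-text log.

    Out-of-order timestamps are stably sorted with a warning; pass
    ``strict=True`` to raise instead.
    """
    events: list[SensorEvent] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            events.append(_parse_line(line, lineno))
    out_of_order = any(b.timestamp < a.timestamp for a, b in zip(events, events[1:]))
    if out_of_order:
        if strict:
            raise ValueError(f"{path}: timestamps out of order")
        warnings.warn(f"{path}: out-of-order timestamps; applying stable sort", stacklevel=2)
        events.sort(key=lambda e: e.timestamp)  # sort() is stable
    return EventLog(events)


def write_casas_log(log: EventLog, path: str | Path) -> None:
    """Write *log* in the CASAS plain-text dialect (re-readable verbatim)."""
    with open(path, "w", encoding="utf-8") as fh:
        for ev in log:
            line = f"{ev.timestamp:{TIME_FORMAT}} {ev.sensor_id} {ev.value}"
            if ev.annotation is not None:
                line += f" {ev.annotation.activity} {ev.annotation.marker}"
            fh.write(line + "\n")


def annotate_activities(log: EventLog) -> list[ActivityInstance]:
    """Pair begin/end markers into activity instances, ordered by start.

    Markers must be well nested per activity name; orphans raise.
    """
    open_stacks: dict[str, list[int]] = {}
    instances: list[ActivityInstance] = []
    for i, ev in enumerate(log):
        ann = ev.annotation
        if ann is None:
            continue
        if ann.marker == "begin":
            open_stacks.setdefault(ann.activity, []).append(i)
        else:
            stack = open_stacks.get(ann.activity, [])
            if not stack:
                raise ValueError(f"orphan end marker for {ann.activity!r} at event {i} ({ev.timestamp})")
            start_idx = stack.pop()
            instances.append(
                ActivityInstance(
                    activity=ann.activity,
                    start=log[start_idx].timestamp,
                    end=ev.timestamp,
                    event_indices=range(start_idx, i + 1),
                )
            )
    orphans = [(name, idx) for name, stack in open_stacks.items() for idx in stack]
    if orphans:
        name, idx = orphans[0]
        raise ValueError(f"orphan begin marker for {name!r} at event {idx} ({log[idx].timestamp})")
    instances.sort(key=lambda inst: (inst.start, inst.event_indices.start))
    return instances


def event_labels(log: EventLog, instances: list[ActivityInstance] | None = None) -> list[str | None]:
    """Per-event activity label from the innermost enclosing instance."""
    if instances is None:
        instances = annotate_activities(log)
    labels: list[str | None] = [None] * len(log)
    # Later (inner) instances overwrite outer ones; sort by span start then width.
    for inst in sorted(instances, key=lambda x: (x.event_indices.start, -len(x.event_indices))):
        for i in inst.event_indices:
            labels[i] = inst.activity
    return labels
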