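"""Ground-truth anomaly injection into annotated event logs.

Two generators: whole activity instances copied into abnormal contexts
(e.g. eating in the middle of a sleeping span), and characteristic-sensor
repetition inside target activity instances.  Both keep the original
events as a subsequence of the output and return per-insertion records.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from pathlib import Path

import numpy as np

from .event_io import ActivityInstance, EventLog, SensorEvent, annotate_activities

KIND_ACTIVITY = "activity"
KIND_SUBACTIVITY = "subactivity"

#: activities inserted into ordinary daytime spans (frequency anomalies)
DEFAULT_DAYTIME_INSERTS = (
    "meal_preparation", "eating", "work", "washing_dishes", "leaving_home", "entering_home",
)
#: activities inserted into sleeping spans (sleep-disorder anomalies)
DEFAULT_SLEEP_INSERTS = ("relaxing", "eating", "bed_to_toilet", "respirating")

#: activity -> characteristic sensor repeated by the sub-activity generator
DEFAULT_SENSOR_MAP = {
    "work": "M026",
    "eating": "M014",
    "meal_preparation": "M018",
    "bed_to_toilet": "M004",
}


@dataclass
class AnomalyRecord:
    """One injected anomaly and where it landed in the output log."""

    kind: str  # "activity" | "subactivity"
    start: datetime
    end: datetime
    activity: str | None = None  # inserted activity (activity kind)
    sensor_id: str | None = None  # repeated sensor (subactivity kind)
    inserted_indices: list[int] = field(default_factory=list)  # indices into the output log
    source: str | None = None  # human-readable reference to the donor/modified instance

    def __post_init__(self) -> None:
        if self.kind not in (KIND_ACTIVITY, KIND_SUBACTIVITY):
            raise ValueError(f"unknown anomaly kind {self.kind!r}")
        if self.kind == KIND_ACTIVITY and self.activity is None:
            raise ValueError("activity-kind record requires an activity name")
        if self.kind == KIND_SUBACTIVITY and self.sensor_id is None:
            raise ValueError("subactivity-kind record requires a sensor id")


@dataclass
class ContextRule:
    """Where copies of ``insert_activity`` may be dropped.

    ``host_activities=None`` admits any instance whose activity differs
    from the inserted one and is not sleeping (a generic daytime host).
    """

    insert_activity: str
    host_activities: tuple[str, ...] | None = None

    def admits(self, host: ActivityInstance) -> bool:
        if self.host_activities is None:
            return host.activity != self.insert_activity and host.activity != "sleeping"
        return host.activity in self.host_activities


def default_context_rules(
    insert_activities: tuple[str, ...] | None = None,
) -> list[ContextRule]:
    rules: list[ContextRule] = []
    for name in insert_activities if insert_activities is not None else DEFAULT_DAYTIME_INSERTS:
        if insert_activities is None or name in DEFAULT_DAYTIME_INSERTS:
            rules.append(ContextRule(name, None))
    for name in DEFAULT_SLEEP_INSERTS:
        if insert_activities is None or name in insert_activities:
            rules.append(ContextRule(name, ("sleeping",)))
    if insert_activities is not None:
        covered = {r.insert_activity for r in rules}
        for name in insert_activities:
            if name not in covered:
                rules.append(ContextRule(name, None))
    return rules


def _merge_inserted(
    log: EventLog,
    insertions: list[tuple[list[SensorEvent], AnomalyRecord]],
) -> tuple[EventLog, list[AnomalyRecord]]:
    """Stable-merge inserted blocks into the log and resolve final indices.

    Originals sort ahead of inserted events at equal timestamps, so the
    input log is always a subsequence of the output.
    """
    tagged: list[tuple[datetime, int, int, SensorEvent]] = []
    for pos, ev in enumerate(log):
        tagged.append((ev.timestamp, 0, pos, ev))
    for ins_id, (block, _) in enumerate(insertions, start=1):
        for pos, ev in enumerate(block):
            tagged.append((ev.timestamp, ins_id, pos, ev))
    tagged.sort(key=lambda item: (item[0], item[1] != 0))
    events = [item[3] for item in tagged]
    records = []
    for ins_id, (_, record) in enumerate(insertions, start=1):
        record.inserted_indices = [i for i, item in enumerate(tagged) if item[1] == ins_id]
        records.append(record)
    return EventLog(events), records


def inject_activity_anomalies(
    log: EventLog,
    insert_activities: tuple[str, ...] | None = None,
    contexts: list[ContextRule] | None = None,
    n: int = 1,
    seed: int = 0,
) -> tuple[EventLog, list[AnomalyRecord]]:
    """Copy *n* donor activity instances into context-sanctioned abnormal spots.

    Each insertion consumes one host instance: the donor block is rigidly
    translated to a random point inside the host span and compressed if it
    would overrun it.  Donors are drawn from the log itself.
    """
    if n == 0:
        return EventLog(list(log.events)), []
    if insert_activities is None:
        insert_activities = DEFAULT_DAYTIME_INSERTS + DEFAULT_SLEEP_INSERTS
    if contexts is None:
        contexts = default_context_rules(tuple(insert_activities))
    instances = annotate_activities(log)
    donors: dict[str, list[ActivityInstance]] = {}
    for inst in instances:
        donors.setdefault(inst.activity, []).append(inst)
    for name in insert_activities:
        if name not in donors:
            raise ValueError(f"no donor instance of activity {name!r} in log")

    rules = [r for r in contexts if r.insert_activity in insert_activities]
    host_choices: dict[int, list[str]] = {}  # instance position -> admissible insert activities
    for i, inst in enumerate(instances):
        admitted = [r.insert_activity for r in rules if r.admits(inst)]
        if admitted:
            host_choices[i] = admitted
    if n > len(host_choices):
        raise ValueError(f"n={n} exceeds available insertion slots ({len(host_choices)})")

    rng = np.random.default_rng(seed)
    host_ids = rng.choice(sorted(host_choices), size=n, replace=False)
    insertions: list[tuple[list[SensorEvent], AnomalyRecord]] = []
    for host_id in host_ids:
        host = instances[int(host_id)]
        name = str(rng.choice(host_choices[int(host_id)]))
        donor = donors[name][int(rng.integers(len(donors[name])))]
        donor_events = [log[i] for i in donor.event_indices]
        donor_span = max((donor.end - donor.start).total_seconds(), 1.0)
        host_span = (host.end - host.start).total_seconds()
        t_ins = host.start + timedelta(seconds=host_span * float(rng.uniform(0.1, 0.6)))
        room = (host.end - t_ins).total_seconds()
        scale = min(1.0, 0.95 * room / donor_span)
        block = []
        for ev in donor_events:
            offset = (ev.timestamp - donor.start).total_seconds() * scale
            block.append(SensorEvent(t_ins + timedelta(seconds=int(offset)),
                                     ev.sensor_id, ev.value, ev.annotation))
        record = AnomalyRecord(
            kind=KIND_ACTIVITY,
            start=block[0].timestamp,
            end=block[-1].timestamp,
            activity=name,
            source=f"donor {name} @ {donor.start:%Y-%m-%d %H:%M:%S}; "
                   f"host {host.activity} @ {host.start:%Y-%m-%d %H:%M:%S}",
        )
        insertions.append((block, record))
    return _merge_inserted(log, insertions)


def inject_subactivity_anomalies(
    log: EventLog,
    sensor_map: dict[str, str] | None = None,
    n: int = 1,
    min_rep: int = 2,
    max_rep: int = 6,
    seed: int = 0,
) -> tuple[EventLog, list[AnomalyRecord]]:
    """Repeat each target activity's characteristic sensor inside *n* instances.

    For a chosen instance s1..sk the mapped sensor is inserted at random
    interior positions with multiplicity uniform in [min_rep, max_rep];
    timestamps are interpolated between the neighbouring events.
    """
    if sensor_map is None:
        sensor_map = dict(DEFAULT_SENSOR_MAP)
    if min_rep < 1 or max_rep < min_rep:
        raise ValueError("need 1 <= min_rep <= max_rep")
    instances = annotate_activities(log)
    by_name: dict[str, list[ActivityInstance]] = {}
    for inst in instances:
        by_name.setdefault(inst.activity, []).append(inst)
    for name in sensor_map:
        if name not in by_name:
            raise ValueError(f"target activity {name!r} absent from log")
    if n == 0:
        return EventLog(list(log.events)), []
    targets = [inst for name in sorted(sensor_map) for inst in by_name[name]]
    targets = [t for t in targets if len(t.event_indices) >= 2]
    if n > len(targets):
        raise ValueError(f"n={n} exceeds available target instances ({len(targets)})")

    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(targets), size=n, replace=False)
    insertions: list[tuple[list[SensorEvent], AnomalyRecord]] = []
    for t_id in sorted(int(i) for i in chosen):
        inst = targets[t_id]
        sensor = sensor_map[inst.activity]
        idxs = list(inst.event_indices)
        reps = int(rng.integers(min_rep, max_rep + 1))
        gaps = rng.integers(1, len(idxs), size=reps)  # gap g sits between events g-1 and g
        block: list[SensorEvent] = []
        for g in sorted(int(g) for g in gaps):
            left = log[idxs[g - 1]].timestamp
            right = log[idxs[g]].timestamp
            span = (right - left).total_seconds()
            ts = left + timedelta(seconds=int(span * float(rng.uniform(0.2, 0.8))))
            block.append(SensorEvent(ts, sensor, "ON"))
        block.sort(key=lambda e: e.timestamp)
        record = AnomalyRecord(
            kind=KIND_SUBACTIVITY,
            start=inst.start,
            end=inst.end,
            sensor_id=sensor,
            source=f"instance {inst.activity} @ {inst.start:%Y-%m-%d %H:%M:%S}",
        )
        insertions.append((block, record))
    return _merge_inserted(log, insertions)


# ---------------------------------------------------------------------------
# JSON (de)serialisation of ground truth


def records_to_json(records: list[AnomalyRecord], path: str | Path) -> None:
    payload = [
        {
            "kind": r.kind,
            "start": r.start.isoformat(sep=" "),
            "end": r.end.isoformat(sep=" "),
            "activity": r.activity,
            "sensor_id": r.sensor_id,
            "inserted_indices": r.inserted_indices,
            "source": r.source,
        }
        for r in records
    ]
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=1)


def records_from_json(path: str | Path) -> list[AnomalyRecord]:
    with open(path, "r", encoding="utf-8") as fh:
        payload = json.load(fh)
    return [
        AnomalyRecord(
            kind=item["kind"],
            start=datetime.fromisoformat(item["start"]),
            end=datetime.fromisoformat(item["end"]),
            activity=item.get("activity"),
            sensor_id=item.get("sensor_id"),
            inserted_indices=list(item.get("inserted_indices", [])),
            source=item.get("source"),
        )
        for item in payload
    ]
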