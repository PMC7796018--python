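"""Synthetic single-resident routines over a 34-sensor home.

Generates annotated event logs with known structure: 11 activity classes,
activity-specific sensor subsets, and first-order Markov transitions
between sensors so that order/frequency statistics are informative for
the downstream models.  Everything is deterministic per seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date, datetime, timedelta
from pathlib import Path

import numpy as np
import yaml

from .event_io import Annotation, EventLog, SensorEvent, SensorRegistry, default_registry

ACTIVITY_NAMES = (
    "sleeping",
    "meal_preparation",
    "relaxing",
    "eating",
    "work",
    "washing_dishes",
    "bed_to_toilet",
    "entering_home",
    "leaving_home",
    "housekeeping",
    "respirating",
)

MINUTES_PER_DAY = 1440


@dataclass
class ActivityProfile:
    """Event-emission model for one activity class.

    Events are a first-order Markov chain over ``sensors`` (registry
    indices) with exponential inter-event gaps at ``rate`` events/min.
    """

    name: str
    sensors: tuple[int, ...]
    transition: np.ndarray  # (m, m), rows sum to 1
    start_dist: np.ndarray  # (m,), sums to 1
    duration_mean: float  # minutes
    duration_sd: float
    rate: float  # events per minute

    def __post_init__(self) -> None:
        self.transition = np.asarray(self.transition, dtype=float)
        self.start_dist = np.asarray(self.start_dist, dtype=float)
        m = len(self.sensors)
        if m == 0:
            raise ValueError(f"profile {self.name!r}: sensor subset must be non-empty")
        if self.rate <= 0:
            raise ValueError(f"profile {self.name!r}: rate must be > 0")
        if self.transition.shape != (m, m):
            raise ValueError(f"profile {self.name!r}: transition matrix must be {m}x{m}")
        if not np.allclose(self.transition.sum(axis=1), 1.0):
            raise ValueError(f"profile {self.name!r}: transition rows must sum to 1")
        if not np.isclose(self.start_dist.sum(), 1.0):
            raise ValueError(f"profile {self.name!r}: start distribution must sum to 1")


@dataclass
class RoutineModel:
    """A daily routine: activity profiles plus a 24 h schedule template."""

    registry: SensorRegistry
    profiles: list[ActivityProfile]
    schedule: list[tuple[str, int]]  # (activity name, nominal duration in minutes), in order
    jitter_sd: float = 2.0  # start-time jitter, minutes
    seed: int = 0

    def __post_init__(self) -> None:
        names = {p.name for p in self.profiles}
        if len(names) != len(self.profiles):
            raise ValueError("duplicate profile names")
        total = sum(d for _, d in self.schedule)
        if total != MINUTES_PER_DAY:
            raise ValueError(f"schedule must cover 24 h exactly, got {total} minutes")
        for name, dur in self.schedule:
            if name not in names:
                raise ValueError(f"schedule references unknown activity {name!r}")
            if dur <= 0:
                raise ValueError("schedule slot durations must be positive")

    def profile(self, name: str) -> ActivityProfile:
        for p in self.profiles:
            if p.name == name:
                return p
        raise KeyError(name)


def _profile(registry: SensorRegistry, name: str, table: dict[str, dict[str, float]],
             start: dict[str, float], duration_mean: float, rate: float,
             duration_sd: float = 2.0) -> ActivityProfile:
    sensors = list(table)
    idx = {s: i for i, s in enumerate(sensors)}
    m = len(sensors)
    T = np.zeros((m, m))
    for src, row in table.items():
        for dst, prob in row.items():
            T[idx[src], idx[dst]] = prob
    s0 = np.zeros(m)
    for sid, prob in start.items():
        s0[idx[sid]] = prob
    return ActivityProfile(
        name=name,
        sensors=tuple(registry.index(s) for s in sensors),
        transition=T,
        start_dist=s0,
        duration_mean=duration_mean,
        duration_sd=duration_sd,
        rate=rate,
    )


def default_aruba_model(seed: int = 0) -> RoutineModel:
    """Default emulation: 34 sensors, 11 activities, 24 h schedule.

    Transition matrices mostly avoid self-transitions, so a repeated
    sensor activation is a distributional novelty; the sleeping profile
    plants a dominant alternating bed-sensor pair (M002<->M003) so that
    pattern mining has a known answer.
    """
    reg = default_registry()
    profiles = [
        _profile(reg, "sleeping",
                 {"M002": {"M003": 0.95, "M007": 0.05},
                  "M003": {"M002": 0.85, "M007": 0.15},
                  "M007": {"M002": 0.7, "M003": 0.3}},
                 {"M002": 0.8, "M003": 0.2}, duration_mean=360, rate=0.55),
        _profile(reg, "meal_preparation",
                 {"M015": {"M019": 0.4, "M016": 0.3, "M017": 0.3},
                  "M016": {"M019": 0.5, "M015": 0.5},
                  "M017": {"M019": 0.5, "M015": 0.5},
                  "M018": {"M019": 0.55, "M015": 0.45},
                  "M019": {"M015": 0.3, "M018": 0.3, "M017": 0.2, "M016": 0.2}},
                 {"M015": 0.3, "M018": 0.4, "M019": 0.3}, duration_mean=45, rate=2.5),
        _profile(reg, "relaxing",
                 {"M009": {"M013": 0.4, "M006": 0.2, "M008": 0.2, "M010": 0.1, "M020": 0.1},
                  "M013": {"M009": 0.7, "M020": 0.3},
                  "M006": {"M009": 0.8, "M010": 0.2},
                  "M008": {"M009": 0.8, "M006": 0.2},
                  "M010": {"M009": 0.7, "M008": 0.3},
                  "M020": {"M009": 0.6, "M013": 0.4}},
                 {"M009": 0.6, "M013": 0.4}, duration_mean=120, rate=1.0),
        _profile(reg, "eating",
                 {"M014": {"M013": 0.5, "M008": 0.25, "M006": 0.25},
                  "M013": {"M014": 0.9, "M008": 0.1},
                  "M008": {"M014": 0.9, "M006": 0.1},
                  "M006": {"M014": 0.9, "M013": 0.1}},
                 {"M014": 0.7, "M013": 0.3}, duration_mean=30, rate=2.0),
        _profile(reg, "work",
                 {"M026": {"M027": 0.55, "M008": 0.25, "M028": 0.2},
                  "M027": {"M026": 0.85, "M028": 0.15},
                  "M008": {"M026": 0.9, "M027": 0.1},
                  "M028": {"M026": 0.8, "M008": 0.2}},
                 {"M026": 0.8, "M027": 0.2}, duration_mean=180, rate=1.5),
        _profile(reg, "washing_dishes",
                 {"M015": {"M019": 0.6, "M018": 0.4},
                  "M018": {"M019": 0.7, "M015": 0.3},
                  "M019": {"M015": 0.5, "M018": 0.3, "M017": 0.2},
                  "M017": {"M019": 0.7, "M015": 0.3}},
                 {"M015": 0.5, "M019": 0.5}, duration_mean=15, rate=2.5),
        _profile(reg, "bed_to_toilet",
                 {"M004": {"M005": 0.5, "M007": 0.5},
                  "M005": {"M004": 0.8, "M007": 0.2},
                  "M007": {"M004": 0.8, "M005": 0.2}},
                 {"M004": 0.8, "M005": 0.1, "M007": 0.1}, duration_mean=10, rate=3.0),
        _profile(reg, "entering_home",
                 {"D003": {"M031": 0.9, "M030": 0.1},
                  "M031": {"M030": 0.7, "D003": 0.3},
                  "M030": {"M029": 0.7, "M022": 0.3},
                  "M029": {"M022": 0.6, "M021": 0.4},
                  "M022": {"M021": 0.7, "M014": 0.3},
                  "M021": {"M014": 0.7, "M022": 0.3},
                  "M014": {"M021": 0.5, "M022": 0.5}},
                 {"D003": 0.8, "M031": 0.2}, duration_mean=5, rate=4.0, duration_sd=1.0),
        _profile(reg, "leaving_home",
                 {"M018": {"M021": 0.8, "M022": 0.2},
                  "M021": {"M022": 0.7, "M029": 0.3},
                  "M022": {"M029": 0.7, "M030": 0.3},
                  "M029": {"M030": 0.8, "M022": 0.2},
                  "M030": {"M031": 0.8, "D003": 0.2},
                  "M031": {"D003": 0.9, "M030": 0.1},
                  "D003": {"M031": 0.5, "M030": 0.5}},
                 {"M018": 0.7, "M021": 0.3}, duration_mean=5, rate=4.0, duration_sd=1.0),
        _profile(reg, "housekeeping",
                 {"M013": {"M020": 0.5, "M014": 0.3, "M018": 0.2},
                  "M014": {"M020": 0.5, "M018": 0.3, "M013": 0.2},
                  "M018": {"M020": 0.4, "M015": 0.4, "M013": 0.2},
                  "M020": {"M013": 0.3, "M014": 0.3, "M018": 0.2, "M015": 0.2},
                  "M015": {"M018": 0.6, "M020": 0.4}},
                 {"M013": 0.5, "M020": 0.5}, duration_mean=95, rate=1.5),
        _profile(reg, "respirating",
                 {"M025": {"M025": 0.6, "M027": 0.4},
                  "M027": {"M025": 0.9, "M027": 0.1}},
                 {"M025": 0.9, "M027": 0.1}, duration_mean=20, rate=1.0),
    ]
    # Order profiles canonically.
    by_name = {p.name: p for p in profiles}
    profiles = [by_name[name] for name in ACTIVITY_NAMES]
    schedule = [
        ("sleeping", 360),
        ("bed_to_toilet", 10),
        ("respirating", 20),
        ("meal_preparation", 45),
        ("eating", 30),
        ("washing_dishes", 15),
        ("work", 240),
        ("meal_preparation", 30),
        ("eating", 30),
        ("washing_dishes", 15),
        ("leaving_home", 5),
        ("entering_home", 5),
        ("housekeeping", 95),
        ("relaxing", 120),
        ("meal_preparation", 45),
        ("eating", 30),
        ("washing_dishes", 15),
        ("work", 90),
        ("relaxing", 150),
        ("sleeping", 90),
    ]
    return RoutineModel(registry=reg, profiles=profiles, schedule=schedule, seed=seed)


def _jittered_boundaries(model: RoutineModel, rng: np.random.Generator) -> list[float]:
    """Slot boundaries (minutes from midnight) with bounded start jitter."""
    nominal = np.cumsum([0.0] + [float(d) for _, d in model.schedule])
    bounds = nominal.copy()
    for i in range(1, len(nominal) - 1):
        left_gap = nominal[i] - nominal[i - 1]
        right_gap = nominal[i + 1] - nominal[i]
        limit = 0.3 * min(left_gap, right_gap)
        bounds[i] = nominal[i] + float(np.clip(rng.normal(0.0, model.jitter_sd), -limit, limit))
    return list(bounds)


def _emit_slot(profile: ActivityProfile, start_min: float, end_min: float,
               rng: np.random.Generator) -> tuple[list[float], list[int]]:
    """Markov-chain sensor activations within [start, end); at least two."""
    duration = end_min - start_min
    times: list[float] = []
    sensors: list[int] = []
    state = int(rng.choice(len(profile.sensors), p=profile.start_dist))
    t = start_min + float(rng.uniform(0.0, min(1.0, duration * 0.1)))
    while t < end_min:
        times.append(t)
        sensors.append(profile.sensors[state])
        state = int(rng.choice(len(profile.sensors), p=profile.transition[state]))
        t += float(rng.exponential(1.0 / profile.rate))
    while len(times) < 2:  # annotation needs distinct begin/end carriers
        t = start_min + duration * (0.3 + 0.4 * float(rng.random()))
        times.append(min(t, end_min - 1e-6))
        sensors.append(profile.sensors[state])
        state = int(rng.choice(len(profile.sensors), p=profile.transition[state]))
        times, sensors = map(list, zip(*sorted(zip(times, sensors))))
    return times, sensors


def generate_days(model: RoutineModel, n_days: int, seed: int | None = None,
                  start_date: date = date(2021, 1, 1), emit_off: bool = False) -> EventLog:
    """Generate *n_days* of fully annotated events; deterministic per seed.

    Only ON activations are emitted by default; ``emit_off`` adds a paired
    OFF event one second after each activation.
    """
    if n_days < 0:
        raise ValueError("n_days must be >= 0")
    if seed is None:
        seed = model.seed
    rng = np.random.default_rng(seed)
    events: list[SensorEvent] = []
    for day in range(n_days):
        day_start = datetime.combine(start_date + timedelta(days=day), datetime.min.time())
        bounds = _jittered_boundaries(model, rng)
        for slot_i, (name, _) in enumerate(model.schedule):
            profile = model.profile(name)
            times, sensors = _emit_slot(profile, bounds[slot_i], bounds[slot_i + 1], rng)
            slot_events = []
            for t, s_idx in zip(times, sensors):
                ts = day_start + timedelta(seconds=int(t * 60.0))
                slot_events.append(SensorEvent(ts, model.registry.name(s_idx), "ON"))
            slot_events[0] = SensorEvent(slot_events[0].timestamp, slot_events[0].sensor_id,
                                         "ON", Annotation(name, "begin"))
            slot_events[-1] = SensorEvent(slot_events[-1].timestamp, slot_events[-1].sensor_id,
                                          "ON", Annotation(name, "end"))
            if emit_off:
                offs = [SensorEvent(ev.timestamp + timedelta(seconds=1), ev.sensor_id, "OFF")
                        for ev in slot_events]
                slot_events = sorted(slot_events + offs, key=lambda e: e.timestamp)
            events.extend(slot_events)
    events.sort(key=lambda e: e.timestamp)  # OFF events may cross slot edges
    return EventLog(events)


# ---------------------------------------------------------------------------
# YAML (de)serialisation of routine models


def model_to_dict(model: RoutineModel) -> dict:
    return {
        "sensors": list(model.registry.sensor_ids),
        "jitter_sd": model.jitter_sd,
        "seed": model.seed,
        "schedule": [[name, dur] for name, dur in model.schedule],
        "profiles": [
            {
                "name": p.name,
                "sensors": [model.registry.name(i) for i in p.sensors],
                "transition": p.transition.tolist(),
                "start_dist": p.start_dist.tolist(),
                "duration_mean": p.duration_mean,
                "duration_sd": p.duration_sd,
                "rate": p.rate,
            }
            for p in model.profiles
        ],
    }


def model_from_dict(data: dict) -> RoutineModel:
    registry = SensorRegistry(data["sensors"])
    profiles = [
        ActivityProfile(
            name=p["name"],
            sensors=tuple(registry.index(s) for s in p["sensors"]),
            transition=np.asarray(p["transition"], dtype=float),
            start_dist=np.asarray(p["start_dist"], dtype=float),
            duration_mean=float(p["duration_mean"]),
            duration_sd=float(p["duration_sd"]),
            rate=float(p["rate"]),
        )
        for p in data["profiles"]
    ]
    return RoutineModel(
        registry=registry,
        profiles=profiles,
        schedule=[(name, int(dur)) for name, dur in data["schedule"]],
        jitter_sd=float(data.get("jitter_sd", 2.0)),
        seed=int(data.get("seed", 0)),
    )


def save_model(model: RoutineModel, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(model_to_dict(model), fh, sort_keys=False)


def load_model(path: str | Path) -> RoutineModel:
    with open(path, "r", encoding="utf-8") as fh:
        return model_from_dict(yaml.safe_load(fh))
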