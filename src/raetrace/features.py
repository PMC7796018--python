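"""Window segmentation and the two window encodings.

A log is cut into tumbling fixed-length windows; each window is encoded
either as a fixed-length binary presence vector over the sensor registry
(order- and frequency-blind) or as the ordered, repeat-preserving token
sequence of activations with a one-hot matrix view.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime, timedelta

import numpy as np
import pandas as pd

from .anomaly_simulation import AnomalyRecord
from .event_io import EventLog, SensorRegistry, annotate_activities, event_labels


@dataclass
class WindowChunk:
    """One fixed-length window of a log."""

    start: datetime
    end: datetime
    tokens: list[int]  # registry indices of ON activations, time order, repeats kept
    event_indices: list[int]  # positions of those activations in the source log
    label: str | None = None  # majority activity label
    abnormal: bool | None = None  # ground truth, when known

    def __len__(self) -> int:
        return len(self.tokens)


@dataclass
class RSMSequence:
    """Ordered activation tokens with a (k x N) one-hot matrix view."""

    tokens: list[int]
    n_sensors: int

    @property
    def onehot(self) -> np.ndarray:
        mat = np.zeros((len(self.tokens), self.n_sensors))
        if self.tokens:
            mat[np.arange(len(self.tokens)), self.tokens] = 1.0
        return mat


def segment_windows(
    log: EventLog,
    registry: SensorRegistry,
    window_minutes: float = 1.0,
) -> list[WindowChunk]:
    """Tile the log's span with tumbling windows of *window_minutes*.

    Every ON/OPEN activation lands in exactly one window; OFF/CLOSE events
    are ignored.  Windows are aligned to the first event's minute.  The
    majority activity label (by event count, ties to the earlier activity)
    is attached when annotations exist.
    """
    if window_minutes <= 0:
        raise ValueError("window length must be positive")
    if len(log) == 0:
        return []
    width = timedelta(minutes=window_minutes)
    t0 = log.start.replace(second=0, microsecond=0)
    n_windows = int((log.end - t0) / width) + 1
    chunks = [
        WindowChunk(start=t0 + i * width, end=t0 + (i + 1) * width, tokens=[], event_indices=[])
        for i in range(n_windows)
    ]
    labels = event_labels(log, annotate_activities(log))
    window_labels: list[list[str]] = [[] for _ in range(n_windows)]
    for i, ev in enumerate(log):
        if not ev.is_on:
            continue
        w = int((ev.timestamp - t0) / width)
        chunks[w].tokens.append(registry.index(ev.sensor_id))
        chunks[w].event_indices.append(i)
        if labels[i] is not None:
            window_labels[w].append(labels[i])
    for chunk, lab in zip(chunks, window_labels):
        if lab:
            counts: dict[str, int] = {}
            for name in lab:
                counts[name] = counts.get(name, 0) + 1
            best = max(counts.values())
            chunk.label = next(name for name in lab if counts[name] == best)  # tie -> earliest
    return chunks


def bos_vector(chunk: WindowChunk, registry: SensorRegistry) -> np.ndarray:
    """Binary presence vector: entry j is 1 iff sensor j triggered at all."""
    vec = np.zeros(len(registry), dtype=np.int8)
    for tok in chunk.tokens:
        if not 0 <= tok < len(registry):
            raise ValueError(f"token index {tok} outside registry of size {len(registry)}")
        vec[tok] = 1
    return vec


def bos_bitstring(chunk: WindowChunk, registry: SensorRegistry) -> str:
    return "".join(str(b) for b in bos_vector(chunk, registry))


def rsm_sequence(chunk: WindowChunk, registry: SensorRegistry) -> RSMSequence:
    """Ordered token sequence with repeats; one-hot rows of width N."""
    for tok in chunk.tokens:
        if not 0 <= tok < len(registry):
            raise ValueError(f"token index {tok} outside registry of size {len(registry)}")
    return RSMSequence(tokens=list(chunk.tokens), n_sensors=len(registry))


def mark_abnormal(chunks: list[WindowChunk], records: list[AnomalyRecord]) -> list[WindowChunk]:
    """Flag a chunk abnormal iff it contains >= 1 injected event."""
    inserted: set[int] = set()
    for rec in records:
        inserted.update(rec.inserted_indices)
    for chunk in chunks:
        chunk.abnormal = any(i in inserted for i in chunk.event_indices)
    return chunks


def stack_bos_chunks(
    chunks: list[WindowChunk],
    registry: SensorRegistry,
    w: int = 25,
) -> list[tuple[np.ndarray, list[WindowChunk]]]:
    """Group consecutive windows into blocks of *w* stacked presence vectors.

    The trailing partial block is dropped.  Returns (w x N matrix, member
    chunk list) pairs.
    """
    if w < 2:
        raise ValueError("chunk width w must be >= 2")
    out = []
    for i in range(0, len(chunks) - w + 1, w):
        members = chunks[i : i + w]
        rows = np.stack([bos_vector(c, registry) for c in members]).astype(float)
        out.append((rows, members))
    return out


def chunks_to_frame(chunks: list[WindowChunk], registry: SensorRegistry) -> pd.DataFrame:
    """Tabular export of a chunk list (start, end, label, tokens, bits)."""
    return pd.DataFrame(
        {
            "start": [c.start.isoformat(sep=" ") for c in chunks],
            "end": [c.end.isoformat(sep=" ") for c in chunks],
            "label": [c.label for c in chunks],
            "abnormal": [c.abnormal for c in chunks],
            "tokens": [" ".join(registry.name(t) for t in c.tokens) for c in chunks],
            "bits": [bos_bitstring(c, registry) for c in chunks],
        }
    )
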