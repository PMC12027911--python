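"""Translocation-event calling from raw ion-current traces.

A single molecule traversing a nanopore transiently reduces the open-pore
current Io to a residual level Ir; the fractional blockade Ir/Io and the
dwell time tau (in raw time points, "tps") characterise the event.  Events
are called with fixed thresholds: a maximal run of consecutive samples with
I/Io below the *all* ratio (0.6) is an event candidate, reported iff its
length lies in [4, 1200] tps and its minimum I/Io is below the *lowest*
ratio (0.55).  Osmium-tagged probes translocate slowly and deeply
(Ir/Io ~ 0.15) and are therefore selectively registered, while untagged
RNA mostly escapes the acquisition rate.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "CurrentTrace",
    "TranslocationEvent",
    "DetectionParams",
    "UnusableChannelError",
    "estimate_open_current",
    "detect_events",
    "duration_tps_to_ms",
    "events_to_frame",
    "frame_to_events",
    "write_event_table",
    "read_event_table",
    "EVENT_COLUMNS",
]

EVENT_COLUMNS = ["channel", "start_tp", "duration_tps", "min_ir_io", "mean_ir_io"]


class UnusableChannelError(ValueError):
    """Raised when a trace carries no interpretable open-pore current."""


@dataclass(frozen=True)
class CurrentTrace:
    """Per-channel ion-current samples in pA at a fixed acquisition rate."""

    channel: int
    samples: np.ndarray
    sampling_rate: float = 3000.0

    def __post_init__(self):
        samples = np.asarray(self.samples, dtype=np.float64)
        if samples.ndim != 1:
            raise ValueError("trace samples must be one-dimensional")
        if not np.all(np.isfinite(samples)):
            raise ValueError("trace samples must be finite")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        object.__setattr__(self, "samples", samples)


@dataclass(frozen=True)
class TranslocationEvent:
    """One blockade: where it starts, how long it lasts, and how deep it is.

    ``min_ir_io`` is the deepest residual-current ratio reached during the
    event and is the per-event depth used by all downstream analysis;
    ``mean_ir_io`` is retained for sensitivity checks.
    """

    channel: int
    start_tp: int
    duration_tps: int
    min_ir_io: float
    mean_ir_io: float

    def __post_init__(self):
        if self.duration_tps < 1:
            raise ValueError("duration_tps must be >= 1")
        if not 0.0 <= self.min_ir_io <= self.mean_ir_io:
            raise ValueError("require 0 <= min_ir_io <= mean_ir_io")


@dataclass(frozen=True)
class DetectionParams:
    """Event-caller thresholds (defaults are the validated working set)."""

    min_duration_tps: int = 4
    max_duration_tps: int = 1200
    lowest_ratio: float = 0.55
    all_ratio: float = 0.60
    channel_min: int = 1
    channel_max: int = 512

    def __post_init__(self):
        if not 0.0 < self.lowest_ratio <= self.all_ratio < 1.0:
            raise ValueError("require 0 < lowest_ratio <= all_ratio < 1")
        if not 0 < self.min_duration_tps <= self.max_duration_tps:
            raise ValueError("require 0 < min_duration_tps <= max_duration_tps")


def estimate_open_current(trace: CurrentTrace | np.ndarray) -> float:
    """Estimate the open-pore current Io as the modal level of the trace.

    The histogram of samples is built with 1 pA bins; the open-pore level is
    the highest-current mode (blockades occupy a small minority of samples
    at lower currents and cannot outweigh the open-pore plateau, but if a
    lower mode ties the open level, the higher-current one wins).  The
    returned value is the mean of the samples falling in that modal bin,
    which is exact for a constant trace.
    """
    samples = trace.samples if isinstance(trace, CurrentTrace) else np.asarray(trace, float)
    if samples.size == 0:
        raise UnusableChannelError("empty trace")
    lo, hi = float(samples.min()), float(samples.max())
    if hi <= 0.0:
        raise UnusableChannelError("trace has no positive current")
    edges = np.arange(np.floor(lo), np.ceil(hi) + 1.0 + 1e-9, 1.0)
    if edges.size < 2:
        edges = np.array([np.floor(lo), np.floor(lo) + 1.0])
    counts, edges = np.histogram(samples, bins=edges)
    top = counts.max()
    # among bins within 50% of the top count, take the highest-current one
    candidates = np.flatnonzero(counts >= 0.5 * top)
    k = candidates[-1]
    in_bin = (samples >= edges[k]) & (samples < edges[k + 1])
    if not in_bin.any():  # right-closed final bin
        in_bin = (samples >= edges[k]) & (samples <= edges[k + 1])
    io = float(samples[in_bin].mean())
    if io <= 0.0:
        raise UnusableChannelError("estimated open current is not positive")
    return io


def detect_events(
    trace: CurrentTrace,
    io: float,
    params: DetectionParams = DetectionParams(),
) -> list[TranslocationEvent]:
    """Call blockade events on one channel trace.

    An event is a maximal run of consecutive samples with I/Io below
    ``params.all_ratio``; it is reported iff its length is within
    [min_duration_tps, max_duration_tps] and its minimum I/Io is below
    ``params.lowest_ratio``.  Events are non-overlapping and ordered by
    start sample.
    """
    if io <= 0:
        raise ValueError("Io must be positive")
    samples = trace.samples
    below = samples < params.all_ratio * io
    if not below.any():
        return []
    padded = np.concatenate(([False], below, [False]))
    diffs = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diffs == 1)
    ends = np.flatnonzero(diffs == -1)  # exclusive
    durations = ends - starts
    keep = (durations >= params.min_duration_tps) & (durations <= params.max_duration_tps)
    starts, ends, durations = starts[keep], ends[keep], durations[keep]
    if starts.size == 0:
        return []
    events: list[TranslocationEvent] = []
    for s, e, d in zip(starts, ends, durations):
        seg = samples[s:e]
        mn = float(seg.min()) / io
        if mn < params.lowest_ratio:
            events.append(
                TranslocationEvent(
                    channel=trace.channel,
                    start_tp=int(s),
                    duration_tps=int(d),
                    min_ir_io=mn,
                    mean_ir_io=float(seg.mean()) / io,
                )
            )
    return events


def duration_tps_to_ms(duration_tps: float, sampling_rate: float) -> float:
    """Convert a dwell time in raw time points to milliseconds."""
    if sampling_rate <= 0:
        raise ValueError("sampling_rate must be positive")
    if duration_tps < 0:
        raise ValueError("duration must be non-negative")
    return duration_tps * 1000.0 / sampling_rate


def events_to_frame(events: Iterable[TranslocationEvent]) -> pd.DataFrame:
    rows = [dataclasses.asdict(e) for e in events]
    frame = pd.DataFrame(rows, columns=EVENT_COLUMNS)
    frame = frame.astype(
        {"channel": np.int64, "start_tp": np.int64, "duration_tps": np.int64,
         "min_ir_io": np.float64, "mean_ir_io": np.float64}
    )
    return frame.sort_values(["channel", "start_tp"], kind="mergesort").reset_index(drop=True)


def frame_to_events(frame: pd.DataFrame) -> list[TranslocationEvent]:
    return [
        TranslocationEvent(
            channel=int(r.channel), start_tp=int(r.start_tp),
            duration_tps=int(r.duration_tps),
            min_ir_io=float(r.min_ir_io), mean_ir_io=float(r.mean_ir_io),
        )
        for r in frame.itertuples(index=False)
    ]


def write_event_table(events: Iterable[TranslocationEvent] | pd.DataFrame, path: str | Path) -> None:
    """Write the per-event table as TSV, sorted by (channel, start_tp)."""
    frame = events if isinstance(events, pd.DataFrame) else events_to_frame(events)
    frame = frame[EVENT_COLUMNS].sort_values(["channel", "start_tp"], kind="mergesort")
    frame.to_csv(path, sep="\t", index=False)


def read_event_table(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t")
    missing = [c for c in EVENT_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"event table missing columns: {missing}")
    return frame[EVENT_COLUMNS]
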