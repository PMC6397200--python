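"""Myofiber contraction calling from intensity-over-time traces.

Innervated myofibers twitch, which shows up as short bursts in the per-frame
ROI intensity of a brightfield movie; denervated fibers produce a flat,
noise-only trace. Each fiber is classified as contracting or non-contracting
and the per-chamber percentage of contracting myotubes is the activity
readout of the neuromuscular co-culture.

The calling rule: a trace is converted to relative deviation from its median
baseline, bursts are maximal runs of at least ``min_frames`` consecutive
frames whose absolute deviation exceeds ``k_mad`` robust standard deviations
(1.4826 x MAD), and a fiber is "contracting" when it shows at least
``min_events`` bursts (default 2, mirroring the multiple bursting events of
an active fiber). Single-event fibers are therefore non-contracting at the
default but remain auditable through the event list on each call.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DataError, ParameterError

DEFAULT_K_MAD = 5.0
DEFAULT_MIN_EVENT_FRAMES = 2
DEFAULT_MIN_EVENTS = 2
#: Absolute relative-deviation threshold used when the MAD collapses to zero.
FALLBACK_ABS_THRESHOLD = 0.2
_MAD_TO_SD = 1.4826


@dataclass(frozen=True)
class IntensityTrace:
    """Per-frame intensity of one myofiber ROI (arbitrary units)."""

    fiber_id: str
    fps: float
    values: np.ndarray
    chamber_id: str = ""
    condition: str = ""

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if self.fps <= 0:
            raise ParameterError(f"trace {self.fiber_id!r}: fps must be > 0")
        if v.ndim != 1 or v.size < 10:
            raise DataError(f"trace {self.fiber_id!r}: needs at least 10 frames")
        if not np.all(np.isfinite(v)):
            raise DataError(f"trace {self.fiber_id!r}: non-finite intensities")

    @property
    def n_frames(self) -> int:
        return int(self.values.size)


@dataclass(frozen=True)
class BurstEvent:
    start_frame: int
    n_frames: int
    peak_deviation: float


@dataclass
class ContractionCall:
    fiber_id: str
    contracting: bool
    events: list[BurstEvent] = field(default_factory=list)


def normalize_trace(trace: IntensityTrace) -> np.ndarray:
    """Relative deviation (value - baseline)/baseline with a median baseline."""
    baseline = float(np.median(trace.values))
    if baseline <= 0:
        raise DataError(f"trace {trace.fiber_id!r}: non-positive median baseline")
    return (trace.values - baseline) / baseline


def detect_bursts(
    norm: np.ndarray,
    k_mad: float = DEFAULT_K_MAD,
    min_frames: int = DEFAULT_MIN_EVENT_FRAMES,
) -> list[BurstEvent]:
    """Maximal runs of >= min_frames frames with |deviation| above the threshold.

    Threshold = k_mad * 1.4826 * MAD of the series. If the MAD is zero while
    some deviations are nonzero (a trace that is flat except for bursts), the
    detector falls back to the documented absolute threshold and warns.
    """
    if k_mad <= 0:
        raise ParameterError("k_mad must be > 0")
    if min_frames < 1:
        raise ParameterError("min_frames must be >= 1")
    norm = np.asarray(norm, dtype=float)
    dev = np.abs(norm)
    mad = float(np.median(np.abs(norm - np.median(norm))))
    if mad == 0.0:
        if np.any(dev > 0):
            warnings.warn(
                "MAD of trace is zero with nonzero deviations; falling back "
                f"to absolute threshold {FALLBACK_ABS_THRESHOLD}",
                stacklevel=2,
            )
            threshold = FALLBACK_ABS_THRESHOLD
        else:
            return []
    else:
        threshold = k_mad * _MAD_TO_SD * mad
    above = dev > threshold
    events: list[BurstEvent] = []
    start = None
    for i, flag in enumerate(above):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            if i - start >= min_frames:
                events.append(BurstEvent(start, i - start, float(np.max(dev[start:i]))))
            start = None
    if start is not None and above.size - start >= min_frames:
        events.append(
            BurstEvent(start, int(above.size - start), float(np.max(dev[start:])))
        )
    return events


def classify_contracting(
    trace: IntensityTrace,
    *,
    k_mad: float = DEFAULT_K_MAD,
    min_event_frames: int = DEFAULT_MIN_EVENT_FRAMES,
    min_events: int = DEFAULT_MIN_EVENTS,
) -> ContractionCall:
    """Call one fiber contracting iff it shows >= min_events burst events."""
    if min_events < 1:
        raise ParameterError("min_events must be >= 1")
    events = detect_bursts(normalize_trace(trace), k_mad, min_event_frames)
    return ContractionCall(trace.fiber_id, len(events) >= min_events, events)


def percent_contracting(
    calls: Sequence[ContractionCall],
    chamber_by_fiber: Mapping[str, str] | None = None,
) -> pd.Series:
    """Per-chamber percentage of contracting fibers (100 * contracting / total).

    Without a chamber mapping all fibers pool into a single "all" chamber.
    Chambers named in the mapping but holding zero analyzed fibers are
    excluded with a warning.
    """
    groups: dict[str, list[bool]] = {}
    for call in calls:
        chamber = "all" if chamber_by_fiber is None else chamber_by_fiber[call.fiber_id]
        groups.setdefault(chamber, []).append(call.contracting)
    if chamber_by_fiber is not None:
        for chamber in set(chamber_by_fiber.values()) - set(groups):
            warnings.warn(f"chamber {chamber!r} has no analyzed fibers; excluded",
                          stacklevel=2)
    out = {
        chamber: 100.0 * sum(flags) / len(flags)
        for chamber, flags in sorted(groups.items())
    }
    return pd.Series(out, dtype=float, name="percent_contracting")


def analyze_traces(
    traces: Sequence[IntensityTrace],
    *,
    k_mad: float = DEFAULT_K_MAD,
    min_event_frames: int = DEFAULT_MIN_EVENT_FRAMES,
    min_events: int = DEFAULT_MIN_EVENTS,
) -> tuple[list[ContractionCall], pd.Series]:
    """Classify every trace and return the calls plus per-chamber percentages."""
    calls = [
        classify_contracting(
            t, k_mad=k_mad, min_event_frames=min_event_frames, min_events=min_events
        )
        for t in traces
    ]
    chamber_by_fiber = {t.fiber_id: t.chamber_id or "all" for t in traces}
    return calls, percent_contracting(calls, chamber_by_fiber)
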