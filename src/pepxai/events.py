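"""Parameterized event primitive (PEP) extraction.

Four event families are extracted from each series:

* increasing runs — maximal stretches of strictly positive first differences,
  summarized as ``(t_start, dura, grad_avg)``: the 0-based time step where the
  positive gradient begins, the number of difference steps it lasts, and the
  mean first difference over the run;
* decreasing runs — the mirror image over strictly negative differences;
* local maxima / local minima — interior points (or plateau onsets) strictly
  above / below both flanking values, summarized as ``(time, value)``.

A zero first difference belongs to no run and terminates any run in progress.
Endpoints never yield extrema; a plateau yields one extremum anchored at its
first index when it is strictly above (below) both flanking values. Series are
used exactly as read — no smoothing, detrending or standardization — so event
parameters stay in raw signal units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datasets_io import TimeSeriesDataset
from .errors import ConfigError, SeriesTooShortError

__all__ = [
    "RUN_KINDS",
    "EXTREMUM_KINDS",
    "EVENT_KINDS",
    "RunEvent",
    "ExtremumEvent",
    "InstanceEvents",
    "extract_run_events",
    "extract_extremum_events",
    "extract_series_events",
    "extract_all",
    "event_vector",
    "events_to_rows",
]

RUN_KINDS = ("increasing", "decreasing")
EXTREMUM_KINDS = ("local_max", "local_min")
#: Canonical ordering used everywhere downstream (clustering, attribution,
#: feature-table column blocks).
EVENT_KINDS = RUN_KINDS + EXTREMUM_KINDS


@dataclass(frozen=True)
class RunEvent:
    """A maximal monotone run: starts at ``t_start``, spans ``dura`` steps."""

    t_start: int
    dura: int
    grad_avg: float
    kind: str = "increasing"


@dataclass(frozen=True)
class ExtremumEvent:
    """An interior local extremum at ``time`` with the series value there."""

    time: int
    value: float
    kind: str = "local_max"


@dataclass
class InstanceEvents:
    """All events of one instance, keyed by kind, each list time-ordered."""

    instance_id: str
    events: dict = field(default_factory=dict)

    def count(self, kind: str) -> int:
        return len(self.events.get(kind, []))


def extract_run_events(
    series,
    kind: str,
    min_dura: int = 1,
    min_abs_grad: float = 0.0,
) -> list[RunEvent]:
    """Extract maximal strictly-increasing or strictly-decreasing runs.

    ``min_dura`` / ``min_abs_grad`` filter short or shallow runs; the defaults
    (1 step, 0.0) are fully permissive.
    """
    if kind not in RUN_KINDS:
        raise ConfigError(f"unknown run kind {kind!r}")
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise ConfigError("extract_run_events expects a single 1-d series")
    if x.size < 2:
        raise SeriesTooShortError(f"series of length {x.size} has no gradient")

    d = np.diff(x)
    keep = d > 0 if kind == "increasing" else d < 0

    events: list[RunEvent] = []
    i = 0
    n = d.size
    while i < n:
        if not keep[i]:
            i += 1
            continue
        j = i
        while j < n and keep[j]:
            j += 1
        dura = j - i
        grad_avg = float(d[i:j].mean())
        if dura >= min_dura and abs(grad_avg) >= min_abs_grad:
            events.append(RunEvent(t_start=i, dura=dura, grad_avg=grad_avg, kind=kind))
        i = j
    return events


def extract_extremum_events(series, kind: str) -> list[ExtremumEvent]:
    """Extract interior local maxima or minima, including plateau onsets."""
    if kind not in EXTREMUM_KINDS:
        raise ConfigError(f"unknown extremum kind {kind!r}")
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise ConfigError("extract_extremum_events expects a single 1-d series")
    if x.size < 3:
        return []

    # compress consecutive equal values into plateaus: (start index, value)
    groups: list[tuple[int, float]] = [(0, float(x[0]))]
    for i in range(1, x.size):
        if x[i] != groups[-1][1]:
            groups.append((i, float(x[i])))

    events: list[ExtremumEvent] = []
    for g in range(1, len(groups) - 1):
        start, val = groups[g]
        prev_val = groups[g - 1][1]
        next_val = groups[g + 1][1]
        if kind == "local_max":
            hit = prev_val < val and val > next_val
        else:
            hit = prev_val > val and val < next_val
        if hit:
            events.append(ExtremumEvent(time=start, value=val, kind=kind))
    return events


def extract_series_events(
    series,
    instance_id: str = "0",
    min_dura: int = 1,
    min_abs_grad: float = 0.0,
) -> InstanceEvents:
    """Extract all four event families from one series."""
    ev = {
        kind: extract_run_events(series, kind, min_dura=min_dura, min_abs_grad=min_abs_grad)
        for kind in RUN_KINDS
    }
    for kind in EXTREMUM_KINDS:
        ev[kind] = extract_extremum_events(series, kind)
    return InstanceEvents(instance_id=instance_id, events=ev)


def extract_all(
    ds: TimeSeriesDataset,
    min_dura: int = 1,
    min_abs_grad: float = 0.0,
) -> list[InstanceEvents]:
    """Extract events for every instance of a dataset."""
    out = []
    for i in range(ds.n_instances):
        try:
            out.append(
                extract_series_events(
                    ds.values[i],
                    instance_id=ds.instance_ids[i],
                    min_dura=min_dura,
                    min_abs_grad=min_abs_grad,
                )
            )
        except SeriesTooShortError as exc:
            raise SeriesTooShortError(
                f"instance {ds.instance_ids[i]!r}: {exc}"
            ) from exc
    return out


def event_vector(event) -> np.ndarray:
    """Parameter-space coordinates of an event (the clustering features)."""
    if isinstance(event, RunEvent):
        return np.array([event.t_start, event.dura, event.grad_avg], dtype=float)
    if isinstance(event, ExtremumEvent):
        return np.array([event.time, event.value], dtype=float)
    raise ConfigError(f"unknown event type {type(event).__name__}")


def events_to_rows(all_events: list[InstanceEvents]) -> list[dict]:
    """Long-format export: one row per event (instance_id, kind, p1, p2, p3)."""
    rows = []
    for inst in all_events:
        for kind in EVENT_KINDS:
            for ev in inst.events.get(kind, []):
                vec = event_vector(ev)
                rows.append(
                    {
                        "instance_id": inst.instance_id,
                        "kind": kind,
                        "p1": vec[0],
                        "p2": vec[1],
                        "p3": vec[2] if vec.size > 2 else "",
                    }
                )
    return rows
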