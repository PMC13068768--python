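"""Event segmentation and per-event kinematic features.

An event is a maximal run of identically labeled samples.  This module
converts label sequences to ordered event lists, computes the kinematic
features used in feature-distribution comparisons (duration, amplitude,
dispersion, peak/min velocity), summarises them, and evaluates
criterion-coverage tables (what fraction of events satisfy each detection
threshold).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import (
    AlignmentError,
    EventLabel,
    GazeRecording,
    InsufficientDataError,
    compute_dispersion,
    compute_velocity,
)

__all__ = [
    "Event",
    "labels_to_events",
    "events_to_labels",
    "event_features",
    "criterion_coverage",
    "feature_summary",
    "DEFAULT_CRITERIA",
]


@dataclass(frozen=True)
class Event:
    """A maximal run of identically labeled samples with derived features.

    Indices are inclusive; times in ms; duration spans ``end - start`` plus
    one sample period.  Kinematic features are NaN (undefined, not zero)
    when the underlying coordinates are missing.
    """

    label: EventLabel
    start_index: int
    end_index: int
    start_time: float
    end_time: float
    duration: float          # ms
    amplitude: float         # °, first -> last non-missing sample
    dispersion: float        # °
    peak_velocity: float     # °/s
    min_velocity: float      # °/s

    @property
    def n_samples(self) -> int:
        return self.end_index - self.start_index + 1


def _features(
    rec: GazeRecording, v: np.ndarray, s: int, e: int
) -> tuple[float, float, float, float]:
    x, y = rec.x[s : e + 1], rec.y[s : e + 1]
    ok = ~(np.isnan(x) | np.isnan(y))
    if not ok.any():
        return math.nan, math.nan, math.nan, math.nan
    xs, ys = x[ok], y[ok]
    amplitude = float(np.hypot(xs[-1] - xs[0], ys[-1] - ys[0]))
    dispersion = compute_dispersion(x, y)
    ev_v = v[s : e + 1]
    ev_v = ev_v[~np.isnan(ev_v)]
    if ev_v.size:
        vmax, vmin = float(ev_v.max()), float(ev_v.min())
    else:
        vmax = vmin = math.nan
    return amplitude, dispersion, vmax, vmin


def labels_to_events(labels: np.ndarray, rec: GazeRecording) -> list[Event]:
    """Segment a label sequence into its ordered, gap-free event list."""
    labels = np.asarray(labels)
    if labels.size == 0:
        return []
    if labels.size != rec.n_samples:
        raise AlignmentError(
            f"labels ({labels.size}) and recording ({rec.n_samples}) lengths differ"
        )
    v = compute_velocity(rec, "sample_diff")
    period = rec.period_ms
    events = []
    # runs split at missing-data boundaries too: an event never spans a gap
    missing = rec.missing.astype(np.int8)
    change = np.flatnonzero((np.diff(labels) != 0) | (np.diff(missing) != 0)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change - 1, [labels.size - 1]))
    for s, e in zip(starts, ends):
        s, e = int(s), int(e)
        amplitude, dispersion, vmax, vmin = _features(rec, v, s, e)
        events.append(
            Event(
                label=EventLabel(int(labels[s])),
                start_index=s,
                end_index=e,
                start_time=float(rec.t[s]),
                end_time=float(rec.t[e]),
                duration=float(rec.t[e] - rec.t[s] + period),
                amplitude=amplitude,
                dispersion=dispersion,
                peak_velocity=vmax,
                min_velocity=vmin,
            )
        )
    return events


def events_to_labels(events: list[Event], n_samples: int | None = None) -> np.ndarray:
    """Inverse of :func:`labels_to_events` for a gap-free event list."""
    if not events:
        return np.zeros(0, dtype=np.int8)
    n = n_samples if n_samples is not None else events[-1].end_index + 1
    labels = np.full(n, int(EventLabel.UNDEFINED), dtype=np.int8)
    for ev in events:
        labels[ev.start_index : ev.end_index + 1] = int(ev.label)
    return labels


def event_features(ev: Event, rec: GazeRecording) -> dict:
    """Feature record of a single event (recomputed from the recording)."""
    if not (0 <= ev.start_index <= ev.end_index < rec.n_samples):
        raise AlignmentError("event indices fall outside the recording")
    v = compute_velocity(rec, "sample_diff")
    amplitude, dispersion, vmax, vmin = _features(rec, v, ev.start_index, ev.end_index)
    return {
        "label": ev.label.name,
        "duration": float(rec.t[ev.end_index] - rec.t[ev.start_index] + rec.period_ms),
        "amplitude": amplitude,
        "dispersion": dispersion,
        "peak_velocity": vmax,
        "min_velocity": vmin,
    }


# Default criterion bounds per event type, as (feature, low, high); None = open.
DEFAULT_CRITERIA: dict[EventLabel, list[tuple[str, float | None, float | None]]] = {
    EventLabel.FIXATION: [
        ("duration", 55.0, 2500.0),
        ("dispersion", None, 2.7),
        ("peak_velocity", None, 45.0),
    ],
    EventLabel.SACCADE: [
        ("duration", 10.0, 200.0),
        ("dispersion", 2.7, None),
        ("peak_velocity", 45.0, 1000.0),
        ("min_velocity", 45.0, None),
    ],
    EventLabel.PSO: [("duration", 4.0, 40.0)],
    EventLabel.BLINK: [("duration", 20.0, 2500.0)],
}


def criterion_coverage(
    events: list[Event],
    table: dict[EventLabel, list[tuple[str, float | None, float | None]]] | None = None,
) -> dict[str, dict[str, float]]:
    """Percentage of events of each type satisfying each criterion.

    ``table`` maps an event type to ``(feature, low, high)`` bounds (either
    bound may be None).  Events lacking the referenced feature (NaN) are
    excluded from that criterion's denominator; types with no events are
    absent from the output.
    """
    table = table if table is not None else DEFAULT_CRITERIA
    out: dict[str, dict[str, float]] = {}
    for label, criteria in table.items():
        of_type = [ev for ev in events if ev.label == label]
        if not of_type:
            continue
        row: dict[str, float] = {}
        for feature, lo, hi in criteria:
            if lo is not None and hi is not None and lo > hi:
                raise ValueError(f"criterion bounds for {feature} are inverted")
            values = np.array(
                [getattr(ev, feature) for ev in of_type], dtype=float
            )
            defined = values[~np.isnan(values)]
            if defined.size == 0:
                continue
            ok = np.ones(defined.size, dtype=bool)
            if lo is not None:
                ok &= defined >= lo
            if hi is not None:
                ok &= defined <= hi
            row[feature] = 100.0 * ok.sum() / defined.size
        if row:
            out[label.name] = row
    return out


def feature_summary(
    events: list[Event], feature: str, group_by: str = "label"
) -> pd.DataFrame:
    """Distribution summary (count, mean, SD, quartiles) of an event feature.

    Groups by event label (or any Event attribute).  The SD of a single
    observation is reported as 0 with the ``single_obs`` flag set, so it
    does not propagate NaNs into summary tables.
    """
    if not events:
        raise InsufficientDataError("no events to summarise")
    groups = [getattr(ev, group_by) for ev in events]
    df = pd.DataFrame(
        {
            # IntEnum members would be silently coerced to int64 by pandas
            "group": [g.name if isinstance(g, EventLabel) else g for g in groups],
            "value": [getattr(ev, feature) for ev in events],
        }
    )
    rows = []
    for g, sub in df.groupby("group", sort=False):
        vals = sub["value"].dropna()
        row = {"group": g, "count": int(len(sub))}
        if len(vals):
            row.update(
                mean=float(vals.mean()),
                sd=0.0 if len(vals) == 1 else float(vals.std(ddof=1)),
                single_obs=len(vals) == 1,
                q25=float(vals.quantile(0.25)),
                median=float(vals.median()),
                q75=float(vals.quantile(0.75)),
            )
        rows.append(row)
    return pd.DataFrame(rows).set_index("group")
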