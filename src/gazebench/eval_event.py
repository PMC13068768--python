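"""Event-boundary evaluation: matching, timing, and boundary sensitivity.

Detected event onsets/offsets are paired with the nearest ground-truth
boundary inside a temporal window of ±delta_t samples.  From the pairing we
derive hit rate, relative timing offset/deviation (RTO/RTD — the mean and
sample SD of the signed differences), per-pair l2/IoU overlap, and a
signal-detection sensitivity index d' whose false-alarm denominator is the
number of non-overlapping, boundary-free ground-truth windows of size
2*delta_t + 1 ("negative windows").  A sweep over delta_t = 0..20 gives the
boundary-sensitivity curve.

Sign convention: delta = detected - ground truth, so positive means the
detector is late.  All boundary arithmetic is in sample indices;
millisecond conversions belong to reporting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import EventLabel
from .eval_sample import SDTCounts
from .events import Event

__all__ = [
    "MatchConfig",
    "BoundaryMatchResult",
    "extract_boundaries",
    "match_boundaries",
    "rto_rtd",
    "timing_l2_iou",
    "negative_count",
    "boundary_sdt",
    "dprime_sweep",
    "onset_offset_contrast",
]


@dataclass(frozen=True)
class MatchConfig:
    """Boundary-matching settings.

    ``delta_t`` is the window half-width in samples (a pair must satisfy
    |detected - gt| <= delta_t).  ``one_to_one`` pairs greedily in order of
    increasing |delta| and consumes matched GT boundaries, preventing one GT
    boundary from absorbing several detections; many-to-one simply takes
    each detection's nearest GT boundary.
    """

    delta_t: int = 5
    kind: str = "onset"  # {"onset", "offset"}
    label: EventLabel = EventLabel.SACCADE
    one_to_one: bool = True

    def __post_init__(self) -> None:
        if self.delta_t < 0:
            raise ValueError("delta_t must be >= 0")
        if self.kind not in ("onset", "offset"):
            raise ValueError("kind must be 'onset' or 'offset'")


@dataclass
class BoundaryMatchResult:
    """Pairing of detected and GT boundaries with the unmatched residue."""

    pairs: list[tuple[int, int, int]]  # (detected index, gt index, signed delta)
    unmatched_detected: list[int]
    unmatched_gt: list[int]
    delta_t: int
    one_to_one: bool

    @property
    def n_gt(self) -> int:
        return len(self.pairs) + len(self.unmatched_gt)

    @property
    def hit_rate(self) -> float:
        return len(self.pairs) / self.n_gt if self.n_gt else math.nan

    @property
    def deltas(self) -> np.ndarray:
        return np.array([d for _, _, d in self.pairs], dtype=float)


def extract_boundaries(
    events: list[Event], label: EventLabel, kind: str
) -> np.ndarray:
    """Ordered sample indices of the onsets (or offsets) of events of a type."""
    if kind == "onset":
        return np.array(
            [ev.start_index for ev in events if ev.label == label], dtype=int
        )
    if kind == "offset":
        return np.array([ev.end_index for ev in events if ev.label == label], dtype=int)
    raise ValueError("kind must be 'onset' or 'offset'")


def match_boundaries(
    detected: np.ndarray, gt: np.ndarray, cfg: MatchConfig
) -> BoundaryMatchResult:
    """Pair each detected boundary with the nearest GT boundary within the window.

    One-to-one mode assigns pairs greedily in increasing |delta| (ties break
    to the earlier GT boundary, then the earlier detection), consuming both
    members.  Enlarging delta_t only appends candidate pairs to the end of
    the greedy order, so the matched count is non-decreasing in delta_t.
    """
    detected = np.sort(np.asarray(detected, dtype=int))
    gt = np.sort(np.asarray(gt, dtype=int))
    candidates = []
    for d in detected:
        lo = np.searchsorted(gt, d - cfg.delta_t, side="left")
        hi = np.searchsorted(gt, d + cfg.delta_t, side="right")
        for g in gt[lo:hi]:
            candidates.append((abs(int(d) - int(g)), int(g), int(d)))
    candidates.sort()
    pairs: list[tuple[int, int, int]] = []
    if cfg.one_to_one:
        used_d: set[int] = set()
        used_g: set[int] = set()
        for absd, g, d in candidates:
            if d in used_d or g in used_g:
                continue
            used_d.add(d)
            used_g.add(g)
            pairs.append((d, g, d - g))
    else:
        used_d = set()
        for absd, g, d in candidates:
            if d in used_d:
                continue
            used_d.add(d)
            pairs.append((d, g, d - g))
        used_g = {g for _, g, _ in pairs}
    pairs.sort()
    return BoundaryMatchResult(
        pairs=pairs,
        unmatched_detected=[int(d) for d in detected if d not in used_d],
        unmatched_gt=[int(g) for g in gt if g not in used_g],
        delta_t=cfg.delta_t,
        one_to_one=cfg.one_to_one,
    )


def rto_rtd(result: BoundaryMatchResult) -> tuple[float, float]:
    """Relative timing offset and deviation of the matched pairs (samples).

    RTO is the mean signed delta; RTD the sample SD (0 for a single pair).
    No matches -> (nan, nan).
    """
    deltas = result.deltas
    if deltas.size == 0:
        return math.nan, math.nan
    rto = float(deltas.mean())
    rtd = 0.0 if deltas.size == 1 else float(deltas.std(ddof=1))
    return rto, rtd


def timing_l2_iou(detected_ev: Event, gt_ev: Event) -> tuple[float, float]:
    """Temporal l2 distance and intersection-over-union of two events.

    l2 = sqrt(delta_onset^2 + delta_offset^2) in samples; IoU on the
    inclusive sample-index intervals, 0 when disjoint.
    """
    d_on = detected_ev.start_index - gt_ev.start_index
    d_off = detected_ev.end_index - gt_ev.end_index
    l2 = math.hypot(d_on, d_off)
    inter = (
        min(detected_ev.end_index, gt_ev.end_index)
        - max(detected_ev.start_index, gt_ev.start_index)
        + 1
    )
    union = (
        max(detected_ev.end_index, gt_ev.end_index)
        - min(detected_ev.start_index, gt_ev.start_index)
        + 1
    )
    iou = max(inter, 0) / union
    return l2, iou


def negative_count(gt_boundaries: np.ndarray, n_samples: int, delta_t: int) -> int:
    """Number of boundary-free negative windows in the ground truth.

    The recording [0, n_samples) is tiled from sample 0 with consecutive
    non-overlapping windows of 2*delta_t + 1 samples (a final partial
    window is discarded); windows containing no GT boundary are negatives —
    the denominator of the boundary false-alarm rate.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    w = 2 * delta_t + 1
    n_windows = n_samples // w
    if n_windows == 0:
        return 0
    b = np.asarray(gt_boundaries, dtype=int)
    b = b[(b >= 0) & (b < n_windows * w)]
    occupied = np.unique(b // w)
    return int(n_windows - occupied.size)


def boundary_sdt(result: BoundaryMatchResult, negatives: int) -> SDTCounts:
    """Signal-detection counts for a boundary matching.

    Hits are matched detections; misses unmatched GT boundaries; false
    alarms unmatched detections.  TPr = hits / #GT; FAr = FAs / negatives.
    The log-linear correction applies when there are no hits or no false
    alarms (and at the complementary extremes), keeping d' finite whenever
    #GT > 0 and negatives > 0.
    """
    return SDTCounts(
        hits=len(result.pairs),
        misses=len(result.unmatched_gt),
        false_alarms=len(result.unmatched_detected),
        negatives=negatives,
    )


def dprime_sweep(
    detected_events: list[Event],
    gt_events: list[Event],
    label: EventLabel,
    kind: str,
    n_samples: int,
    delta_ts: range | list[int] = range(0, 21),
    one_to_one: bool = True,
) -> pd.DataFrame:
    """Boundary-sensitivity curve: full pipeline per temporal window size.

    For each delta_t, extracts boundaries, matches them, counts negative
    windows, and derives the SDT quantities.  Hits are non-decreasing in
    delta_t under the greedy one-to-one matcher.
    """
    if not len(delta_ts):
        raise ValueError("delta_ts must be non-empty")
    det_b = extract_boundaries(detected_events, label, kind)
    gt_b = extract_boundaries(gt_events, label, kind)
    rows = []
    for dt in delta_ts:
        cfg = MatchConfig(delta_t=int(dt), kind=kind, label=label, one_to_one=one_to_one)
        result = match_boundaries(det_b, gt_b, cfg)
        counts = boundary_sdt(result, negative_count(gt_b, n_samples, int(dt)))
        rto, rtd = rto_rtd(result)
        rows.append(
            {"delta_t": int(dt), "rto": rto, "rtd": rtd,
             "hit_rate": result.hit_rate, **counts.to_dict()}
        )
    return pd.DataFrame(rows).set_index("delta_t")


def onset_offset_contrast(dprimes: pd.DataFrame) -> pd.DataFrame:
    """Paired per-recording onset-vs-offset d' differences.

    Expects columns ``onset_dprime`` and ``offset_dprime`` (plus any
    grouping columns such as detector or recording id); recordings missing
    either member are excluded.  Adds ``diff = onset_dprime -
    offset_dprime``; the caller can feed the diffs to whatever paired test
    suits the design.
    """
    required = {"onset_dprime", "offset_dprime"}
    if not required.issubset(dprimes.columns):
        raise ValueError(f"dprimes must have columns {sorted(required)}")
    out = dprimes.dropna(subset=list(required)).copy()
    out["diff"] = out["onset_dprime"] - out["offset_dprime"]
    if "detector" in out.columns:
        out.attrs["median_diff"] = out.groupby("detector")["diff"].median()
    else:
        out.attrs["median_diff"] = float(out["diff"].median()) if len(out) else math.nan
    return out
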