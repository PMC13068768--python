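"""Threshold-based eye-movement detectors.

Seven classical detectors mapping a :class:`~gazebench.core.GazeRecording`
to a per-sample label sequence:

====================  ==========  ==========================================
detector              thresholds  labels produced
====================  ==========  ==========================================
I-VT                  global      fixation / saccade
I-VVT                 global      fixation / saccade / smooth pursuit
I-DT                  global      fixation / saccade (spatial dispersion)
I-DVT                 global      fixation / saccade / smooth pursuit
Engbert               adaptive    fixation / saccade (median-based SD)
NH                    adaptive    fixation / saccade / PSO
REMoDNaV              adaptive    fixation / saccade / PSO / smooth pursuit
====================  ==========  ==========================================

Missing samples are always labeled BLINK in a pre-pass; every detector ends
with :func:`enforce_durations`, which dissolves sub-minimum event runs.
Pass ``postprocess=False`` to inspect the raw per-sample thresholding.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.signal import savgol_filter

from .core import (
    ConfigurationError,
    ConvergenceError,
    EventLabel,
    GazeRecording,
    compute_velocity,
    velocity_components,
)

__all__ = [
    "DetectorConfig",
    "detect_ivt",
    "detect_ivvt",
    "detect_idt",
    "detect_idvt",
    "detect_engbert",
    "detect_nh",
    "detect_remodnav",
    "enforce_durations",
    "DETECTORS",
]

# threshold floor (°/s) for a degenerate (zero-variance) adaptive axis:
# any strictly nonzero velocity on that axis then counts as saccadic
_DEGENERATE_ETA = 1e-12


@dataclass
class DetectorConfig:
    """Shared detector parameters.

    Defaults follow the thresholds calibrated against human annotation of
    free-viewing image data: 45°/s saccade velocity, 2.7° maximum fixation
    dispersion, 55 ms minimum fixation duration (the I-DT window span),
    26°/s intermediate pursuit threshold, a 2-sample minimum for every
    event type, and a 10 ms minimum saccade duration.  The adaptive
    detectors' internal constants follow their original publications.
    """

    v_sac: float = 45.0        # °/s, saccade/fixation velocity threshold
    v_sp: float = 26.0         # °/s, pursuit/fixation threshold (I-VVT, I-DVT)
    disp_max: float = 2.7      # °, maximum fixation dispersion (I-DT, I-DVT)
    min_fix_ms: float = 55.0   # ms, I-DT initial window span
    max_fix_ms: float | None = 2500.0  # ms, criterion-table upper bound (unused here)
    min_sac_ms: float = 10.0   # ms, minimum saccade duration
    min_event_samples: int = 2  # samples, minimum duration of any event type
    engbert_lambda: float = 6.0  # multiplier on the median-based velocity SD

    # Nyström–Holmqvist internals
    nh_pt_init: float = 100.0      # °/s, initial peak threshold
    nh_peak_mult: float = 6.0      # PT = centre + 6·spread of sub-PT samples
    nh_onset_mult: float = 3.0     # onset threshold = centre + 3·spread
    nh_tol: float = 1.0            # °/s, peak-threshold convergence tolerance
    nh_max_iter: int = 100
    nh_savgol_order: int = 2
    nh_savgol_ms: float | None = None  # smoothing span; defaults to 2·min_sac_ms
    nh_pso_window_ms: float = 40.0     # how far past offset a PSO may start/extend

    # REMoDNaV internals
    rdn_pursuit_threshold: float = 2.0   # °/s, on the smoothed drift velocity
    rdn_pursuit_window_ms: float = 100.0  # drift-velocity smoothing span
    rdn_min_chunk_ms: float = 100.0      # shorter chunks inherit the global threshold

    def __post_init__(self) -> None:
        for name in ("v_sac", "v_sp", "disp_max", "min_fix_ms", "min_sac_ms"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be strictly positive")
        if self.min_event_samples < 1:
            raise ConfigurationError("min_event_samples must be >= 1")
        if self.engbert_lambda <= 0:
            raise ConfigurationError("engbert_lambda must be strictly positive")

    def to_dict(self) -> dict:
        return asdict(self)


def _ms_to_samples(ms: float, rate: float) -> int:
    # ceiling: a minimum duration must not be undershot by rounding
    return int(math.ceil(ms * rate / 1000.0))


def _blank_labels(rec: GazeRecording) -> np.ndarray:
    labels = np.full(rec.n_samples, int(EventLabel.FIXATION), dtype=np.int8)
    labels[rec.missing] = int(EventLabel.BLINK)
    return labels


def _run_lengths(labels: np.ndarray) -> list[tuple[int, int, int]]:
    """Maximal runs as (label, start, end) with inclusive ends."""
    labels = np.asarray(labels)
    if labels.size == 0:
        return []
    change = np.flatnonzero(np.diff(labels)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change - 1, [labels.size - 1]))
    return [(int(labels[s]), int(s), int(e)) for s, e in zip(starts, ends)]


# ---------------------------------------------------------------------------
# duration enforcement
# ---------------------------------------------------------------------------

def enforce_durations(
    labels: np.ndarray, rec: GazeRecording, cfg: DetectorConfig
) -> np.ndarray:
    """Dissolve event runs shorter than their minimum duration.

    Every non-BLINK run shorter than ``min_event_samples`` (or, for
    saccades, shorter than ``min_sac_ms``) is merged into the longer
    non-BLINK flanking run (ties go to the preceding run).  BLINK runs are
    never dissolved.  The result contains no surviving sub-minimum
    non-blink run, and the operation is idempotent.
    """
    labels = np.asarray(labels).copy()
    if labels.size != rec.n_samples:
        raise ConfigurationError("labels and recording lengths differ")
    min_sac = max(cfg.min_event_samples, _ms_to_samples(cfg.min_sac_ms, rec.sampling_rate))

    def min_len(label: int) -> int:
        return min_sac if label == EventLabel.SACCADE else cfg.min_event_samples

    while True:
        runs = _run_lengths(labels)
        dissolved = False
        for k, (lab, s, e) in enumerate(runs):
            if lab == EventLabel.BLINK:
                continue
            if e - s + 1 >= min_len(lab):
                continue
            prev_run = runs[k - 1] if k > 0 else None
            next_run = runs[k + 1] if k + 1 < len(runs) else None
            candidates = [
                r for r in (prev_run, next_run)
                if r is not None and r[0] != EventLabel.BLINK
            ]
            if not candidates:
                continue  # isolated between blinks/edges: nothing to merge into
            # longer flank wins; ties go to the preceding run
            target = max(candidates, key=lambda r: (r[2] - r[1] + 1, r is prev_run))
            labels[s : e + 1] = target[0]
            dissolved = True
            break
        if not dissolved:
            return labels


# ---------------------------------------------------------------------------
# global-threshold detectors
# ---------------------------------------------------------------------------

def detect_ivt(
    rec: GazeRecording, cfg: DetectorConfig | None = None, *, postprocess: bool = True
) -> np.ndarray:
    """Velocity-threshold detector: saccade where speed exceeds ``v_sac``.

    Samples with undefined velocity but valid coordinates default to
    FIXATION (the resting state).
    """
    cfg = cfg or DetectorConfig()
    v = compute_velocity(rec, "sample_diff")
    labels = _blank_labels(rec)
    ok = ~rec.missing
    labels[ok & (v > cfg.v_sac)] = int(EventLabel.SACCADE)
    return enforce_durations(labels, rec, cfg) if postprocess else labels


def detect_ivvt(
    rec: GazeRecording, cfg: DetectorConfig | None = None, *, postprocess: bool = True
) -> np.ndarray:
    """Two-threshold velocity detector: adds a pursuit band ``(v_sp, v_sac]``."""
    cfg = cfg or DetectorConfig()
    if cfg.v_sp >= cfg.v_sac:
        raise ConfigurationError(
            f"v_sp ({cfg.v_sp}) must be below v_sac ({cfg.v_sac})"
        )
    v = compute_velocity(rec, "sample_diff")
    labels = _blank_labels(rec)
    ok = ~rec.missing
    labels[ok & (v > cfg.v_sp)] = int(EventLabel.SMOOTH_PURSUIT)
    labels[ok & (v > cfg.v_sac)] = int(EventLabel.SACCADE)
    return enforce_durations(labels, rec, cfg) if postprocess else labels


def _idt_fixation_mask(rec: GazeRecording, cfg: DetectorConfig) -> np.ndarray:
    """Sliding-window dispersion protocol; True where a sample is fixational.

    A window of the minimum fixation duration is grown while its dispersion
    stays at or below ``disp_max``; on exceeding, the grown window minus its
    last sample is a fixation and the last sample is not.  If the initial
    window already exceeds the threshold its first sample is non-fixational
    and the window slides by one.  A terminal window still under threshold
    is wholly fixational.  Runs on each contiguous valid segment.
    """
    w0 = max(2, _ms_to_samples(cfg.min_fix_ms, rec.sampling_rate))
    fix = np.zeros(rec.n_samples, dtype=bool)
    x, y = rec.x, rec.y
    for _, a, b in _run_lengths(rec.missing.astype(np.int8)):
        if rec.missing[a]:
            continue
        i = a
        while i <= b:
            j = i + w0 - 1
            if j > b:
                fix[i : b + 1] = True  # terminal under-length window
                break
            xmin, xmax = x[i : j + 1].min(), x[i : j + 1].max()
            ymin, ymax = y[i : j + 1].min(), y[i : j + 1].max()
            if (xmax - xmin) + (ymax - ymin) > cfg.disp_max:
                i += 1  # initial window dispersed: first sample is not a fixation
                continue
            while j + 1 <= b:
                nx, ny = x[j + 1], y[j + 1]
                txmin, txmax = min(xmin, nx), max(xmax, nx)
                tymin, tymax = min(ymin, ny), max(ymax, ny)
                if (txmax - txmin) + (tymax - tymin) > cfg.disp_max:
                    break
                xmin, xmax, ymin, ymax = txmin, txmax, tymin, tymax
                j += 1
            if j + 1 > b:
                fix[i : b + 1] = True  # trace ended while under threshold
                break
            # window [i..j+1] exceeded: fixation up to j, sample j+1 is not
            fix[i : j + 1] = True
            i = j + 2
    return fix


def detect_idt(
    rec: GazeRecording, cfg: DetectorConfig | None = None, *, postprocess: bool = True
) -> np.ndarray:
    """Dispersion-threshold detector: non-fixational samples become saccades."""
    cfg = cfg or DetectorConfig()
    labels = _blank_labels(rec)
    fix = _idt_fixation_mask(rec, cfg)
    labels[~rec.missing & ~fix] = int(EventLabel.SACCADE)
    return enforce_durations(labels, rec, cfg) if postprocess else labels


def detect_idvt(
    rec: GazeRecording, cfg: DetectorConfig | None = None, *, postprocess: bool = True
) -> np.ndarray:
    """Dispersion + velocity detector.

    Fixations from the I-DT protocol; remaining samples split into saccades
    (speed above ``v_sac``) and smooth pursuit.
    """
    cfg = cfg or DetectorConfig()
    labels = _blank_labels(rec)
    fix = _idt_fixation_mask(rec, cfg)
    v = compute_velocity(rec, "sample_diff")
    rest = ~rec.missing & ~fix
    labels[rest] = int(EventLabel.SMOOTH_PURSUIT)
    # undefined velocity on a non-fixational sample defaults to saccade,
    # matching what plain I-DT would have called it
    labels[rest & ((v > cfg.v_sac) | np.isnan(v))] = int(EventLabel.SACCADE)
    return enforce_durations(labels, rec, cfg) if postprocess else labels


# ---------------------------------------------------------------------------
# Engbert adaptive detector
# ---------------------------------------------------------------------------

def _median_sd(v: np.ndarray) -> float:
    """Median-based standard deviation: sqrt(median(v^2) - median(v)^2)."""
    v = v[~np.isnan(v)]
    var = float(np.median(v**2) - np.median(v) ** 2)
    return math.sqrt(var) if var > 0 else 0.0


def detect_engbert(
    rec: GazeRecording,
    cfg: DetectorConfig | None = None,
    *,
    postprocess: bool = True,
    return_info: bool = False,
):
    """Adaptive velocity-threshold detector of Engbert & Kliegl.

    Velocities come from the 5-sample moving-window difference; each axis
    gets a threshold ``eta = lambda * median-based SD`` computed over the
    whole recording, and a sample is saccadic when it falls outside the
    ellipse ``(vx/eta_x)^2 + (vy/eta_y)^2 > 1``.  A zero-variance axis
    degenerates to "any nonzero velocity is saccadic" (with a warning),
    so a perfectly constant trace is all-FIXATION.
    """
    cfg = cfg or DetectorConfig()
    vx, vy = velocity_components(rec, "moving_window")
    etas = []
    for v in (vx, vy):
        sd = _median_sd(v)
        if sd == 0.0:
            warnings.warn(
                "degenerate Engbert threshold (zero median-based SD on an axis); "
                "any nonzero velocity on that axis counts as saccadic",
                stacklevel=2,
            )
            etas.append(_DEGENERATE_ETA)
        else:
            etas.append(cfg.engbert_lambda * sd)
    eta_x, eta_y = etas
    labels = _blank_labels(rec)
    ok = ~rec.missing & ~np.isnan(vx) & ~np.isnan(vy)
    with np.errstate(over="ignore"):
        radial = np.zeros(rec.n_samples)
        radial[ok] = (vx[ok] / eta_x) ** 2 + (vy[ok] / eta_y) ** 2
    labels[ok & (radial > 1.0)] = int(EventLabel.SACCADE)
    out = enforce_durations(labels, rec, cfg) if postprocess else labels
    if return_info:
        return out, {"eta_x": eta_x, "eta_y": eta_y}
    return out


# ---------------------------------------------------------------------------
# NH and REMoDNaV adaptive detectors
# ---------------------------------------------------------------------------

def _savgol_speed(rec: GazeRecording, cfg: DetectorConfig) -> np.ndarray:
    """Savitzky–Golay-smoothed speed, NaN over short/missing spans."""
    span_ms = cfg.nh_savgol_ms if cfg.nh_savgol_ms is not None else 2.0 * cfg.min_sac_ms
    w = _ms_to_samples(span_ms, rec.sampling_rate)
    w = max(w, cfg.nh_savgol_order + 2)
    if w % 2 == 0:
        w += 1
    v = np.full(rec.n_samples, np.nan)
    delta = 1.0 / rec.sampling_rate
    for _, a, b in _run_lengths(rec.missing.astype(np.int8)):
        if rec.missing[a]:
            continue
        seg = slice(a, b + 1)
        if b - a + 1 < w:
            continue  # too short to smooth; left undefined -> fixation
        dx = savgol_filter(rec.x[seg], w, cfg.nh_savgol_order, deriv=1, delta=delta)
        dy = savgol_filter(rec.y[seg], w, cfg.nh_savgol_order, deriv=1, delta=delta)
        v[seg] = np.hypot(dx, dy)
    return v


def _iterative_threshold(
    v: np.ndarray, cfg: DetectorConfig, robust: bool
) -> tuple[float, float] | None:
    """Data-driven peak/onset thresholds from sub-threshold velocity noise.

    Iterates ``PT_{k+1} = centre + peak_mult * spread`` over the samples
    below ``PT_k``, starting at ``nh_pt_init``, until the change is below
    ``nh_tol``.  ``centre``/``spread`` are mean/SD, or median/1.4826·MAD in
    robust mode.  Returns (peak_threshold, onset_threshold), or None when
    the velocity distribution is degenerate (no detectable peaks).
    """
    v = v[~np.isnan(v)]
    pt = cfg.nh_pt_init
    last = pt
    for _ in range(cfg.nh_max_iter):
        below = v[v < pt]
        if below.size < 2:
            return None
        if robust:
            centre = float(np.median(below))
            spread = 1.4826 * float(np.median(np.abs(below - centre)))
        else:
            centre = float(below.mean())
            spread = float(below.std())
        if spread < 1e-6:  # °/s: numerically still data has no detectable peaks
            return None
        new = centre + cfg.nh_peak_mult * spread
        if abs(new - pt) < cfg.nh_tol:
            onset = centre + cfg.nh_onset_mult * spread
            return new, onset
        last, pt = pt, new
    raise ConvergenceError(
        f"peak-threshold iteration did not converge in {cfg.nh_max_iter} steps "
        f"(last PT = {last:.3f} °/s)"
    )


def _label_saccades_psos(
    labels: np.ndarray,
    v: np.ndarray,
    lo: int,
    hi: int,
    pt: float,
    onset_th: float,
    cfg: DetectorConfig,
    rate: float,
) -> None:
    """Walk each supra-PT peak run outwards to onset/offset, then tag PSOs.

    Operates in place on ``labels`` within the inclusive span [lo, hi].
    The saccade onset is the first local velocity minimum below the onset
    threshold when walking backward from the peak; the offset is found
    analogously forward.  A post-saccadic oscillation is labeled where the
    velocity re-exceeds the onset threshold within ``nh_pso_window_ms`` of
    the offset while staying below the peak threshold.
    """
    pso_w = _ms_to_samples(cfg.nh_pso_window_ms, rate)
    i = lo
    spans: list[tuple[int, int]] = []
    while i <= hi:
        if not (not np.isnan(v[i]) and v[i] > pt):
            i += 1
            continue
        run_start = i
        while i + 1 <= hi and not np.isnan(v[i + 1]) and v[i + 1] > pt:
            i += 1
        run_end = i
        # backward to onset
        on = run_start
        k = run_start - 1
        while k >= lo and not np.isnan(v[k]):
            if v[k] < onset_th and (k == lo or np.isnan(v[k - 1]) or v[k - 1] >= v[k]):
                on = k
                break
            k -= 1
        else:
            on = max(k + 1, lo)
        # forward to offset
        off = run_end
        k = run_end + 1
        while k <= hi and not np.isnan(v[k]):
            if v[k] < onset_th and (k == hi or np.isnan(v[k + 1]) or v[k + 1] >= v[k]):
                off = k
                break
            k += 1
        else:
            off = min(k - 1, hi)
        spans.append((on, off))
        i = off + 1
    for on, off in spans:
        labels[on : off + 1] = int(EventLabel.SACCADE)
        # PSO: a bounded re-excursion above the onset threshold after offset
        j_max = min(off + pso_w, hi)
        window = v[off + 1 : j_max + 1]
        if window.size == 0 or np.isnan(window).all():
            continue
        if np.nanmax(window) >= pt:
            continue  # another full saccade follows; not an oscillation
        above = np.flatnonzero(window > onset_th)
        if above.size == 0:
            continue
        pso_end = off + 1 + above[-1]
        labels[off + 1 : pso_end + 1] = int(EventLabel.PSO)


def detect_nh(
    rec: GazeRecording,
    cfg: DetectorConfig | None = None,
    *,
    postprocess: bool = True,
    return_info: bool = False,
):
    """Nyström–Holmqvist adaptive detector: saccades plus PSOs.

    Smooths position with a Savitzky–Golay filter, derives a data-driven
    peak velocity threshold by iterating ``mean + 6·SD`` over sub-threshold
    samples, walks each peak backwards/forwards to its onset/offset, and
    labels a PSO where velocity re-exceeds the onset threshold shortly
    after the offset.  Everything else is fixation.
    """
    cfg = cfg or DetectorConfig()
    v = _savgol_speed(rec, cfg)
    labels = _blank_labels(rec)
    est = _iterative_threshold(v, cfg, robust=False)
    info = {"peak_threshold": None, "onset_threshold": None}
    if est is not None:
        pt, onset_th = est
        info = {"peak_threshold": pt, "onset_threshold": onset_th}
        for _, a, b in _run_lengths(rec.missing.astype(np.int8)):
            if not rec.missing[a]:
                _label_saccades_psos(labels, v, a, b, pt, onset_th, cfg, rec.sampling_rate)
    out = enforce_durations(labels, rec, cfg) if postprocess else labels
    return (out, info) if return_info else out


def detect_remodnav(
    rec: GazeRecording,
    cfg: DetectorConfig | None = None,
    *,
    postprocess: bool = True,
    return_info: bool = False,
):
    """Chunked robust adaptive detector with smooth-pursuit support.

    Major saccades are found with a global NH-style threshold; the data are
    then split into chunks at major-saccade onsets, and each chunk long
    enough recomputes a locally adaptive threshold from robust statistics
    (median + 6·1.4826·MAD), labeling saccades and PSOs as in the NH
    detector.  Remaining low-velocity spans become smooth pursuit where a
    low-pass-filtered velocity exceeds ``rdn_pursuit_threshold``, else
    fixation.  Chunks shorter than ``rdn_min_chunk_ms`` inherit the global
    threshold.
    """
    cfg = cfg or DetectorConfig()
    v = _savgol_speed(rec, cfg)
    labels = _blank_labels(rec)
    info: dict = {"global": None, "chunks": []}
    est = _iterative_threshold(v, cfg, robust=False)
    if est is not None:
        pt_g, onset_g = est
        info["global"] = {"peak_threshold": pt_g, "onset_threshold": onset_g}
        min_chunk = _ms_to_samples(cfg.rdn_min_chunk_ms, rec.sampling_rate)
        for _, a, b in _run_lengths(rec.missing.astype(np.int8)):
            if rec.missing[a]:
                continue
            seg_v = v[a : b + 1]
            supra = ~np.isnan(seg_v) & (seg_v > pt_g)
            starts = [
                a + s for lab, s, _ in _run_lengths(supra.astype(np.int8)) if lab == 1
            ]
            cuts = [a] + [s for s in starts if s > a] + [b + 1]
            for lo, hi in zip(cuts[:-1], cuts[1:]):
                hi -= 1
                if hi < lo:
                    continue
                local = None
                if hi - lo + 1 >= min_chunk:
                    local = _iterative_threshold(v[lo : hi + 1], cfg, robust=True)
                pt, onset_th = local if local is not None else (pt_g, onset_g)
                info["chunks"].append(
                    {"start": lo, "end": hi, "peak_threshold": pt,
                     "onset_threshold": onset_th}
                )
                _label_saccades_psos(labels, v, lo, hi, pt, onset_th, cfg,
                                     rec.sampling_rate)
    # pursuit pass on the remaining low-velocity spans
    _mark_pursuit(labels, rec, cfg)
    out = enforce_durations(labels, rec, cfg) if postprocess else labels
    return (out, info) if return_info else out


def _mark_pursuit(labels: np.ndarray, rec: GazeRecording, cfg: DetectorConfig) -> None:
    """Relabel slow drifts within the still-unlabeled spans as smooth pursuit.

    Each maximal unlabeled (fixation-candidate) span is treated on its own
    — drift velocity is rebuilt from the span's positions only, so saccade
    displacement cannot leak in.  The drift estimate is the
    Savitzky–Golay slope over ``rdn_pursuit_window_ms`` (a quadratic local
    fit suppresses fixational jitter by orders of magnitude while passing a
    constant-velocity drift unchanged); spans shorter than the window fall
    back to their mean drift speed.
    """
    rate = rec.sampling_rate
    w = _ms_to_samples(cfg.rdn_pursuit_window_ms, rate)
    if w % 2 == 0:
        w += 1
    w = max(w, 5)
    fix = int(EventLabel.FIXATION)
    for lab, lo, hi in _run_lengths(labels):
        if lab != fix or rec.missing[lo]:
            continue
        n = hi - lo + 1
        if n < 2:
            continue
        seg = slice(lo, hi + 1)
        if n >= w:
            dx = savgol_filter(rec.x[seg], w, 2, deriv=1, delta=1.0 / rate)
            dy = savgol_filter(rec.y[seg], w, 2, deriv=1, delta=1.0 / rate)
            mask = np.hypot(dx, dy) > cfg.rdn_pursuit_threshold
        else:
            drift = np.hypot(
                (rec.x[hi] - rec.x[lo]) * rate / (n - 1),
                (rec.y[hi] - rec.y[lo]) * rate / (n - 1),
            )
            mask = np.full(n, drift > cfg.rdn_pursuit_threshold)
        labels[seg][mask] = int(EventLabel.SMOOTH_PURSUIT)


DETECTORS = {
    "ivt": detect_ivt,
    "ivvt": detect_ivvt,
    "idt": detect_idt,
    "idvt": detect_idvt,
    "engbert": detect_engbert,
    "nh": detect_nh,
    "remodnav": detect_remodnav,
}
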