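"""Seeded synthetic gaze generator with known ground-truth labels.

Emulates a fixation-dominated monocular recording from a high-speed
(250-1000 Hz) screen-based eye tracker: stationary fixations with Gaussian
jitter, logistic-profile saccades whose duration and peak velocity follow a
main-sequence rule, optional decaying-oscillation post-saccadic wobble,
and blink gaps of missing signal.  Every draw flows from one explicit seed,
so a simulation is bit-reproducible.

The generator is the test substrate standing in for human-annotated
recordings: its schedule *is* the ground truth, which real annotation only
approximates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .core import ConfigurationError, EventLabel, GazeRecording
from .events import Event, labels_to_events

__all__ = [
    "SimulationConfig",
    "LabeledSimulation",
    "generate",
    "generate_pursuit_segment",
    "jitter_boundaries",
    "degrade",
]


@dataclass
class SimulationConfig:
    """Parameters of a simulated free-viewing recording.

    The main sequence maps saccade amplitude A (degrees) to duration
    ``main_seq_slope * A + main_seq_intercept`` ms; peak velocity follows
    from the logistic waveform's analytic maximum.  Fixation durations are
    normal, truncated below at ``fixation_min_ms``.  Amplitudes are uniform
    in ``saccade_amplitude_range``; the 2.5° lower bound keeps mean saccade
    speed well clear of fixational noise at free-viewing scale.
    """

    sampling_rate: float = 500.0  # Hz
    n_saccades: int = 20
    fixation_mean_ms: float = 250.0
    fixation_sd_ms: float = 100.0
    fixation_min_ms: float = 60.0
    saccade_amplitude_range: tuple[float, float] = (2.5, 8.0)  # degrees
    main_seq_slope: float = 2.2      # ms per degree
    main_seq_intercept: float = 21.0  # ms
    pso_probability: float = 0.25
    pso_amplitude: float = 0.4       # degrees
    pso_frequency_hz: float = 50.0
    pso_duration_ms: float = 20.0
    pso_decay_ms: float = 8.0
    noise_sd: float = 0.02           # degrees, fixational jitter
    blink_probability: float = 0.05  # per fixation
    blink_duration_ms: float = 150.0
    field_halfwidth: float = 12.0    # degrees, gaze kept inside +/- this
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ConfigurationError("sampling_rate must be positive")
        if self.n_saccades < 0:
            raise ConfigurationError("n_saccades must be >= 0")
        lo, hi = self.saccade_amplitude_range
        if not (0 < lo <= hi):
            raise ConfigurationError("saccade amplitudes must be positive, lo <= hi")
        if self.noise_sd < 0 or not (0 <= self.pso_probability <= 1):
            raise ConfigurationError("invalid noise/probability settings")


@dataclass
class LabeledSimulation:
    """A generated recording with its ground-truth labels and events."""

    recording: GazeRecording
    labels: np.ndarray
    events: list[Event] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.events:
            self.events = labels_to_events(self.labels, self.recording)


# logistic waveform truncated to its central 15-85% span and renormalized;
# keeps edge sample-to-sample velocities above the global saccade threshold
_LOGISTIC_TRUNC = 0.15


def _saccade_profile(m: int) -> np.ndarray:
    """Normalized displacement at the m saccade samples, from 0 to 1.

    The first saccade-labeled sample sits exactly at the launch position
    (phase 0) and the last exactly at the landing position (phase 1), so
    the scheduled labels bracket the samples where displacement occurs.
    """
    if m < 2:
        raise ConfigurationError("a saccade needs at least 2 samples")
    p = _LOGISTIC_TRUNC
    half = math.log((1 - p) / p)  # logistic argument at the truncation point
    u = np.linspace(-half, half, m)
    sig = 1.0 / (1.0 + np.exp(-u))
    return (sig - p) / (1.0 - 2.0 * p)


def saccade_peak_velocity(amplitude: float, duration_ms: float) -> float:
    """Analytic peak velocity (°/s) of the truncated-logistic waveform."""
    p = _LOGISTIC_TRUNC
    k = 2.0 * math.log((1 - p) / p) / (duration_ms / 1000.0)
    return amplitude * k / 4.0 / (1.0 - 2.0 * p)


def generate(cfg: SimulationConfig) -> LabeledSimulation:
    """Simulate one labeled recording from an alternating schedule.

    The schedule is fixation, then for each saccade: saccade, optional PSO,
    fixation; blinks replace a span inside a fixation with missing samples.
    """
    rng = np.random.default_rng(cfg.seed)
    rate = cfg.sampling_rate

    def ms_to_n(ms: float) -> int:
        return max(1, int(round(ms * rate / 1000.0)))

    def fixation_n() -> int:
        dur = rng.normal(cfg.fixation_mean_ms, cfg.fixation_sd_ms)
        return ms_to_n(max(dur, cfg.fixation_min_ms))

    x_parts: list[np.ndarray] = []
    y_parts: list[np.ndarray] = []
    label_parts: list[np.ndarray] = []

    def emit_fixation(pos: np.ndarray, n: int) -> None:
        n_blink = 0
        if rng.random() < cfg.blink_probability:
            n_blink = ms_to_n(cfg.blink_duration_ms)
        if n_blink and n >= 3 * cfg_min_run:
            # blink in the middle of the fixation, flanked by visible spans
            n_a = max(cfg_min_run, n // 3)
            n_b = max(cfg_min_run, n - n_a)
            for part_n, blink in ((n_a, False), (n_blink, True), (n_b, False)):
                if blink:
                    x_parts.append(np.full(part_n, np.nan))
                    y_parts.append(np.full(part_n, np.nan))
                    label_parts.append(
                        np.full(part_n, int(EventLabel.BLINK), dtype=np.int8)
                    )
                else:
                    x_parts.append(pos[0] + rng.normal(0, cfg.noise_sd, part_n))
                    y_parts.append(pos[1] + rng.normal(0, cfg.noise_sd, part_n))
                    label_parts.append(
                        np.full(part_n, int(EventLabel.FIXATION), dtype=np.int8)
                    )
        else:
            x_parts.append(pos[0] + rng.normal(0, cfg.noise_sd, n))
            y_parts.append(pos[1] + rng.normal(0, cfg.noise_sd, n))
            label_parts.append(np.full(n, int(EventLabel.FIXATION), dtype=np.int8))

    cfg_min_run = 2
    pos = rng.uniform(-cfg.field_halfwidth / 2, cfg.field_halfwidth / 2, 2)
    emit_fixation(pos, fixation_n())
    for _ in range(cfg.n_saccades):
        amp = rng.uniform(*cfg.saccade_amplitude_range)
        theta = rng.uniform(0, 2 * math.pi)
        step = amp * np.array([math.cos(theta), math.sin(theta)])
        # reflect the direction if the landing point would leave the field
        for axis in range(2):
            if abs(pos[axis] + step[axis]) > cfg.field_halfwidth:
                step[axis] = -step[axis]
        target = pos + step
        dur_ms = cfg.main_seq_slope * amp + cfg.main_seq_intercept
        m = max(2, int(math.ceil(dur_ms * rate / 1000.0)))
        profile = _saccade_profile(m)
        x_parts.append(pos[0] + step[0] * profile)
        y_parts.append(pos[1] + step[1] * profile)
        label_parts.append(np.full(m, int(EventLabel.SACCADE), dtype=np.int8))
        pos = target
        if rng.random() < cfg.pso_probability:
            n_pso = ms_to_n(cfg.pso_duration_ms)
            t = np.arange(1, n_pso + 1) / rate  # seconds after landing
            ring = (
                cfg.pso_amplitude
                * np.exp(-t / (cfg.pso_decay_ms / 1000.0))
                * np.sin(2 * math.pi * cfg.pso_frequency_hz * t)
            )
            direction = step / np.linalg.norm(step)
            x_parts.append(pos[0] + ring * direction[0])
            y_parts.append(pos[1] + ring * direction[1])
            label_parts.append(np.full(n_pso, int(EventLabel.PSO), dtype=np.int8))
        emit_fixation(pos, fixation_n())

    x = np.concatenate(x_parts)
    y = np.concatenate(y_parts)
    labels = np.concatenate(label_parts)
    n = x.size
    t = np.arange(n) * (1000.0 / rate)
    rec = GazeRecording(t=t, x=x, y=y, sampling_rate=rate)
    return LabeledSimulation(recording=rec, labels=labels)


def generate_pursuit_segment(
    duration_ms: float = 400.0,
    speed: float = 30.0,
    sampling_rate: float = 500.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> LabeledSimulation:
    """A constant-velocity drift segment bracketed by fixations.

    A minimal smooth-pursuit test input for the detectors that have a
    pursuit class; not a model of target tracking.
    """
    rng = np.random.default_rng(seed)
    rate = sampling_rate
    n_fix = int(round(0.4 * rate))
    n_sp = int(round(duration_ms * rate / 1000.0))
    drift = speed * np.arange(1, n_sp + 1) / rate
    x = np.concatenate([np.zeros(n_fix), drift, np.full(n_fix, drift[-1])])
    x = x + rng.normal(0, noise_sd, x.size)
    y = rng.normal(0, noise_sd, x.size)
    labels = np.concatenate(
        [
            np.full(n_fix, int(EventLabel.FIXATION), dtype=np.int8),
            np.full(n_sp, int(EventLabel.SMOOTH_PURSUIT), dtype=np.int8),
            np.full(n_fix, int(EventLabel.FIXATION), dtype=np.int8),
        ]
    )
    t = np.arange(x.size) * (1000.0 / rate)
    rec = GazeRecording(t=t, x=x, y=y, sampling_rate=rate)
    return LabeledSimulation(recording=rec, labels=labels)


def jitter_boundaries(
    labels: np.ndarray, mu: float, sigma: float, seed: int
) -> np.ndarray:
    """Displace every event boundary by a discretized normal draw.

    Each internal run boundary moves by ``round(N(mu, sigma))`` samples,
    clamped so the run order is preserved and every run keeps at least one
    sample.  The run labels and their order are untouched, which makes the
    construction an exact test harness for RTO/RTD recovery.
    """
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    bounds = np.flatnonzero(np.diff(labels)) + 1  # internal run starts
    if bounds.size == 0:
        return labels.copy()
    run_labels = np.concatenate(([labels[0]], labels[bounds]))
    draws = np.rint(rng.normal(mu, sigma, bounds.size)).astype(int)
    new = bounds + draws
    n = labels.size
    k = bounds.size
    # forward pass: strictly increasing, leaving >= 1 sample per run
    prev = 0
    for i in range(k):
        new[i] = max(new[i], prev + 1)
        prev = new[i]
    # backward pass: clip against the end of the recording
    nxt = n
    for i in range(k - 1, -1, -1):
        new[i] = min(new[i], nxt - 1)
        nxt = new[i]
    out = np.empty(n, dtype=labels.dtype)
    starts = np.concatenate(([0], new))
    ends = np.concatenate((new, [n]))
    for lab, s, e in zip(run_labels, starts, ends):
        out[s:e] = lab
    return out


def degrade(labels: np.ndarray, flip_rate: float, seed: int) -> np.ndarray:
    """Independently flip each sample label with probability ``flip_rate``.

    A flipped sample takes a uniform draw from the *other* labels present
    in the sequence (falling back to the full label set when the sequence
    is constant), so agreement metrics decay smoothly toward chance as
    flip_rate rises.
    """
    if not 0 <= flip_rate <= 1:
        raise ConfigurationError("flip_rate must be in [0, 1]")
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    alphabet = np.unique(labels)
    if alphabet.size < 2:
        alphabet = np.array([int(v) for v in EventLabel], dtype=labels.dtype)
    out = labels.copy()
    flip = rng.random(labels.size) < flip_rate
    idx = np.flatnonzero(flip)
    for i in idx:
        others = alphabet[alphabet != out[i]]
        out[i] = others[rng.integers(others.size)]
    return out
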