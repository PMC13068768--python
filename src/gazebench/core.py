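"""Core gaze-data containers and per-sample kinematics.

Degrees of visual angle are the canonical internal unit: every detection
threshold in this package is angular, so pixel-based recordings must be
converted up front with :func:`pixels_to_degrees` and a
:class:`ViewerGeometry`.  Missing samples (blinks, track loss) are encoded
as NaN coordinates and propagate as undefined velocities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np

__all__ = [
    "EventLabel",
    "ViewerGeometry",
    "GazeRecording",
    "ConfigurationError",
    "InsufficientDataError",
    "AlignmentError",
    "ConvergenceError",
    "pixels_to_degrees",
    "compute_velocity",
    "velocity_components",
    "compute_dispersion",
]


class ConfigurationError(ValueError):
    """Invalid geometry, thresholds, or other configuration."""


class InsufficientDataError(ValueError):
    """Too few valid samples for the requested computation."""


class AlignmentError(ValueError):
    """Label sequence and recording lengths do not match."""


class ConvergenceError(RuntimeError):
    """An iterative threshold estimate failed to converge."""


class EventLabel(IntEnum):
    """Closed set of per-sample eye-movement labels.

    UNDEFINED is the only fallback; BLINK marks spans of missing signal.
    """

    UNDEFINED = 0
    FIXATION = 1
    SACCADE = 2
    PSO = 3
    SMOOTH_PURSUIT = 4
    BLINK = 5


@dataclass(frozen=True)
class ViewerGeometry:
    """Viewing distance and screen pixel pitch, both in centimetres.

    Needed to express pixel gaze coordinates in degrees of visual angle,
    relative to an origin at the screen point nearest the eye.
    """

    viewing_distance: float  # cm
    pixel_pitch: float  # cm per pixel

    def __post_init__(self) -> None:
        if not (self.viewing_distance > 0 and self.pixel_pitch > 0):
            raise ConfigurationError(
                "viewing_distance and pixel_pitch must be strictly positive, "
                f"got {self.viewing_distance} cm and {self.pixel_pitch} cm/px"
            )


# relative tolerance for "uniformly sampled" timestamp spacing
_UNIFORMITY_RTOL = 0.01


@dataclass
class GazeRecording:
    """A uniformly sampled monocular gaze time series.

    Parameters
    ----------
    t : ndarray
        Timestamps in milliseconds, strictly increasing.
    x, y : ndarray
        Gaze position in degrees visual angle. NaN marks missing samples.
    sampling_rate : float, optional
        Hz. Inferred from the median timestamp spacing when omitted; a
        supplied value inconsistent with the timestamps (beyond 1% of the
        nominal period) triggers a warning and the timestamps win.
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    sampling_rate: float | None = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        n = self.t.size
        if not (self.x.size == n and self.y.size == n):
            raise AlignmentError(
                f"t, x, y must have equal length; got {n}, {self.x.size}, {self.y.size}"
            )
        if n < 2:
            raise InsufficientDataError("a recording needs at least 2 samples")
        dt = np.diff(self.t)
        if np.any(dt <= 0):
            raise ConfigurationError("timestamps must be strictly increasing")
        period = float(np.median(dt))
        if np.any(np.abs(dt - period) > _UNIFORMITY_RTOL * period):
            warnings.warn(
                "timestamp spacing deviates from uniform by more than 1%; "
                "trusting timestamps over the nominal rate",
                stacklevel=2,
            )
        inferred = 1000.0 / period
        if self.sampling_rate is None:
            self.sampling_rate = inferred
        else:
            if self.sampling_rate <= 0:
                raise ConfigurationError("sampling_rate must be positive")
            if abs(self.sampling_rate - inferred) > _UNIFORMITY_RTOL * inferred:
                warnings.warn(
                    f"declared sampling rate {self.sampling_rate:g} Hz is inconsistent "
                    f"with median timestamp spacing ({inferred:g} Hz); using timestamps",
                    stacklevel=2,
                )
                self.sampling_rate = inferred

    @property
    def n_samples(self) -> int:
        return self.t.size

    @property
    def period_ms(self) -> float:
        return 1000.0 / self.sampling_rate

    @property
    def missing(self) -> np.ndarray:
        """Boolean mask of samples with undefined coordinates."""
        return np.isnan(self.x) | np.isnan(self.y)


def pixels_to_degrees(
    x_px: np.ndarray,
    y_px: np.ndarray,
    geom: ViewerGeometry,
    origin: tuple[float, float] = (0.0, 0.0),
) -> tuple[np.ndarray, np.ndarray]:
    """Map pixel coordinates to degrees of visual angle.

    The origin (default pixel (0, 0)) is taken as the screen point nearest
    the eye; each coordinate is mapped independently by
    ``atan(offset_px * pixel_pitch / viewing_distance)``, which is monotone
    in the pixel value and linear in the small-angle regime.
    """
    x_px = np.asarray(x_px, dtype=float)
    y_px = np.asarray(y_px, dtype=float)

    def _one(p: np.ndarray, o: float) -> np.ndarray:
        return np.degrees(
            np.arctan((p - o) * geom.pixel_pitch / geom.viewing_distance)
        )

    return _one(x_px, origin[0]), _one(y_px, origin[1])


def velocity_components(
    rec: GazeRecording, method: str = "sample_diff"
) -> tuple[np.ndarray, np.ndarray]:
    """Per-axis angular velocity (°/s), NaN where undefined.

    ``sample_diff``
        The speed of the step (i-1 -> i), stored at index i; index 0 is
        undefined.  This is the velocity used by the global-threshold
        detectors.
    ``moving_window``
        The 5-sample centred difference of Engbert & Kliegl:
        ``v[i] = (x[i+1] + x[i+2] - x[i-1] - x[i-2]) * rate / 6``.
        The first and last two samples are undefined.

    Velocities touching a missing sample are undefined (NaN).
    """
    valid = (~rec.missing).sum()
    rate = rec.sampling_rate
    n = rec.n_samples
    if method == "sample_diff":
        if valid < 2:
            raise InsufficientDataError("sample_diff velocity needs >= 2 valid samples")
        vx = np.full(n, np.nan)
        vy = np.full(n, np.nan)
        vx[1:] = np.diff(rec.x) * rate
        vy[1:] = np.diff(rec.y) * rate
        return vx, vy
    if method == "moving_window":
        if valid < 5:
            raise InsufficientDataError("moving_window velocity needs >= 5 valid samples")
        vx = np.full(n, np.nan)
        vy = np.full(n, np.nan)
        if n >= 5:
            vx[2:-2] = (rec.x[3:-1] + rec.x[4:] - rec.x[1:-3] - rec.x[:-4]) * rate / 6.0
            vy[2:-2] = (rec.y[3:-1] + rec.y[4:] - rec.y[1:-3] - rec.y[:-4]) * rate / 6.0
        return vx, vy
    raise ConfigurationError(f"unknown velocity method {method!r}")


def compute_velocity(rec: GazeRecording, method: str = "sample_diff") -> np.ndarray:
    """Per-sample angular speed (°/s): Euclidean norm of the axis velocities."""
    vx, vy = velocity_components(rec, method)
    return np.hypot(vx, vy)


def compute_dispersion(x: np.ndarray, y: np.ndarray) -> float:
    """Dispersion of a gaze-point window in degrees.

    Defined as (max x - min x) + (max y - min y) over the non-missing
    points — the quantity the dispersion-threshold detectors compare with
    their spatial threshold.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    if not ok.any():
        raise InsufficientDataError("dispersion of an all-missing window is undefined")
    xs, ys = x[ok], y[ok]
    return float((xs.max() - xs.min()) + (ys.max() - ys.min()))
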