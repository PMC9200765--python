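"""Geometry and photometry of simulated looming stimuli.

A looming stimulus is a dark disk whose angular size grows as if a real
object of fixed diameter approached the observer at constant speed on a
direct collision course.  Everything downstream (escape timing, neuronal
drive) is expressed on the *time-to-collision* axis: the time remaining
before the virtual object would reach the observer.

Angles are degrees in the public interface; radians internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class InvalidParameterError(ValueError):
    """A stimulus or analysis parameter violates its physical constraints."""


class DataError(ValueError):
    """Measured input data violate the assumptions of an operation."""


@dataclass(frozen=True)
class LoomingStimulus:
    """A virtual object approaching at constant speed on a collision course.

    Parameters
    ----------
    object_diameter : float
        Real diameter of the simulated object, mm.
    approach_speed : float
        Constant approach speed, mm/s.
    start_distance : float
        Distance at stimulus onset, mm.
    weber_contrast : float
        Weber contrast of the disk against the background, in [-1, 0]
        (dark stimuli on a brighter background; -1.0 is black on the
        background, -0.4 a dark grey).
    azimuth : float
        Approach direction in the observer-centred frame, deg in [0, 360).
    elevation : float
        Elevation of the stimulus centre above the visual horizon, deg.
    """

    object_diameter: float = 30.0
    approach_speed: float = 200.0
    start_distance: float = 5000.0
    weber_contrast: float = -1.0
    azimuth: float = 0.0
    elevation: float = 15.0

    def __post_init__(self) -> None:
        if self.object_diameter <= 0:
            raise InvalidParameterError("object_diameter must be > 0")
        if self.approach_speed <= 0:
            raise InvalidParameterError("approach_speed must be > 0")
        if self.start_distance <= self.object_diameter / 2.0:
            raise InvalidParameterError(
                "start_distance must exceed the object radius"
            )
        if not -1.0 <= self.weber_contrast <= 0.0:
            raise InvalidParameterError("weber_contrast must lie in [-1, 0]")
        object.__setattr__(self, "azimuth", float(self.azimuth) % 360.0)


@dataclass(frozen=True)
class StimulusTrace:
    """Time-resolved description of a looming stimulus.

    ``time_to_collision`` decreases towards 0; ``angular_diameter`` (deg)
    increases monotonically and saturates at 180 deg when the virtual
    object reaches the eye; ``expansion_rate`` is its derivative in deg/s.
    """

    time_to_collision: np.ndarray
    angular_diameter: np.ndarray
    expansion_rate: np.ndarray
    stimulus: LoomingStimulus = field(default_factory=LoomingStimulus)


def collision_time(stimulus: LoomingStimulus) -> float:
    """Time from stimulus onset to the predicted collision, seconds."""
    return stimulus.start_distance / stimulus.approach_speed


def angular_diameter(stimulus: LoomingStimulus, tau):
    """Full angular subtense of the object at time-to-collision ``tau``.

    Uses the exact full-diameter form ``2 * arctan(R / d)`` with
    ``R = D/2`` and remaining distance ``d = v * tau``.  Once the object
    is within one radius of the eye (``d <= R``) the subtense is clamped
    to 180 deg: on screen the disk has filled the monitor.

    Parameters
    ----------
    tau : float or array_like
        Time to collision, s; must be >= 0.

    Returns
    -------
    float or ndarray, deg in (0, 180].
    """
    tau = np.asarray(tau, dtype=float)
    if np.any(tau < 0):
        raise InvalidParameterError("time to collision must be >= 0")
    radius = stimulus.object_diameter / 2.0
    distance = stimulus.approach_speed * tau
    with np.errstate(divide="ignore"):
        theta = 2.0 * np.degrees(np.arctan2(radius, distance))
    theta = np.where(distance <= radius, 180.0, theta)
    return theta if theta.ndim else float(theta)


def expansion_rate(stimulus: LoomingStimulus, tau):
    """Rate of change of the angular diameter at time-to-collision ``tau``.

    Analytic derivative of :func:`angular_diameter`:
    ``d(theta)/dt = 2 R v / (d^2 + R^2)`` rad/s with ``d = v * tau``,
    returned in deg/s.  Zero once the disk has filled the screen
    (``d <= R``), where the rendered stimulus no longer changes.
    """
    tau = np.asarray(tau, dtype=float)
    if np.any(tau <= 0):
        raise InvalidParameterError("time to collision must be > 0")
    radius = stimulus.object_diameter / 2.0
    speed = stimulus.approach_speed
    distance = speed * tau
    rate = 2.0 * radius * speed / (distance**2 + radius**2)
    rate = np.where(distance <= radius, 0.0, np.degrees(rate))
    return rate if rate.ndim else float(rate)


def weber_contrast(stim_level: float, bg_level: float) -> float:
    """Weber contrast ``(L_stim - L_bg) / L_bg`` of a stimulus patch."""
    if bg_level <= 0:
        raise InvalidParameterError("background luminance must be > 0")
    return (stim_level - bg_level) / bg_level


def stimulus_trace(
    stimulus: LoomingStimulus, dt: float = 0.01, t_end: float = 0.0
) -> StimulusTrace:
    """Sample the stimulus geometry on a uniform time-to-collision grid.

    The grid runs from stimulus onset (``tau = collision_time``) down to
    ``t_end`` (default 0, the predicted collision) in steps of ``dt``.
    """
    if dt <= 0:
        raise InvalidParameterError("dt must be > 0")
    t0 = collision_time(stimulus)
    n = int(np.floor((t0 - t_end) / dt)) + 1
    tau = t0 - dt * np.arange(n)
    tau = np.clip(tau, max(t_end, 0.0), None)
    theta = angular_diameter(stimulus, tau)
    rate = expansion_rate(stimulus, np.clip(tau, dt * 1e-6, None))
    return StimulusTrace(
        time_to_collision=tau,
        angular_diameter=np.asarray(theta),
        expansion_rate=np.asarray(rate),
        stimulus=stimulus,
    )


def linearization_lut(radiance_by_level: np.ndarray) -> np.ndarray:
    """Display look-up table linearizing a measured radiance curve.

    Given the radiance measured at every display level 0..L-1 (typically
    256 levels), return an integer LUT such that presenting
    ``LUT[level]`` produces radiance that grows linearly with ``level``
    between the measured endpoints.

    Raises
    ------
    DataError
        If the measured curve is non-monotone or flat (not invertible).
    """
    radiance = np.asarray(radiance_by_level, dtype=float)
    if radiance.ndim != 1 or radiance.size < 2:
        raise DataError("need a 1-D radiance curve with >= 2 levels")
    if np.any(np.diff(radiance) < 0):
        raise DataError("measured radiance must be monotone non-decreasing")
    if radiance[-1] <= radiance[0]:
        raise DataError("radiance curve is flat; cannot linearize")
    levels = np.arange(radiance.size)
    target = np.linspace(radiance[0], radiance[-1], radiance.size)
    # invert the measured curve at the target radiances; interp handles
    # plateaus by returning the left edge, which stays within one level
    lut = np.interp(target, radiance, levels)
    lut = np.rint(lut).astype(int)
    lut[0], lut[-1] = levels[0], levels[-1]
    return lut
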