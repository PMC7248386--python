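"""Closed-form sigma-lognormal forward model.

A planar rapid movement is represented as a vector sum of lognormal
"impulse response" components.  Each component is parameterised by a
command emission time ``t0``, an amplitude ``D`` (the distance the
component covers, in mm), log-time-scale parameters ``mu`` and ``sigma``,
and start/end angles ``theta_s``/``theta_e`` describing the circle arc the
component traces.

All functions here are pure; they are consumed by the synthetic generator,
the extractor and the reporting layers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import erf

__all__ = [
    "LognormalComponent",
    "DerivedParams",
    "InvalidParameterError",
    "UndefinedReactionTimeError",
    "lognormal_speed",
    "lognormal_peak_time",
    "lognormal_peak_value",
    "angular_profile",
    "superpose",
    "derived_parameters",
    "reaction_time",
    "conduction_time",
    "wrap_angle",
]


class InvalidParameterError(ValueError):
    """Raised when a lognormal component has non-physical parameters."""


class UndefinedReactionTimeError(ValueError):
    """Raised when a reaction time cannot be read off a speed profile."""


def wrap_angle(theta: float) -> float:
    """Wrap an angle to the interval (-pi, pi]."""
    wrapped = math.remainder(float(theta), 2.0 * math.pi)
    if wrapped <= -math.pi:
        wrapped += 2.0 * math.pi
    return wrapped


@dataclass(frozen=True)
class LognormalComponent:
    """One neuromuscular impulse response.

    Parameters
    ----------
    t0:
        Command emission time in seconds, relative to the stimulus at T=0.
    D:
        Command amplitude in mm (distance covered by the component).
    mu:
        Log time delay, ln(s).
    sigma:
        Log response time, ln(s); must be positive.
    theta_s, theta_e:
        Start and end angles of the traced arc, radians CCW from +x,
        wrapped to (-pi, pi].
    """

    t0: float
    D: float
    mu: float
    sigma: float
    theta_s: float = 0.0
    theta_e: float = 0.0

    def __post_init__(self) -> None:
        if not np.isfinite([self.t0, self.D, self.mu, self.sigma]).all():
            raise InvalidParameterError("component parameters must be finite")
        if self.sigma <= 0:
            raise InvalidParameterError(f"sigma must be > 0, got {self.sigma}")
        if self.D <= 0:
            raise InvalidParameterError(f"D must be > 0, got {self.D}")
        object.__setattr__(self, "theta_s", wrap_angle(self.theta_s))
        object.__setattr__(self, "theta_e", wrap_angle(self.theta_e))


@dataclass(frozen=True)
class DerivedParams:
    """Timing parameters derived from one component.

    ``mode``, ``median`` and ``time_delay`` are absolute times (seconds,
    stimulus-relative); ``response_time`` is the spread of the impulse
    response and ``asymmetry`` its skewness (dimensionless).
    """

    mode: float
    median: float
    time_delay: float
    response_time: float
    asymmetry: float


def _as_times(times: Sequence[float]) -> np.ndarray:
    t = np.asarray(times, dtype=float)
    if t.ndim != 1:
        raise ValueError("times must be one-dimensional")
    if not np.isfinite(t).all():
        raise ValueError("times must be finite")
    if t.size > 1 and np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    return t


def lognormal_speed(component: LognormalComponent, times: Sequence[float]) -> np.ndarray:
    """Speed profile D * Lambda(t; t0, mu, sigma^2) of one component.

    Identically zero for t <= t0; non-negative everywhere.
    """
    t = _as_times(times)
    out = np.zeros_like(t)
    dt = t - component.t0
    mask = dt > 0
    if mask.any():
        s = component.sigma
        z = (np.log(dt[mask]) - component.mu) / s
        out[mask] = (
            component.D
            / (s * math.sqrt(2.0 * math.pi) * dt[mask])
            * np.exp(-0.5 * z * z)
        )
    return out


def lognormal_peak_time(component: LognormalComponent) -> float:
    """Time of the component's speed maximum: t0 + exp(mu - sigma^2)."""
    return component.t0 + math.exp(component.mu - component.sigma**2)


def lognormal_peak_value(component: LognormalComponent) -> float:
    """Maximum speed: D * exp(sigma^2/2 - mu) / (sigma * sqrt(2*pi))."""
    s = component.sigma
    return component.D * math.exp(s * s / 2.0 - component.mu) / (s * math.sqrt(2.0 * math.pi))


def angular_profile(component: LognormalComponent, times: Sequence[float]) -> np.ndarray:
    """Direction of travel theta(t) along the component's circle arc.

    Interpolates from ``theta_s`` to ``theta_e`` through the lognormal's
    cumulative distribution (an erf); for t <= t0 the start angle is
    returned.  The interpolation runs over the *unwrapped* angular span so
    that arcs crossing the -pi/pi cut stay continuous.
    """
    t = _as_times(times)
    span = wrap_angle(component.theta_e - component.theta_s)
    out = np.full_like(t, component.theta_s)
    dt = t - component.t0
    mask = dt > 0
    if mask.any():
        z = (np.log(dt[mask]) - component.mu) / (component.sigma * math.sqrt(2.0))
        out[mask] = component.theta_s + span / 2.0 * (1.0 + erf(z))
    return out


def superpose(
    components: Sequence[LognormalComponent], times: Sequence[float]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vector-sum velocity of several components on a common time grid.

    Returns ``(vx, vy, speed)`` where ``speed`` is the magnitude of the
    summed planar velocity (not the sum of component speeds).
    """
    if len(components) == 0:
        raise ValueError("superpose requires at least one component")
    t = _as_times(times)
    vx = np.zeros_like(t)
    vy = np.zeros_like(t)
    for comp in components:
        mag = lognormal_speed(comp, t)
        ang = angular_profile(comp, t)
        vx += mag * np.cos(ang)
        vy += mag * np.sin(ang)
    return vx, vy, np.hypot(vx, vy)


def derived_parameters(component: LognormalComponent) -> DerivedParams:
    """Standard lognormal timing statistics of one component.

    mode = t0 + exp(mu - sigma^2); median = t0 + exp(mu);
    time_delay (mean) = t0 + exp(mu + sigma^2/2);
    response_time (SD) = exp(mu + sigma^2/2) * sqrt(exp(sigma^2) - 1);
    asymmetry (skewness) = (exp(sigma^2) + 2) * sqrt(exp(sigma^2) - 1).
    """
    s2 = component.sigma**2
    emu = math.exp(component.mu)
    mean_scale = emu * math.exp(s2 / 2.0)
    spread = math.sqrt(math.expm1(s2))
    return DerivedParams(
        mode=component.t0 + emu * math.exp(-s2),
        median=component.t0 + emu,
        time_delay=component.t0 + mean_scale,
        response_time=mean_scale * spread,
        asymmetry=(math.exp(s2) + 2.0) * spread,
    )


def reaction_time(
    speed: Sequence[float], times: Sequence[float], t_stimulus: float = 0.0
) -> float:
    """First time at/after the stimulus where speed reaches 10% of its max.

    Raises :class:`UndefinedReactionTimeError` when the speed profile has
    no strictly positive maximum after the stimulus.
    """
    t = _as_times(times)
    v = np.asarray(speed, dtype=float)
    if v.shape != t.shape:
        raise ValueError("speed and times must have the same shape")
    after = t >= t_stimulus
    if not after.any() or np.nanmax(v[after]) <= 0:
        raise UndefinedReactionTimeError("speed has no positive maximum after the stimulus")
    threshold = 0.10 * float(np.nanmax(v[after]))
    idx = np.nonzero(after & (v >= threshold))[0]
    if idx.size == 0:  # pragma: no cover - threshold <= max guarantees a hit
        raise UndefinedReactionTimeError("threshold never reached")
    return float(t[idx[0]])


def conduction_time(t0: float, rt: float) -> float:
    """Duration of command propagation |t0 - RT|."""
    return abs(float(t0) - float(rt))
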