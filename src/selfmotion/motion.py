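"""Single-cycle sinusoidal-acceleration motion profiles.

The inertial stimulus used throughout the package is one full cycle of
sinusoidal acceleration delivered over a duration ``T`` (1 s by default),
moving the platform a total signed displacement ``D`` in one direction:

    a(t) = A sin(2 pi t / T)
    v(t) = (A T / 2 pi) (1 - cos(2 pi t / T))
    p(t) = (A T / 2 pi) (t - (T / 2 pi) sin(2 pi t / T))

with acceleration amplitude ``A = 2 pi D / T**2``.  This is the unique
single-cycle form with no discontinuity in acceleration, velocity or
position: a, v are zero at both endpoints and position runs monotonically
from 0 to D.  Peak velocity is reached at mid-movement and equals
``2 D / T``; the rest of the package expresses stimulus magnitudes as this
signed peak velocity (cm/s for sway translation, deg/s for yaw rotation).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = ["MotionProfile", "peak_velocity", "displacement_for_peak_velocity", "trajectory"]

#: Axes of motion supported by the platform model.
AXES = ("sway", "yaw")


def peak_velocity(displacement: float, duration: float) -> float:
    """Peak velocity of a single-cycle sinusoidal-acceleration movement.

    Parameters
    ----------
    displacement : float
        Total displacement ``D`` (cm for sway, degrees for yaw). Must be
        non-negative; use a signed :class:`MotionProfile` for direction.
    duration : float
        Movement duration ``T`` in seconds, strictly positive.

    Returns
    -------
    float
        ``2 * D / T`` in displacement-units per second.
    """
    if duration <= 0:
        raise ValueError(f"duration must be positive, got {duration}")
    if displacement < 0:
        raise ValueError(f"displacement must be non-negative, got {displacement}")
    return 2.0 * displacement / duration


def displacement_for_peak_velocity(v_peak: float, duration: float) -> float:
    """Inverse of :func:`peak_velocity`: displacement giving peak velocity ``v_peak``."""
    if duration <= 0:
        raise ValueError(f"duration must be positive, got {duration}")
    return v_peak * duration / 2.0


@dataclass(frozen=True)
class MotionProfile:
    """A signed single-direction movement on one axis.

    Parameters
    ----------
    axis : {"sway", "yaw"}
    direction : {+1, -1}
        +1 is rightward (rightward translation / rightward yaw).
    duration : float
        Movement duration ``T`` in seconds.
    displacement : float
        Total unsigned displacement ``D`` (cm or degrees).
    nominal_frequency : float
        Descriptive label only; the waveform is always one full cycle
        over ``duration``.
    """

    axis: str
    direction: int
    duration: float = 1.0
    displacement: float = 10.0
    nominal_frequency: float = field(default=0.5, compare=False)

    def __post_init__(self) -> None:
        if self.axis not in AXES:
            raise ValueError(f"axis must be one of {AXES}, got {self.axis!r}")
        if self.direction not in (1, -1):
            raise ValueError(f"direction must be +1 or -1, got {self.direction!r}")
        if self.duration <= 0:
            raise ValueError(f"duration must be positive, got {self.duration}")
        if self.displacement < 0:
            raise ValueError(f"displacement must be non-negative, got {self.displacement}")

    @property
    def acceleration_amplitude(self) -> float:
        """Amplitude ``A = 2 pi D / T**2`` of the acceleration sinusoid."""
        return 2.0 * math.pi * self.displacement / self.duration**2

    @property
    def peak_velocity(self) -> float:
        """Unsigned peak velocity ``2 D / T``."""
        return peak_velocity(self.displacement, self.duration)

    @property
    def signed_peak_velocity(self) -> float:
        return self.direction * self.peak_velocity

    def trajectory(self, t):
        """Acceleration, velocity and position at time(s) ``t`` in ``[0, T]``.

        Returns a tuple of arrays (or scalars, matching the input shape)
        ``(a, v, p)``, each carrying the profile's sign.
        """
        t_arr = np.asarray(t, dtype=float)
        if np.any(t_arr < 0) or np.any(t_arr > self.duration):
            raise ValueError(f"t must lie in [0, {self.duration}]")
        omega = 2.0 * math.pi / self.duration
        amp = self.acceleration_amplitude
        a = amp * np.sin(omega * t_arr)
        v = (amp / omega) * (1.0 - np.cos(omega * t_arr))
        p = (amp / omega) * (t_arr - np.sin(omega * t_arr) / omega)
        scale = float(self.direction)
        if np.isscalar(t) or t_arr.ndim == 0:
            return scale * float(a), scale * float(v), scale * float(p)
        return scale * a, scale * v, scale * p


def trajectory(profile: MotionProfile, t):
    """Functional alias for :meth:`MotionProfile.trajectory`."""
    return profile.trajectory(t)
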