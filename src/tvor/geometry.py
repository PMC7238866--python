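"""Gaze geometry and biomechanics for platform-induced vertical translation.

A subject stands on a tilting platform with the ankle joints at radius ``r``
from the tilt axis and fixates an LED at distance ``d`` straight ahead at eye
level.  Tilting the platform by ``theta`` translates the body (and the eyes)
vertically by ``r * sin(theta)``; keeping the LED foveated therefore requires
a compensatory vertical eye rotation of ``atan(translation / d)`` in the
opposite direction.  With the default geometry (r = 12.5 cm, d = 50 cm,
theta = +/-6 deg) the translation is +/-1.3 cm and the required eye rotation
+/-1.5 deg.

The module also covers the two anthropometric computations used downstream:
the head-neck segment mass (a fixed, sex-specific fraction of body weight)
and the swing period of the head-neck segment treated as an inverted gravity
pendulum.

Angles are degrees at every public interface; radians are internal only.
Upward platform rotation (dorsiflexion side up) is positive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "GeometryParams",
    "Anthropometrics",
    "HEAD_NECK_MASS_FACTOR",
    "vertical_translation",
    "required_eye_angle",
    "required_eye_trace",
    "head_neck_mass",
    "pendulum_period",
]

#: Head-neck segment mass as a fraction of total body weight, by sex.
HEAD_NECK_MASS_FACTOR = {"female": 0.08, "male": 0.0826}


@dataclass(frozen=True)
class GeometryParams:
    """Platform / fixation geometry.

    Parameters
    ----------
    ankle_radius_cm
        Distance of the ankle joints from the platform tilt axis (cm).
    led_distance_cm
        Distance from the eyes to the fixation LED (cm).
    platform_amplitude_deg
        Peak platform inclination (deg).
    gravity_m_s2
        Gravitational acceleration (m/s^2), used for the pendulum model.
    """

    ankle_radius_cm: float = 12.5
    led_distance_cm: float = 50.0
    platform_amplitude_deg: float = 6.0
    gravity_m_s2: float = 9.81

    def __post_init__(self) -> None:
        if self.ankle_radius_cm <= 0:
            raise ValueError("ankle_radius_cm must be positive")
        if self.led_distance_cm <= 0:
            raise ValueError("led_distance_cm must be positive")
        if not 0 < self.platform_amplitude_deg < 90:
            raise ValueError("platform_amplitude_deg must be in (0, 90)")
        if self.gravity_m_s2 <= 0:
            raise ValueError("gravity_m_s2 must be positive")


@dataclass(frozen=True)
class Anthropometrics:
    """Per-subject anthropometrics relevant to the head-neck segment.

    ``head_neck_length_cm`` is the eye-to-C7 height difference and
    ``head_neck_mass_kg`` a fixed fraction of body weight (0.08 for women,
    0.0826 for men); both are derived on construction.
    """

    weight_kg: float
    sex: str
    eye_height_cm: float
    c7_height_cm: float

    def __post_init__(self) -> None:
        if self.weight_kg <= 0:
            raise ValueError("weight_kg must be positive")
        if self.sex not in HEAD_NECK_MASS_FACTOR:
            raise ValueError(f"unknown sex category: {self.sex!r}")
        if not self.eye_height_cm > self.c7_height_cm:
            raise ValueError("eye_height_cm must exceed c7_height_cm")

    @property
    def head_neck_length_cm(self) -> float:
        return self.eye_height_cm - self.c7_height_cm

    @property
    def head_neck_mass_kg(self) -> float:
        return head_neck_mass(self.weight_kg, self.sex)


def vertical_translation(theta_deg, params: GeometryParams = GeometryParams()):
    """Vertical head translation (cm) produced by a platform tilt of ``theta_deg``.

    Rigid-body motion of the ankle point at radius ``r``:
    ``translation = r * sin(theta)``.  Odd in ``theta``.
    """
    theta = np.asarray(theta_deg, dtype=float)
    if np.any(np.abs(theta) > 90):
        raise ValueError("|theta_deg| must not exceed 90")
    out = params.ankle_radius_cm * np.sin(np.deg2rad(theta))
    return out if out.ndim else float(out)


def required_eye_angle(translation_cm, params: GeometryParams = GeometryParams()):
    """Eye rotation (deg) required to keep the LED foveated after a vertical
    translation of ``translation_cm``: ``atan(translation / d)``.  Odd in the
    translation."""
    tr = np.asarray(translation_cm, dtype=float)
    out = np.rad2deg(np.arctan2(tr, params.led_distance_cm))
    return out if out.ndim else float(out)


def required_eye_trace(platform, params: GeometryParams = GeometryParams()):
    """Theoretically necessary compensatory eye trace for a platform trace.

    Sample-wise ``-atan(r * sin(theta_t) / d)`` on the platform's own grid:
    the eye must rotate opposite to the translation, hence the sign flip.

    Parameters
    ----------
    platform
        A ``PlatformTrace`` (or any object with ``t``, ``angle_deg`` and
        ``fs`` attributes).

    Returns
    -------
    EyeTrace
        Required vertical eye position, same sampling grid as the input.
    """
    from .preprocess import EyeTrace  # local import to avoid a cycle

    eye = -required_eye_angle(vertical_translation(platform.angle_deg, params), params)
    return EyeTrace(t=np.array(platform.t, copy=True), eye_deg=eye,
                    fs=platform.fs, provenance="required")


def required_angle_of_tilt(theta_deg, params: GeometryParams = GeometryParams()):
    """Compensatory eye angle (deg) as a direct function of platform tilt.

    Convenience composition ``-atan(r*sin(theta)/d)`` used by the simulator,
    which needs the mapping at arbitrary (off-grid) times.
    """
    return -required_eye_angle(vertical_translation(theta_deg, params), params)


def head_neck_mass(weight_kg: float, sex: str) -> float:
    """Head-neck segment mass (kg) as a sex-specific fraction of body weight."""
    if weight_kg <= 0:
        raise ValueError("weight_kg must be positive")
    try:
        factor = HEAD_NECK_MASS_FACTOR[sex]
    except KeyError:
        raise ValueError(f"unknown sex category: {sex!r}") from None
    return weight_kg * factor


def pendulum_period(length_m: float, gravity_m_s2: float = 9.81) -> float:
    """Swing period (s) of a simple gravity pendulum: ``2*pi*sqrt(L/g)``.

    Applied to the head-neck segment (default length 0.255 m this gives
    ~1.01 s, i.e. ~1 swing/s, coinciding with preferred stride frequency).
    """
    if length_m <= 0:
        raise ValueError("length_m must be positive")
    if gravity_m_s2 <= 0:
        raise ValueError("gravity_m_s2 must be positive")
    return 2.0 * np.pi * np.sqrt(length_m / gravity_m_s2)
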