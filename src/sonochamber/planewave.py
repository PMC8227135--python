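"""Single-interface plane-wave coefficients.

Normal-incidence intensity transmission/reflection from the impedance pair,
Snell refraction for oblique incidence, longitudinal and shear critical
angles, the fluid-fluid oblique power transmission coefficient, and the
intromission angle (total transmission), when one exists.

Angles are degrees (measured from the interface normal) in the public API
and radians internally.  Equality with the critical angle is classified as
evanescent (zero transmitted longitudinal power).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

from .errors import ValidationError
from .materials import AcousticMedium, impedance


@dataclass(frozen=True)
class InterfaceCoefficients:
    """Intensity transmission and reflection at normal incidence.

    Invariant: Ti + Ri = 1 (no absorption at a sharp interface).
    """
    Ti: float
    Ri: float


@dataclass(frozen=True)
class CriticalAngles:
    """Critical angles (degrees) for the longitudinal and shear branches.

    An entry is None when the corresponding solid speed does not exceed the
    fluid speed (no total-reflection branch).
    """
    longitudinal: Optional[float]
    shear: Optional[float]


def normal_coeffs(r1: float, r2: float) -> InterfaceCoefficients:
    """Intensity coefficients for normal incidence on the r1 -> r2 interface.

    Ti = 4 r1 r2 / (r1 + r2)^2,  Ri = (r1 - r2)^2 / (r1 + r2)^2.
    Matched impedances (r1 == r2) give total transmission.
    """
    if not (r1 > 0 and r2 > 0):
        raise ValidationError("impedances must be > 0")
    s = r1 + r2
    Ti = 4.0 * r1 * r2 / (s * s)
    Ri = (r1 - r2) ** 2 / (s * s)
    return InterfaceCoefficients(Ti=Ti, Ri=Ri)


def refract(theta_i: float, c1: float, c2: float) -> Optional[float]:
    """Snell refraction: sin(theta_t) = (c2/c1) sin(theta_i).

    Returns the transmitted angle in degrees, or None when the refracted
    wave is evanescent (argument of asin at or beyond 1).
    """
    if not 0.0 <= theta_i < 90.0:
        raise ValidationError("incidence angle must be in [0, 90) degrees")
    s = (c2 / c1) * math.sin(math.radians(theta_i))
    if s >= 1.0 and theta_i > 0.0:
        return None
    if s >= 1.0:  # theta_i == 0 with c2/c1 huge cannot happen (sin 0 = 0)
        return None
    return math.degrees(math.asin(s))


def critical_angles(fluid: AcousticMedium, solid: AcousticMedium) -> CriticalAngles:
    """Critical angles for a fluid-loaded solid, degrees from the normal.

    The longitudinal branch closes at asin(c_fluid/c_long); the slower shear
    branch persists to the larger angle asin(c_fluid/c_shear), so some power
    still crosses between the two critical angles.
    """
    def branch(c_solid: float) -> Optional[float]:
        if c_solid > fluid.c_long:
            return math.degrees(math.asin(fluid.c_long / c_solid))
        return None

    return CriticalAngles(
        longitudinal=branch(solid.c_long),
        shear=branch(solid.c_shear) if solid.c_shear > 0 else None,
    )


def oblique_power_transmission(theta_i: float,
                               medium1: AcousticMedium,
                               medium2: AcousticMedium) -> float:
    """Fluid-fluid power transmission at oblique incidence.

    T = 4 (r2/r1)(cos theta_t / cos theta_i) /
        (r2/r1 + cos theta_t / cos theta_i)^2
    below the critical angle; 0 at or beyond it (longitudinal branch only).
    Reduces to the normal-incidence intensity coefficient at theta_i = 0.
    """
    theta_t = refract(theta_i, medium1.c_long, medium2.c_long)
    if theta_t is None:
        return 0.0
    cos_ratio = math.cos(math.radians(theta_t)) / math.cos(math.radians(theta_i))
    m = impedance(medium2) / impedance(medium1)
    return 4.0 * m * cos_ratio / (m + cos_ratio) ** 2


def intromission_angle(medium1: AcousticMedium,
                       medium2: AcousticMedium) -> Optional[float]:
    """Angle of total transmission (reflection vanishes), degrees, or None.

    Solves r2 cos(theta_i) = r1 cos(theta_t) with Snell's law:
        sin^2(theta_i) = (r2^2 - r1^2) / (r2^2 - r1^2 (c2/c1)^2).
    A real solution in (0, 90) requires either r2 > r1 with c2 < c1 or
    r2 < r1 with c2 > c1 (the latter pair also has a critical angle, the
    canonical water/adiprene case).  Identical media transmit totally at
    every angle; 0 is returned by convention.
    """
    r1, r2 = impedance(medium1), impedance(medium2)
    c1, c2 = medium1.c_long, medium2.c_long
    if r1 == r2 and c1 == c2:
        return 0.0
    num = r2 * r2 - r1 * r1
    den = r2 * r2 - r1 * r1 * (c2 / c1) ** 2
    if den == 0.0:
        return None
    s2 = num / den
    if not 0.0 < s2 < 1.0:
        return None
    return math.degrees(math.asin(math.sqrt(s2)))
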