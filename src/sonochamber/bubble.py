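"""Microbubble linear resonance and mechanical index.

A lipid-shelled gas microbubble of rest radius R0 in a liquid of density
rho resonates at

    w0^2 = (1 / rho R0^2) [3 gamma (P0 + 2 sigma/R0 + 2 chi/R0)
                           - 2 sigma/R0 - 6 chi/R0]

where gamma is the polytropic gas constant, P0 the hydrostatic pressure,
sigma the interfacial tension and chi the shell elasticity modulus.  With
sigma = chi = 0 this reduces to the classical Minnaert resonance of a bare
bubble.  The mechanical index MI = PNP(kPa)/sqrt(f(Hz)) — numerically
identical to the conventional MPa/sqrt(MHz) — gauges the likelihood of
(inertial) cavitation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

from scipy.optimize import brentq

from .errors import NoResonanceError, ValidationError


@dataclass(frozen=True)
class BubbleParameters:
    """Shelled-bubble parameters (SI).

    Defaults describe a lipid-shelled perfluorocarbon contrast-agent
    bubble in water: gamma = 1.07, sigma = 0.072 N/m, chi = 0.55 N/m.
    """
    R0: float                        # rest radius, m
    rho: float = 1000.0              # liquid density, kg/m^3
    gamma: float = 1.07              # polytropic gas constant
    P0: float = 101325.0             # hydrostatic pressure, Pa
    sigma: float = 0.072             # interfacial tension, N/m
    chi: float = 0.55                # shell elasticity modulus, N/m

    def __post_init__(self) -> None:
        if not self.R0 > 0:
            raise ValidationError("R0 must be > 0")
        if not self.rho > 0:
            raise ValidationError("rho must be > 0")
        if self.gamma < 1.0:
            raise ValidationError("gamma must be >= 1")
        if not self.P0 > 0:
            raise ValidationError("P0 must be > 0")
        if self.sigma < 0 or self.chi < 0:
            raise ValidationError("sigma and chi must be >= 0")


@dataclass(frozen=True)
class ExposureSetting:
    """One ultrasound exposure: peak negative pressure and frequency."""
    pnp_kpa: float                   # peak negative pressure, kPa
    f_hz: float                      # centre frequency, Hz
    duty_cycle_pct: float = 100.0
    prf_hz: float = 0.0              # pulse repetition frequency

    def __post_init__(self) -> None:
        if self.pnp_kpa < 0:
            raise ValidationError("PNP must be >= 0")
        if not self.f_hz > 0:
            raise ValidationError("frequency must be > 0")
        if not 0.0 < self.duty_cycle_pct <= 100.0:
            raise ValidationError("duty cycle must be in (0, 100] %")


def resonance_frequency(params: BubbleParameters) -> float:
    """Linear resonance frequency f0 = w0/2pi of a shelled bubble, Hz."""
    R0 = params.R0
    bracket = (3.0 * params.gamma
               * (params.P0 + 2.0 * params.sigma / R0 + 2.0 * params.chi / R0)
               - 2.0 * params.sigma / R0 - 6.0 * params.chi / R0)
    if bracket <= 0:
        raise NoResonanceError(
            f"no real resonance: effective stiffness {bracket:.3e} <= 0")
    w0 = math.sqrt(bracket / (params.rho * R0 * R0))
    return w0 / (2.0 * math.pi)


def minnaert_frequency(R0: float, rho: float = 1000.0, gamma: float = 1.4,
                       P0: float = 101325.0) -> float:
    """Closed-form Minnaert resonance of a bare (unshelled) bubble, Hz."""
    if not R0 > 0:
        raise ValidationError("R0 must be > 0")
    return math.sqrt(3.0 * gamma * P0 / rho) / (2.0 * math.pi * R0)


def resonant_radius(f: float, params: BubbleParameters,
                    r_min: float = 10e-9, r_max: float = 100e-6,
                    rtol: float = 1e-6) -> float:
    """Rest radius whose resonance frequency equals f (numeric inversion).

    Root-bracketing over [r_min, r_max]; the R0 in ``params`` is ignored.
    Raises if f lies outside the resonance range of the bracket.
    """
    if not f > 0:
        raise ValidationError("frequency must be > 0")

    def g(R: float) -> float:
        return resonance_frequency(replace(params, R0=R)) - f

    g_lo, g_hi = g(r_min), g(r_max)
    if g_lo * g_hi > 0:
        raise NoResonanceError(
            f"no resonant radius in [{r_min:.2e}, {r_max:.2e}] m for f={f:.3e} Hz")
    root = brentq(g, r_min, r_max, rtol=rtol)
    return float(root)


def mechanical_index(setting: ExposureSetting) -> float:
    """MI = PNP(kPa) / sqrt(f(Hz)), dimensionless."""
    return setting.pnp_kpa / math.sqrt(setting.f_hz)
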