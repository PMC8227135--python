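"""Layered-media transmission and reflection for the exposure chamber stack.

The chamber is modelled as a stack of media with the first and last layers
semi-infinite — canonically water (immersion bath) | glass slide | cell
medium (the 10-20 um sample gap) | glass coverslip | air.  Three solution
routes are provided:

* :func:`solve_normal` — 2x2 pressure/velocity transfer-matrix product at
  normal incidence, solids treated as fluids with their longitudinal
  properties (mode conversion vanishes at normal incidence).
* :func:`solve_oblique` — global-matrix solution conserving the lateral
  wavenumber (Snell), with full longitudinal + vertically polarized shear
  waves in solid layers; supports incidence beyond the longitudinal
  critical angle, where transmission proceeds via the shear branch and
  evanescent tunneling.
* :func:`brute_force_five_layer` — the 8-unknown boundary-condition linear
  system for the five-layer fluid stack, written independently of the
  transfer matrices; a test oracle.

Conventions: time dependence exp(+i omega t), propagation along +z, z = 0
at the first interface; complex wavenumber k = omega/c - i alpha(f);
amplitudes are complex pressure amplitudes relative to a unit incident
wave.  Down-going amplitudes are referenced at the top of their layer,
up-going amplitudes at the bottom, which keeps every stored exponential
bounded.
"""

from __future__ import annotations

import cmath
import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import SingularStackError, ValidationError
from .materials import AcousticMedium, attenuation_at

HALF_SPACE = math.inf


@dataclass(frozen=True)
class LayerStack:
    """Ordered media with thicknesses; first and last are half-spaces."""

    layers: tuple[tuple[AcousticMedium, float], ...]

    def __post_init__(self) -> None:
        if len(self.layers) < 2:
            raise ValidationError("a stack needs at least two half-spaces")
        for i, (_, d) in enumerate(self.layers):
            if i in (0, len(self.layers) - 1):
                if not math.isinf(d):
                    raise ValidationError(
                        f"layer {i} must be a half-space (thickness=inf)")
            elif d < 0 or math.isinf(d):
                raise ValidationError(
                    f"layer {i}: interior thickness must be finite and >= 0")

    @classmethod
    def from_sequence(cls, seq: Sequence[tuple[AcousticMedium, float]]) -> "LayerStack":
        return cls(layers=tuple(seq))

    @property
    def media(self) -> tuple[AcousticMedium, ...]:
        return tuple(m for m, _ in self.layers)

    @property
    def thicknesses(self) -> tuple[float, ...]:
        return tuple(d for _, d in self.layers)

    def reversed(self) -> "LayerStack":
        return LayerStack(layers=tuple(reversed(self.layers)))

    def with_thickness(self, index: int, thickness: float) -> "LayerStack":
        if index <= 0 or index >= len(self.layers) - 1:
            raise ValidationError("only interior layer thicknesses can be set")
        layers = list(self.layers)
        layers[index] = (layers[index][0], thickness)
        return LayerStack(layers=tuple(layers))

    def without_zero_layers(self) -> "LayerStack":
        """Interior layers of zero thickness are physically absent."""
        kept = [self.layers[0]]
        kept += [(m, d) for m, d in self.layers[1:-1] if d > 0]
        kept.append(self.layers[-1])
        return LayerStack(layers=tuple(kept))


@dataclass(frozen=True)
class LayerWaves:
    """Per-layer complex amplitudes.

    ``p_down``/``p_up`` are pressure amplitudes for fluid-modelled layers
    (down referenced at the layer top, up at the layer bottom).  In solid
    layers solved elastically, ``phi_down``/``phi_up`` and
    ``psi_down``/``psi_up`` are displacement-potential amplitudes of the
    longitudinal and shear branches and ``p_down``/``p_up`` are None.
    """
    kind: str                      # "fluid" or "solid"
    kz_long: complex               # vertical wavenumber, longitudinal branch
    thickness: float
    p_down: Optional[complex] = None
    p_up: Optional[complex] = None
    phi_down: Optional[complex] = None
    phi_up: Optional[complex] = None
    psi_down: Optional[complex] = None
    psi_up: Optional[complex] = None
    kz_shear: Optional[complex] = None


@dataclass(frozen=True)
class LayerField:
    """Solved wave field of a stack at one frequency and incidence angle."""

    stack: LayerStack
    f: float
    theta_i: float
    waves: tuple[LayerWaves, ...]
    pressure_reflection: complex
    pressure_transmission: complex
    power_reflection: float
    power_transmission: float
    solver: str = "transfer-matrix"

    def pressure_at(self, layer_index: int, z_local: float) -> complex:
        """Complex pressure in a fluid-modelled layer at local depth z.

        z is measured from the layer top (for the first half-space z <= 0
        reaches up from the first interface).
        """
        w = self.waves[layer_index]
        if w.p_down is None:
            raise ValidationError(
                "pressure sampling is defined for fluid-modelled layers only")
        d = 0.0 if math.isinf(w.thickness) else w.thickness
        kz = w.kz_long
        return (w.p_down * cmath.exp(-1j * kz * z_local)
                + w.p_up * cmath.exp(1j * kz * (z_local - d)))

    def max_pressure_in_layer(self, layer_index: int, n: int = 201) -> float:
        """Peak |p| inside an interior fluid layer, sampled on n points."""
        d = self.stack.thicknesses[layer_index]
        if math.isinf(d):
            raise ValidationError("layer must be interior (finite thickness)")
        zs = np.linspace(0.0, d, n)
        return max(abs(self.pressure_at(layer_index, z)) for z in zs)


# ----------------------------------------------------------------------
# helpers

def _complex_k(medium: AcousticMedium, f: float, speed: Optional[float] = None) -> complex:
    """k = omega/c - i alpha(f); same attenuation law for either branch."""
    c = medium.c_long if speed is None else speed
    return 2.0 * math.pi * f / c - 1j * attenuation_at(medium, f)


def _char_impedance(medium: AcousticMedium, f: float) -> complex:
    """Characteristic impedance rho*omega/k (equals rho*c when lossless)."""
    return medium.density * 2.0 * math.pi * f / _complex_k(medium, f)


def _vertical_wavenumber(k: complex, kx: complex) -> complex:
    """Branch of sqrt(k^2 - kx^2) that decays (Im <= 0) for exp(-i kz z)."""
    kz = cmath.sqrt(k * k - kx * kx)
    if kz.imag > 0 or (kz.imag == 0 and kz.real < 0):
        kz = -kz
    return kz


def _validated(stack: LayerStack, f: float) -> LayerStack:
    if not f > 0:
        raise ValidationError("frequency must be > 0")
    return stack.without_zero_layers()


# ----------------------------------------------------------------------
# normal incidence: 2x2 transfer matrix

def solve_normal(stack: LayerStack, f: float) -> LayerField:
    """Normal-incidence field by the 2x2 (p, v) transfer-matrix product.

    Solids are treated with their longitudinal properties; pressure and
    normal velocity are continuous at every interface and the final
    half-space carries no backward wave (radiation condition).
    """
    work = _validated(stack, f)
    media = work.media
    ds = work.thicknesses
    n = len(media)
    ks = [_complex_k(m, f) for m in media]
    Zs = [_char_impedance(m, f) for m in media]

    # M maps the (p, v) state at a layer's top to the state at its bottom
    # ... inverted: state(top) = M @ state(bottom).
    M_total = np.eye(2, dtype=complex)
    mats = []
    for j in range(1, n - 1):
        kd = ks[j] * ds[j]
        M = np.array([[np.cos(kd), 1j * Zs[j] * np.sin(kd)],
                      [1j * np.sin(kd) / Zs[j], np.cos(kd)]])
        mats.append(M)
        M_total = M_total @ M

    X = M_total[0, 0] + M_total[0, 1] / Zs[-1]
    Y = Zs[0] * (M_total[1, 0] + M_total[1, 1] / Zs[-1])
    T = 2.0 / (X + Y)
    R = (X - Y) / (X + Y)

    # back-substitute per-layer amplitudes from the bottom state upward
    states = [None] * n               # state at each layer's top
    states[-1] = np.array([T, T / Zs[-1]])
    for j in range(n - 2, 0, -1):
        states[j] = mats[j - 1] @ states[j + 1]
    states[0] = np.array([1.0 + R, (1.0 - R) / Zs[0]])

    waves = []
    for j in range(n):
        p, v = states[j]
        A = (p + Zs[j] * v) / 2.0
        B_top = (p - Zs[j] * v) / 2.0
        d = ds[j] if not math.isinf(ds[j]) else 0.0
        B = B_top * np.exp(1j * ks[j] * d)   # re-reference up wave at bottom
        if j == n - 1:
            B = 0.0
        waves.append(LayerWaves(kind="fluid", kz_long=complex(ks[j]),
                                thickness=ds[j],
                                p_down=complex(A), p_up=complex(B)))

    Z0, Zn = Zs[0], Zs[-1]
    flux = lambda p, Z: abs(p) ** 2 * (1.0 / Z).conjugate().real
    power_t = flux(T, Zn) / flux(1.0, Z0)
    power_r = abs(R) ** 2

    return LayerField(stack=work, f=f, theta_i=0.0, waves=tuple(waves),
                      pressure_reflection=complex(R),
                      pressure_transmission=complex(T),
                      power_reflection=power_r, power_transmission=power_t,
                      solver="transfer-matrix")


# ----------------------------------------------------------------------
# oblique incidence: global matrix with elastic solid layers

def _layer_params(medium: AcousticMedium, f: float, kx: complex) -> dict:
    omega = 2.0 * math.pi * f
    kp = _complex_k(medium, f)
    alpha = _vertical_wavenumber(kp, kx)
    out = {"rho": medium.density, "omega": omega, "kp": kp, "alpha": alpha,
           "fluid": medium.is_fluid}
    if medium.is_fluid:
        out["mu"] = 0.0
        out["eta"] = medium.density * omega * omega
    else:
        ks = _complex_k(medium, f, speed=medium.c_shear)
        beta = _vertical_wavenumber(ks, kx)
        mu = medium.density * omega * omega / (ks * ks)
        out.update(ks=ks, beta=beta, mu=mu,
                   eta=medium.density * omega * omega - 2.0 * mu * kx * kx)
    return out


def _field_columns(par: dict, kx: complex, z: float, d: float,
                   down: bool = True, up: bool = True) -> np.ndarray:
    """Rows (u_x, u_z, sigma_zz, sigma_xz) x columns (partial waves).

    Down-going waves carry exp(-i kz z) referenced at the layer top; the
    up-going phase is referenced at the bottom, exp(+i kz (z - d)).
    """
    a, mu, eta = par["alpha"], par["mu"], par["eta"]
    cols = []
    ep_d = cmath.exp(-1j * a * z)
    ep_u = cmath.exp(1j * a * (z - d))
    if down:
        cols.append(np.array([-1j * kx, -1j * a, -eta, -2.0 * mu * kx * a]) * ep_d)
    if up:
        cols.append(np.array([-1j * kx, 1j * a, -eta, 2.0 * mu * kx * a]) * ep_u)
    if not par["fluid"]:
        b = par["beta"]
        es_d = cmath.exp(-1j * b * z)
        es_u = cmath.exp(1j * b * (z - d))
        if down:
            cols.append(np.array([1j * b, -1j * kx, -2.0 * mu * kx * b, eta]) * es_d)
        if up:
            cols.append(np.array([-1j * b, -1j * kx, 2.0 * mu * kx * b, eta]) * es_u)
    return np.stack(cols, axis=1)


_UX, _UZ, _SZZ, _SXZ = 0, 1, 2, 3


def _assemble_global(media, ds, pars, kx) -> tuple[np.ndarray, np.ndarray, list]:
    n = len(media)
    # unknown columns per layer
    ncols, starts = [], []
    pos = 0
    for j in range(n):
        if j == 0:
            c = 1                      # reflected P (fluid first layer)
        elif j == n - 1:
            c = 1 if media[j].is_fluid else 2
        else:
            c = 2 if media[j].is_fluid else 4
        starts.append(pos)
        ncols.append(c)
        pos += c
    total = pos

    rows_a: list[np.ndarray] = []
    rhs: list[complex] = []

    def layer_cols(j: int, z: float) -> np.ndarray:
        d = 0.0 if math.isinf(ds[j]) else ds[j]
        if j == 0:
            return _field_columns(pars[j], kx, z, 0.0, down=False, up=True)
        if j == n - 1:
            # transmitted half-space: down-going branches only (radiation)
            return _field_columns(pars[j], kx, z, 0.0, down=True, up=False)
        return _field_columns(pars[j], kx, z, d)

    incident = _field_columns(pars[0], kx, 0.0, 0.0, down=True, up=False)[:, 0]

    for i in range(n - 1):           # interface between layer i and i+1
        a, b = i, i + 1
        za = 0.0 if (a == 0 or math.isinf(ds[a])) else ds[a]
        cols_a = layer_cols(a, za)
        cols_b = layer_cols(b, 0.0)
        fa, fb = media[a].is_fluid, media[b].is_fluid

        if fa and fb:
            needed = [(_UZ, "cont"), (_SZZ, "cont")]
        elif not fa and not fb:
            needed = [(_UX, "cont"), (_UZ, "cont"), (_SZZ, "cont"), (_SXZ, "cont")]
        elif fa:                      # fluid above solid
            needed = [(_UZ, "cont"), (_SZZ, "cont"), (_SXZ, "b")]
        else:                         # solid above fluid
            needed = [(_UZ, "cont"), (_SZZ, "cont"), (_SXZ, "a")]

        for comp, kind in needed:
            row = np.zeros(total, dtype=complex)
            r = 0.0 + 0.0j
            if kind in ("cont", "a"):
                row[starts[a]:starts[a] + ncols[a]] += cols_a[comp]
                if a == 0:
                    r -= incident[comp]
            if kind in ("cont", "b"):
                sign = -1.0 if kind == "cont" else 1.0
                row[starts[b]:starts[b] + ncols[b]] += sign * cols_b[comp]
            rows_a.append(row)
            rhs.append(r)

    return np.array(rows_a), np.array(rhs), starts


def solve_oblique(stack: LayerStack, f: float, theta_i: float) -> LayerField:
    """Oblique-incidence field by the global-matrix method.

    The lateral wavenumber kx = k1 sin(theta_i) is conserved across layers
    (Snell's law); solid layers carry longitudinal and vertically polarized
    shear partial waves, fluids longitudinal only.  Welded contact at
    solid-solid interfaces, slip with zero shear traction at fluid-solid
    ones.  At isolated angles where the global matrix is numerically
    singular (layer resonances) the angle is nudged by 1e-6 degree and a
    warning is emitted.
    """
    if not 0.0 <= theta_i < 90.0:
        raise ValidationError("incidence angle must be in [0, 90) degrees")
    work = _validated(stack, f)
    if not work.media[0].is_fluid:
        raise ValidationError("first (incidence) half-space must be a fluid")

    try:
        return _solve_oblique_once(work, f, theta_i)
    except SingularStackError:
        nudged = theta_i + 1e-6 if theta_i < 89.999 else theta_i - 1e-6
        warnings.warn(
            f"global matrix singular at {theta_i} deg; re-solved at {nudged} deg",
            RuntimeWarning, stacklevel=2)
        return _solve_oblique_once(work, f, nudged)


def _solve_oblique_once(work: LayerStack, f: float, theta_i: float) -> LayerField:
    media, ds = work.media, work.thicknesses
    n = len(media)
    omega = 2.0 * math.pi * f
    k1 = _complex_k(media[0], f)
    kx = k1 * math.sin(math.radians(theta_i))
    pars = [_layer_params(m, f, kx) for m in media]

    A, rhs, starts = _assemble_global(media, ds, pars, kx)
    # row equilibration: stress rows (~rho w^2) dwarf displacement rows (~k)
    scale = np.max(np.abs(A), axis=1)
    scale[scale == 0] = 1.0
    A = A / scale[:, None]
    rhs = rhs / scale
    cond = np.linalg.cond(A)
    if not np.isfinite(cond) or cond > 1e13:
        raise SingularStackError(f"global matrix condition number {cond:.2e}")
    x = np.linalg.solve(A, rhs)

    # rescale so the incident PRESSURE is 1: p = rho w^2 phi, so the
    # incident potential is 1/(rho1 w^2) and all unknowns scale with it
    rho1 = media[0].density
    p_scale0 = rho1 * omega * omega
    x = x / p_scale0
    inc_pot = 1.0 / p_scale0
    waves = []
    for j in range(n):
        par = pars[j]
        d = ds[j] if not math.isinf(ds[j]) else 0.0
        s = starts[j]
        if j == 0:
            phi_d, phi_u = complex(inc_pot), complex(x[s])
        elif j == n - 1:
            phi_d = complex(x[s])
            phi_u = 0.0 + 0.0j
        else:
            phi_d, phi_u = complex(x[s]), complex(x[s + 1])
        if media[j].is_fluid:
            pj = media[j].density * omega * omega
            waves.append(LayerWaves(
                kind="fluid", kz_long=par["alpha"], thickness=ds[j],
                p_down=pj * phi_d, p_up=pj * phi_u))
        else:
            if j == 0:
                raise ValidationError("first half-space must be fluid")
            if j == n - 1:
                psi_d, psi_u = complex(x[s + 1]), 0.0 + 0.0j
            else:
                psi_d, psi_u = complex(x[s + 2]), complex(x[s + 3])
            waves.append(LayerWaves(
                kind="solid", kz_long=par["alpha"], kz_shear=par["beta"],
                thickness=ds[j],
                phi_down=phi_d, phi_up=phi_u,
                psi_down=psi_d, psi_up=psi_u))

    # pressure coefficients relative to the unit incident pressure
    R = waves[0].p_up
    last = waves[-1]
    rho_n = media[-1].density
    if media[-1].is_fluid:
        T = last.p_down
        Tpot, Spot = last.p_down / (rho_n * omega * omega), 0.0
    else:
        Tpot, Spot = last.phi_down, last.psi_down
        T = rho_n * omega * omega * Tpot        # longitudinal branch

    # power flux ratios (potential amplitudes): I_z = rho w^3 Re(kz) |A|^2 / 2
    inc_flux = rho1 * pars[0]["alpha"].real * abs(inc_pot) ** 2
    r_flux = rho1 * pars[0]["alpha"].real * abs(x[starts[0]]) ** 2
    t_flux = rho_n * pars[-1]["alpha"].real * abs(Tpot) ** 2
    if not media[-1].is_fluid:
        t_flux += rho_n * pars[-1]["beta"].real * abs(Spot) ** 2

    field = LayerField(
        stack=work, f=f, theta_i=theta_i, waves=tuple(waves),
        pressure_reflection=complex(R), pressure_transmission=complex(T),
        power_reflection=r_flux / inc_flux if inc_flux else math.nan,
        power_transmission=t_flux / inc_flux if inc_flux else math.nan,
        solver="global-matrix")
    return field


# ----------------------------------------------------------------------
# derived quantities

def power_loss_through(medium: AcousticMedium, d: float, f: float) -> float:
    """Fraction of acoustic power lost to attenuation over a path d.

    Power attenuates at twice the amplitude rate: loss = 1 - exp(-2 a d).
    """
    if d < 0:
        raise ValidationError("path length must be >= 0")
    return 1.0 - math.exp(-2.0 * attenuation_at(medium, f) * d)


def sample_amplitude_vs_gap(stack_template: LayerStack,
                            gap_range: Sequence[float],
                            f: float,
                            theta_i: float = 0.0,
                            sample_index: Optional[int] = None,
                            n_z: int = 101) -> pd.DataFrame:
    """Peak sample-layer pressure amplitude as a function of the gap L.

    For each L the stack is rebuilt with the sample (middle, unless
    ``sample_index`` is given) layer thickness set to L and the maximum
    |p| inside that layer, relative to the unit incident amplitude, is
    reported.  Interference between the forward wave and the wave
    reflected off the far wall makes this periodic in L with period
    lambda_sample/2 in the lossless normal-incidence case.

    Returns a DataFrame with columns ``L_m`` and ``amplitude_ratio``.
    """
    gaps = list(gap_range)
    if len(gaps) == 0:
        raise ValidationError("gap_range must be non-empty")
    idx = sample_index if sample_index is not None else len(stack_template.layers) // 2
    rows = []
    for L in gaps:
        stack = stack_template.with_thickness(idx, float(L))
        if theta_i == 0.0:
            sol = solve_normal(stack, f)
        else:
            sol = solve_oblique(stack, f, theta_i)
        rows.append((float(L), sol.max_pressure_in_layer(idx, n=n_z)))
    return pd.DataFrame(rows, columns=["L_m", "amplitude_ratio"])


# ----------------------------------------------------------------------
# brute-force oracle and fixture generator

def brute_force_five_layer(stack: LayerStack, f: float) -> LayerField:
    """Five-layer normal-incidence solution by direct boundary conditions.

    Solves the 8-unknown linear system (reflected wave, the three interior
    layers' forward/backward pairs, transmitted wave) from pressure and
    normal-velocity continuity at the four interfaces, with a unit incident
    wave.  Written independently of the transfer-matrix route; used as a
    test oracle.
    """
    work = _validated(stack, f)
    if len(work.layers) != 5:
        raise ValidationError("the brute-force oracle expects exactly 5 layers")
    media, ds = work.media, work.thicknesses
    ks = [_complex_k(m, f) for m in media]
    Zs = [_char_impedance(m, f) for m in media]

    # unknowns: [B0, A1, B1, A2, B2, A3, B3, A4]; A0 = 1, B4 = 0.
    # down-going referenced at layer top, up-going at layer bottom.
    def p_bot(j):
        """(coeff_A, coeff_B, const) of pressure at the bottom of layer j."""
        d = 0.0 if math.isinf(ds[j]) else ds[j]
        e = np.exp(-1j * ks[j] * d)
        return e, 1.0
    def v_bot(j):
        d = 0.0 if math.isinf(ds[j]) else ds[j]
        e = np.exp(-1j * ks[j] * d)
        return e / Zs[j], -1.0 / Zs[j]
    def p_top(j):
        d = 0.0 if math.isinf(ds[j]) else ds[j]
        e = np.exp(-1j * ks[j] * d)
        return 1.0, e
    def v_top(j):
        d = 0.0 if math.isinf(ds[j]) else ds[j]
        e = np.exp(-1j * ks[j] * d)
        return 1.0 / Zs[j], -e / Zs[j]

    A = np.zeros((8, 8), dtype=complex)
    b = np.zeros(8, dtype=complex)
    col_A = {1: 1, 2: 3, 3: 5, 4: 7}   # down-going amplitude columns
    col_B = {0: 0, 1: 2, 2: 4, 3: 6}   # up-going amplitude columns

    row = 0
    for i in range(4):                 # interface between layers i and i+1
        for fa, fb in ((p_bot, p_top), (v_bot, v_top)):
            ca, cb_ = fa(i), fb(i + 1)
            if i == 0:
                b[row] -= ca[0] * 1.0          # incident A0 = 1 at z=0
            else:
                A[row, col_A[i]] += ca[0]
            A[row, col_B[i]] += ca[1]
            A[row, col_A[i + 1]] -= cb_[0]
            if i + 1 != 4:
                A[row, col_B[i + 1]] -= cb_[1]  # B4 = 0
            row += 1

    cond = np.linalg.cond(A)
    if not np.isfinite(cond) or cond > 1e13:
        raise SingularStackError(
            f"five-layer boundary-condition system singular (cond {cond:.2e})")
    x = np.linalg.solve(A, b)

    amps = [(1.0 + 0.0j, complex(x[0]))]
    for j in range(1, 4):
        amps.append((complex(x[col_A[j]]), complex(x[col_B[j]])))
    amps.append((complex(x[7]), 0.0 + 0.0j))

    waves = tuple(
        LayerWaves(kind="fluid", kz_long=complex(ks[j]),
                   thickness=ds[j], p_down=amps[j][0], p_up=amps[j][1])
        for j in range(5))
    R, T = amps[0][1], amps[4][0]
    flux = lambda p, Z: abs(p) ** 2 * (1.0 / Z).conjugate().real
    return LayerField(stack=work, f=f, theta_i=0.0, waves=waves,
                      pressure_reflection=R, pressure_transmission=T,
                      power_reflection=abs(R) ** 2,
                      power_transmission=flux(T, Zs[4]) / flux(1.0, Zs[0]),
                      solver="brute-force")


def generate_random_stack(seed: int, n_layers: int,
                          attenuating: bool = False) -> LayerStack:
    """Deterministic random fluid stack for property tests.

    Media impedances span three orders of magnitude (densities 100-3000
    kg/m^3, speeds 300-6000 m/s log-uniform), interior thicknesses
    10 um - 10 mm log-uniform.  Lossless unless ``attenuating``.
    """
    if n_layers < 2:
        raise ValidationError("n_layers must be >= 2")
    rng = np.random.default_rng(seed)
    layers = []
    for j in range(n_layers):
        rho = float(10 ** rng.uniform(2.0, math.log10(3000.0)))
        c = float(10 ** rng.uniform(math.log10(300.0), math.log10(6000.0)))
        alpha0 = float(rng.uniform(0.05, 1.0)) if attenuating else 0.0
        medium = AcousticMedium(name=f"rand{seed}_{j}", density=rho, c_long=c,
                                alpha0_db_per_cm=alpha0, alpha_exponent=1.0)
        if j in (0, n_layers - 1):
            layers.append((medium, HALF_SPACE))
        else:
            layers.append((medium, float(10 ** rng.uniform(-5.0, -2.0))))
    return LayerStack(layers=tuple(layers))
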