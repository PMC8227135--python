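"""Free-field pressure models for flat and focused circular piston sources.

The flat baffled piston has the closed-form on-axis magnitude

    |p(z)| = 2 p0 |sin( (k/2) (sqrt(z^2 + a^2) - z) )|

whose last on-axis maximum — the focal spot — sits near a^2/lambda - lambda/4.
Off axis the field is evaluated by numerical quadrature of the Rayleigh
surface integral over the piston face.  The focused source uses the O'Neil
spherical-cap on-axis expression and, for field maps, a focusing-phase disk
integral.  Focal metrics (distance, -6 dB length/width, iso-amplitude
surface areas) summarize a sampled field map.

These are free-field models: no tube walls or reverberation, so absolute
iso-areas from bounded-domain finite-element simulations are not
reproduced — the focal distance and the flat-vs-focused orderings are.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import minimize_scalar

from .errors import ValidationError
from .materials import AcousticMedium


@dataclass(frozen=True)
class TransducerSpec:
    """Piston geometry, drive frequency and source amplitude.

    ``source_amplitude`` is the surface pressure amplitude p0 = rho c u0 (Pa).
    ``curvature_radius`` (m) is required for the focused geometry.
    """
    geometry: str                     # "flat" | "focused"
    element_radius: float             # a, m
    frequency: float                  # Hz
    medium: AcousticMedium
    curvature_radius: Optional[float] = None
    source_amplitude: float = 1.0

    def __post_init__(self) -> None:
        if self.geometry not in ("flat", "focused"):
            raise ValidationError("geometry must be 'flat' or 'focused'")
        if not self.element_radius > 0:
            raise ValidationError("element_radius must be > 0")
        if not self.frequency > 0:
            raise ValidationError("frequency must be > 0")
        if self.geometry == "focused":
            if self.curvature_radius is None or not self.curvature_radius > 0:
                raise ValidationError("focused geometry requires curvature_radius > 0")

    @property
    def wavelength(self) -> float:
        return self.medium.c_long / self.frequency

    @property
    def wavenumber(self) -> float:
        return 2.0 * math.pi * self.frequency / self.medium.c_long

    @property
    def rayleigh_distance(self) -> float:
        """a^2/lambda, the conventional near-field length of a flat piston."""
        return self.element_radius ** 2 / self.wavelength


@dataclass(frozen=True)
class FieldMap:
    """|pressure| sampled on an axisymmetric (r, z) grid."""
    r: np.ndarray                     # m, strictly increasing, r[0] may be 0
    z: np.ndarray                     # m, strictly increasing
    pressure: np.ndarray              # Pa, shape (len(z), len(r))

    def __post_init__(self) -> None:
        if self.pressure.shape != (len(self.z), len(self.r)):
            raise ValidationError("pressure grid shape must be (len(z), len(r))")
        if np.any(self.pressure < 0):
            raise ValidationError("pressure magnitudes must be non-negative")

    def on_axis(self) -> np.ndarray:
        return self.pressure[:, 0]


@dataclass(frozen=True)
class FocalMetrics:
    """Focal-spot summary; lengths in mm, areas in mm^2.

    Length and width use the -6 dB (half-pressure) convention, recorded in
    ``conventions``.  ``iso_areas`` maps the band fraction (0.05, 0.15,
    0.25) to the area of the surface of revolution of the |p| =
    peak*(1-band) contour around the focal peak.
    """
    focal_distance_mm: float
    focal_length_mm: float
    focal_width_mm: float
    iso_areas_mm2: dict[float, float]
    peak_pressure_pa: float
    conventions: dict = field(default_factory=lambda: {
        "length_width": "-6 dB (half-pressure) extent",
        "iso_area": "surface of revolution of the peak*(1-band) contour",
    })


# ----------------------------------------------------------------------
# on-axis closed forms

def on_axis_flat(spec: TransducerSpec, z) -> np.ndarray | float:
    """Closed-form |p| on the axis of a flat baffled piston."""
    if spec.geometry != "flat":
        raise ValidationError("on_axis_flat requires a flat geometry")
    zs = np.asarray(z, dtype=float)
    if np.any(zs <= 0):
        raise ValidationError("axial positions must be > 0")
    a, k, p0 = spec.element_radius, spec.wavenumber, spec.source_amplitude
    mag = 2.0 * p0 * np.abs(np.sin(0.5 * k * (np.sqrt(zs**2 + a**2) - zs)))
    return mag if mag.ndim else float(mag)


def on_axis_focused(spec: TransducerSpec, z) -> np.ndarray | float:
    """O'Neil on-axis |p| of a spherically focused piston.

    |p(z)| = 2 p0 |sin(k (r_e - z)/2) / (1 - z/A)| with A the curvature
    radius, r_e the distance from the rim to the axial point; the removable
    singularity at z = A evaluates to p0 k h with h the cap depth.
    Converges to the flat closed form as A -> infinity.
    """
    if spec.geometry != "focused":
        raise ValidationError("on_axis_focused requires a focused geometry")
    zs = np.asarray(z, dtype=float)
    if np.any(zs <= 0):
        raise ValidationError("axial positions must be > 0")
    a, k, p0, A = (spec.element_radius, spec.wavenumber,
                   spec.source_amplitude, spec.curvature_radius)
    if a >= A:
        raise ValidationError("element radius must be smaller than curvature radius")
    h = A - math.sqrt(A * A - a * a)
    r_e = np.sqrt((zs - h) ** 2 + a * a)
    q = 1.0 - zs / A
    with np.errstate(divide="ignore", invalid="ignore"):
        mag = 2.0 * p0 * np.abs(np.sin(0.5 * k * (r_e - zs)) / q)
    mag = np.where(np.abs(q) < 1e-9, p0 * k * h, mag)
    return mag if mag.ndim else float(mag)


def last_axial_maximum(spec: TransducerSpec,
                       z_min: float = 1e-3,
                       z_max: Optional[float] = None,
                       step: float = 1e-6) -> float:
    """Axial position (m) of the last on-axis maximum of a flat piston.

    Dense grid scan (default 1 um step) followed by bounded local
    refinement; the result is the focal distance, approximately
    a^2/lambda - lambda/4.
    """
    if spec.geometry != "flat":
        raise ValidationError("last_axial_maximum is defined for flat pistons")
    if z_max is None:
        z_max = max(4.0 * spec.rayleigh_distance, z_min * 10.0)
    zs = np.arange(z_min, z_max, step)
    p = on_axis_flat(spec, zs)
    interior = (p[1:-1] >= p[:-2]) & (p[1:-1] >= p[2:])
    maxima = np.nonzero(interior)[0] + 1
    if len(maxima) == 0:
        raise ValidationError("no on-axis maximum in the scanned range; enlarge it")
    i = maxima[-1]
    lo, hi = zs[max(i - 2, 0)], zs[min(i + 2, len(zs) - 1)]
    res = minimize_scalar(lambda z: -on_axis_flat(spec, z),
                          bounds=(lo, hi), method="bounded",
                          options={"xatol": step * 1e-3})
    return float(res.x)


# ----------------------------------------------------------------------
# Rayleigh surface integral

def rayleigh_field_map(spec: TransducerSpec,
                       r_grid, z_grid,
                       n_radial: int = 48,
                       n_angular: int = 64) -> FieldMap:
    """|p(r, z)| by numerical quadrature of the Rayleigh integral.

    Gauss-Legendre in the source radius, periodic trapezoid in azimuth.
    For the focused geometry a focusing phase exp(+ik(sqrt(A^2+s^2)-A)) is
    applied across the aperture (thin-lens equalization to the curvature
    center).  The on-axis column of the flat map matches the closed form
    to better than 0.5% on sensible grids.
    """
    r = np.asarray(r_grid, dtype=float)
    z = np.asarray(z_grid, dtype=float)
    if r.ndim != 1 or z.ndim != 1 or np.any(np.diff(r) <= 0) or np.any(np.diff(z) <= 0):
        raise ValidationError("grids must be 1-D and strictly increasing")
    if np.any(z <= 0) or np.any(r < 0):
        raise ValidationError("grid must satisfy z > 0, r >= 0")
    focal = (spec.curvature_radius if spec.geometry == "focused"
             else spec.rayleigh_distance)
    if z[-1] > 4.0 * focal:
        warnings.warn("z grid extends beyond 4x the focal distance; "
                      "the model is unvalidated there", RuntimeWarning,
                      stacklevel=2)

    a, k, p0 = spec.element_radius, spec.wavenumber, spec.source_amplitude
    # Gauss-Legendre nodes on [0, a]
    x, w = np.polynomial.legendre.leggauss(n_radial)
    s = 0.5 * a * (x + 1.0)
    ws = 0.5 * a * w * s                       # includes the radial Jacobian
    phi = np.linspace(0.0, 2.0 * math.pi, n_angular, endpoint=False)
    wphi = 2.0 * math.pi / n_angular
    cphi = np.cos(phi)

    if spec.geometry == "focused":
        A = spec.curvature_radius
        lens = np.exp(1j * k * (np.sqrt(A * A + s * s) - A))
    else:
        lens = np.ones_like(s)

    # source points: s (radial) x phi (angular)
    s2 = s * s
    sc = s[:, None] * cphi[None, :]            # s*cos(phi), (n_radial, n_angular)

    pressure = np.empty((len(z), len(r)))
    for iz, zz in enumerate(z):
        # R^2 = z^2 + r^2 + s^2 - 2 r s cos(phi)
        R2 = (zz * zz + r[None, None, :] ** 2 + s2[:, None, None]
              - 2.0 * sc[:, :, None] * r[None, None, :])
        R = np.sqrt(R2)
        kern = np.exp(-1j * k * R) / R
        integ = np.einsum("i,ijr->r", ws * lens, kern) * wphi
        pressure[iz] = np.abs(1j * k * p0 / (2.0 * math.pi) * integ)
    return FieldMap(r=r, z=z, pressure=pressure)


# ----------------------------------------------------------------------
# focal metrics

def _interp_crossing(x0, x1, y0, y1, level):
    if y1 == y0:
        return x0
    return x0 + (level - y0) * (x1 - x0) / (y1 - y0)


def _half_extent(coords: np.ndarray, values: np.ndarray, i_peak: int,
                 level: float) -> tuple[float, float]:
    """Extent of the contiguous region >= level around index i_peak."""
    lo = coords[0]
    for i in range(i_peak, 0, -1):
        if values[i - 1] < level:
            lo = _interp_crossing(coords[i], coords[i - 1], values[i], values[i - 1], level)
            break
    hi = coords[-1]
    for i in range(i_peak, len(values) - 1):
        if values[i + 1] < level:
            hi = _interp_crossing(coords[i], coords[i + 1], values[i], values[i + 1], level)
            break
    return lo, hi


def focal_metrics(fmap: FieldMap,
                  iso_bands: tuple[float, ...] = (0.05, 0.15, 0.25)) -> FocalMetrics:
    """Summarize the focal spot of a sampled field map.

    The focal peak is the LAST on-axis local maximum within 10% of the
    on-axis supremum (the flat piston's near-field lobes reach the same
    amplitude as the focal lobe; the focal spot is by definition the final
    one).  Length and width are the -6 dB extents along and across the
    axis; iso-areas are surfaces of revolution of the |p| = peak*(1-band)
    contour component enclosing the peak.
    """
    from skimage import measure

    axis = fmap.on_axis()
    top = float(axis.max())
    if top <= 0 or np.allclose(axis, axis[0]):
        raise ValidationError("uniform or empty field map: focal peak undefined")
    interior = (axis[1:-1] >= axis[:-2]) & (axis[1:-1] >= axis[2:])
    candidates = np.nonzero(interior & (axis[1:-1] >= 0.9 * top))[0] + 1
    if len(candidates) == 0:
        raise ValidationError("no on-axis maximum inside the map; enlarge grid")
    iz = int(candidates[-1])
    if iz in (0, len(axis) - 1):
        raise ValidationError("focal peak on grid boundary: enlarge grid")
    peak = float(axis[iz])
    z_f = float(fmap.z[iz])

    half = 0.5 * peak
    z_mm = fmap.z * 1e3
    r_mm = fmap.r * 1e3
    lo, hi = _half_extent(z_mm, axis, iz, half)
    length_mm = hi - lo
    profile = fmap.pressure[iz, :]
    _, r_hi = _half_extent(r_mm, profile, 0, half)
    width_mm = 2.0 * r_hi

    iso_areas: dict[float, float] = {}
    # test point a quarter-pixel off the r=0 border so polygon containment
    # is unambiguous for contours clipped at the axis
    peak_pt = (float(iz), 0.25)

    for band in iso_bands:
        level = peak * (1.0 - band)
        area = 0.0
        for contour in measure.find_contours(fmap.pressure, level):
            closed = np.vstack([contour, contour[:1]])
            if not measure.points_in_poly(np.array([peak_pt]), closed)[0]:
                continue
            # map index coords -> physical mm
            zc = np.interp(contour[:, 0], np.arange(len(z_mm)), z_mm)
            rc = np.interp(contour[:, 1], np.arange(len(r_mm)), r_mm)
            ds = np.hypot(np.diff(zc), np.diff(rc))
            r_mid = 0.5 * (rc[:-1] + rc[1:])
            area += float(np.sum(2.0 * math.pi * r_mid * ds))
        iso_areas[band] = area

    return FocalMetrics(focal_distance_mm=z_f * 1e3,
                        focal_length_mm=length_mm,
                        focal_width_mm=width_mm,
                        iso_areas_mm2=iso_areas,
                        peak_pressure_pa=peak)
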