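"""Material property registry and elementary acoustic quantities.

Every medium on the ultrasonic path (immersion bath, microscope slide, cell
medium, coverslip, backing air) is described by an :class:`AcousticMedium`:
density, longitudinal and shear sound speeds, and a power-law attenuation
coefficient referenced to 1 MHz.  The specific acoustic impedance r = rho*c
governs reflection at interfaces; for small solids (microscope slides) the
*bar* longitudinal speed, set by the Young modulus, is the relevant one,
while extended solids propagate at the *bulk* speed set by the bulk and
shear moduli.

All internal computation is SI; the table I/O uses the customary
engineering units (kg/m^3, m/s, dB/cm).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from importlib import resources
from typing import Optional

import pandas as pd

from .errors import MaterialTableError, NoShearBranchError, ValidationError

#: 1 dB/cm expressed in Np/m: 100 cm/m divided by 20*log10(e) dB/Np.
DB_PER_CM_TO_NP_PER_M = 100.0 / (20.0 * math.log10(math.e))

#: Relative tolerance for the stored-speed vs. moduli-derived-speed check.
MODULI_SPEED_RTOL = 1e-3

_TABLE_COLUMNS = [
    "name", "density", "c_long", "c_shear",
    "alpha0_db_per_cm", "f_ref_hz", "alpha_exponent",
]
_MODULI_COLUMNS = ["K", "G", "E"]


@dataclass(frozen=True)
class AcousticMedium:
    """One material's acoustic description.

    Parameters
    ----------
    name : str
        Registry key.
    density : float
        Mass density, kg/m^3.
    c_long : float
        Longitudinal sound speed, m/s.
    c_shear : float
        Shear speed, m/s; 0 for fluids (no shear branch).
    alpha0_db_per_cm : float
        Attenuation at the reference frequency, dB/cm.
    f_ref_hz : float
        Reference frequency for the attenuation law, Hz.
    alpha_exponent : float
        Power-law exponent: alpha(f) = alpha0 * (f/f_ref)**exponent.
    bulk_modulus, shear_modulus, young_modulus : float, optional
        Elastic moduli (Pa).  When bulk and shear moduli are given they must
        reproduce the stored speeds to within ``MODULI_SPEED_RTOL``.
    """

    name: str
    density: float
    c_long: float
    c_shear: float = 0.0
    alpha0_db_per_cm: float = 0.0
    f_ref_hz: float = 1.0e6
    alpha_exponent: float = 1.0
    bulk_modulus: Optional[float] = None
    shear_modulus: Optional[float] = None
    young_modulus: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.density > 0:
            raise ValidationError(f"{self.name}: density must be > 0")
        if not self.c_long > 0:
            raise ValidationError(f"{self.name}: c_long must be > 0")
        if self.c_shear < 0:
            raise ValidationError(f"{self.name}: c_shear must be >= 0")
        if self.alpha0_db_per_cm < 0:
            raise ValidationError(f"{self.name}: alpha0 must be >= 0")
        if self.alpha_exponent < 0:
            raise ValidationError(f"{self.name}: alpha_exponent must be >= 0")
        if not self.f_ref_hz > 0:
            raise ValidationError(f"{self.name}: f_ref_hz must be > 0")
        for label, value in (("K", self.bulk_modulus),
                             ("G", self.shear_modulus),
                             ("E", self.young_modulus)):
            if value is not None and value < 0:
                raise ValidationError(f"{self.name}: modulus {label} must be >= 0")
        self._check_moduli_consistency()

    def _check_moduli_consistency(self) -> None:
        K, G = self.bulk_modulus, self.shear_modulus
        if K is None or G is None:
            return
        bulk_speed, _ = speeds_from_moduli(self.density, K=K, G=G)
        if abs(bulk_speed - self.c_long) > MODULI_SPEED_RTOL * self.c_long:
            raise ValidationError(
                f"{self.name}: bulk speed from moduli ({bulk_speed:.1f} m/s) "
                f"disagrees with stored c_long ({self.c_long:.1f} m/s)")
        if G > 0:
            shear_speed = math.sqrt(G / self.density)
            if abs(shear_speed - self.c_shear) > MODULI_SPEED_RTOL * max(self.c_shear, 1.0):
                raise ValidationError(
                    f"{self.name}: shear speed from G ({shear_speed:.1f} m/s) "
                    f"disagrees with stored c_shear ({self.c_shear:.1f} m/s)")

    @property
    def is_fluid(self) -> bool:
        return self.c_shear == 0.0

    def with_(self, **changes) -> "AcousticMedium":
        """Return a copy with the given fields replaced."""
        return replace(self, **changes)


def impedance(medium: AcousticMedium) -> float:
    """Specific acoustic impedance r = rho * c_long, in Pa.s/m (rayl)."""
    return medium.density * medium.c_long


def shear_impedance(medium: AcousticMedium) -> float:
    """Shear-wave impedance rho * c_shear; fluids have no shear branch."""
    if medium.c_shear == 0.0:
        raise NoShearBranchError(f"{medium.name}: fluid media carry no shear branch")
    return medium.density * medium.c_shear


def speeds_from_moduli(density: float,
                       K: Optional[float] = None,
                       G: Optional[float] = None,
                       E: Optional[float] = None,
                       ) -> tuple[Optional[float], Optional[float]]:
    """Longitudinal speeds from elastic moduli.

    Returns ``(bulk_speed, bar_speed)``: the bulk (extended-solid) speed
    sqrt((K + 4G/3)/rho) and the bar (thin-rod) speed sqrt(E/rho).  Either
    entry is None when its moduli were not supplied.
    """
    if not density > 0:
        raise ValidationError("density must be > 0")
    for label, value in (("K", K), ("G", G), ("E", E)):
        if value is not None and value < 0:
            raise ValidationError(f"modulus {label} must be >= 0")
    bulk_speed = None
    if K is not None and G is not None:
        bulk_speed = math.sqrt((K + 4.0 * G / 3.0) / density)
    bar_speed = math.sqrt(E / density) if E is not None else None
    return bulk_speed, bar_speed


def attenuation_at(medium: AcousticMedium, f: float) -> float:
    """Amplitude attenuation coefficient alpha(f) in Np/m.

    Power law: alpha(f) = alpha0 * (f/f_ref)**exponent, converted from the
    tabulated dB/cm.
    """
    if not f > 0:
        raise ValidationError("frequency must be > 0")
    alpha_db_cm = medium.alpha0_db_per_cm * (f / medium.f_ref_hz) ** medium.alpha_exponent
    return alpha_db_cm * DB_PER_CM_TO_NP_PER_M


class MaterialRegistry:
    """Name-keyed collection of :class:`AcousticMedium` records."""

    def __init__(self, media: dict[str, AcousticMedium] | None = None):
        self._media: dict[str, AcousticMedium] = dict(media or {})

    def __getitem__(self, name: str) -> AcousticMedium:
        try:
            return self._media[name]
        except KeyError:
            raise KeyError(
                f"unknown material {name!r}; available: {sorted(self._media)}") from None

    def __contains__(self, name: str) -> bool:
        return name in self._media

    def __iter__(self):
        return iter(self._media.values())

    def __len__(self) -> int:
        return len(self._media)

    def __eq__(self, other) -> bool:
        return isinstance(other, MaterialRegistry) and self._media == other._media

    def names(self) -> list[str]:
        return sorted(self._media)

    def add(self, medium: AcousticMedium) -> None:
        self._media[medium.name] = medium

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for m in sorted(self._media.values(), key=lambda m: m.name):
            rows.append({
                "name": m.name, "density": m.density, "c_long": m.c_long,
                "c_shear": m.c_shear, "alpha0_db_per_cm": m.alpha0_db_per_cm,
                "f_ref_hz": m.f_ref_hz, "alpha_exponent": m.alpha_exponent,
                "K": m.bulk_modulus, "G": m.shear_modulus, "E": m.young_modulus,
            })
        return pd.DataFrame(rows, columns=_TABLE_COLUMNS + _MODULI_COLUMNS)

    def save(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _medium_from_row(row: pd.Series, row_label) -> AcousticMedium:
    def num(col, default=None, required=True):
        value = row.get(col)
        if value is None or (isinstance(value, float) and math.isnan(value)):
            if required:
                raise MaterialTableError(f"row {row_label!r}: missing value in column {col!r}")
            return default
        try:
            return float(value)
        except (TypeError, ValueError):
            raise MaterialTableError(
                f"row {row_label!r}: non-numeric value {value!r} in column {col!r}") from None

    try:
        return AcousticMedium(
            name=str(row["name"]),
            density=num("density"),
            c_long=num("c_long"),
            c_shear=num("c_shear", 0.0, required=False) or 0.0,
            alpha0_db_per_cm=num("alpha0_db_per_cm", 0.0, required=False) or 0.0,
            f_ref_hz=num("f_ref_hz", 1.0e6, required=False) or 1.0e6,
            alpha_exponent=num("alpha_exponent", 1.0, required=False),
            bulk_modulus=num("K", required=False),
            shear_modulus=num("G", required=False),
            young_modulus=num("E", required=False),
        )
    except ValidationError as exc:
        raise MaterialTableError(f"row {row_label!r}: {exc}") from exc


def load_material_table(path) -> MaterialRegistry:
    """Load a CSV material table into a registry.

    Required columns: ``name, density, c_long``; optional: ``c_shear,
    alpha0_db_per_cm, f_ref_hz, alpha_exponent, K, G, E``.  Parse errors
    name the offending row and column.
    """
    frame = pd.read_csv(path)
    for col in ("name", "density", "c_long"):
        if col not in frame.columns:
            raise MaterialTableError(f"material table missing required column {col!r}")
    registry = MaterialRegistry()
    for _, row in frame.iterrows():
        registry.add(_medium_from_row(row, row["name"]))
    return registry


def default_materials() -> MaterialRegistry:
    """The shipped default table (water, glass, polystyrene, adiprene,
    polyethylene, air) with pinned handbook constants."""
    with resources.as_file(resources.files("sonochamber.data") / "materials.csv") as path:
        return load_material_table(path)
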