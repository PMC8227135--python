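"""Chamber design model and end-to-end acoustic evaluation pipeline.

A :class:`ChamberDesign` captures the exposure-chamber geometry: an
immersion transducer firing through a water bath at an oblique design
angle (default 26.5 degrees) onto a microscope slide (default glass,
1.2 mm), through the thin sample gap (10-20 um of cell medium, set either
directly or as drop volume / contact area), through the coverslip and into
the backing air.  :func:`evaluate_design` runs the full pipeline —
free-field calibration of the piston source, five-layer oblique solve,
attenuation and standing-wave bookkeeping, critical-angle verdicts, bubble
resonance and mechanical index — into a :class:`DesignReport`, every
number carrying its units and every modelling assumption echoed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import yaml

from . import bubble as bubble_mod
from . import multilayer, piston, planewave
from .errors import ValidationError
from .materials import AcousticMedium, MaterialRegistry, default_materials
from .multilayer import HALF_SPACE, LayerStack


def gap_from_volume(volume: float, area: float) -> float:
    """Sample gap L = drop volume / coverslip contact area (SI: m)."""
    if volume < 0:
        raise ValidationError("volume must be >= 0")
    if not area > 0:
        raise ValidationError("contact area must be > 0")
    return volume / area


def minimum_bath_volume(R: float, H: float) -> int:
    """Smallest whole number of mL not below the water cylinder pi R^2 H.

    R and H are lower bounds (transducer external radius, focal distance),
    so the volume is rounded up.  This is the classical-bath volume the
    microliter chamber replaces.
    """
    if R < 0 or H < 0:
        raise ValidationError("R and H must be >= 0")
    volume_ml = math.pi * R * R * H * 1e6
    return int(math.ceil(volume_ml - 1e-12))


@dataclass(frozen=True)
class ChamberDesign:
    """Exposure-chamber geometry and exposure conditions.

    The sample gap is given either directly (``gap_m``) or as a drop
    volume and contact area — exactly one of the two forms.
    """
    incidence_angle_deg: float = 26.5
    bath_material: str = "water"
    slide_material: str = "glass"
    slide_thickness_m: float = 1.2e-3
    sample_material: str = "water"
    gap_m: Optional[float] = 15e-6
    sample_volume_m3: Optional[float] = None
    contact_area_m2: Optional[float] = None
    gap_range_m: tuple[float, float] = (10e-6, 20e-6)
    coverslip_material: str = "glass"
    coverslip_thickness_m: float = 0.17e-3
    backing_material: str = "air"
    frequency_hz: float = 1.0e6
    element_radius_m: float = 9.43e-3
    transducer_external_radius_m: float = 12.5e-3
    focal_distance_m: float = 60e-3
    calibration_focal_pressure_pa: float = 500e3
    bubble_radius_m: float = 1.5e-6

    def __post_init__(self) -> None:
        if not 0.0 <= self.incidence_angle_deg < 90.0:
            raise ValidationError("incidence angle must be in [0, 90) degrees")
        if not self.slide_thickness_m > 0:
            raise ValidationError("slide thickness must be > 0")
        direct = self.gap_m is not None
        derived = self.sample_volume_m3 is not None and self.contact_area_m2 is not None
        if direct == derived:
            raise ValidationError(
                "give exactly one of gap_m or (sample_volume_m3 + contact_area_m2)")
        if direct and not self.gap_m > 0:
            raise ValidationError("gap must be > 0")

    @property
    def gap(self) -> float:
        if self.gap_m is not None:
            return self.gap_m
        return gap_from_volume(self.sample_volume_m3, self.contact_area_m2)

    def stack(self, materials: MaterialRegistry,
              slide: Optional[str] = None,
              coverslip: Optional[str] = None) -> LayerStack:
        """The five-layer bath | slide | sample | coverslip | backing stack."""
        return LayerStack.from_sequence([
            (materials[self.bath_material], HALF_SPACE),
            (materials[slide or self.slide_material], self.slide_thickness_m),
            (materials[self.sample_material], self.gap),
            (materials[coverslip or self.coverslip_material], self.coverslip_thickness_m),
            (materials[self.backing_material], HALF_SPACE),
        ])

    def transducer(self, materials: MaterialRegistry,
                   source_amplitude: float = 1.0) -> piston.TransducerSpec:
        return piston.TransducerSpec(
            geometry="flat", element_radius=self.element_radius_m,
            frequency=self.frequency_hz, medium=materials[self.bath_material],
            source_amplitude=source_amplitude)


@dataclass(frozen=True)
class DesignReport:
    """Evaluated acoustic summary of a chamber design."""
    free_field_focal_pressure_pa: float
    focal_distance_m: float
    source_amplitude_pa: float
    transmitted_sample_peak_pa: float
    transmitted_amplitude_ratio: float
    power_transmission_fraction: float
    power_reflection_fraction: float
    attenuation_loss_pct_per_layer: dict[str, float]
    standing_wave_ratio_min: float
    standing_wave_ratio_max: float
    critical_angle_long_deg: Optional[float]
    critical_angle_shear_deg: Optional[float]
    beyond_critical_long: Optional[bool]
    beyond_critical_shear: Optional[bool]
    bubble_radius_m: float
    bubble_resonance_hz: float
    mechanical_index: float
    minimum_bath_volume_ml: int
    reference_transmitted_pressure_pa: float
    assumptions: tuple[str, ...]

    def to_dict(self) -> dict:
        d = {
            "free_field_focal_pressure_pa": self.free_field_focal_pressure_pa,
            "focal_distance_m": self.focal_distance_m,
            "source_amplitude_pa": self.source_amplitude_pa,
            "transmitted_sample_peak_pa": self.transmitted_sample_peak_pa,
            "transmitted_amplitude_ratio": self.transmitted_amplitude_ratio,
            "power_transmission_fraction": self.power_transmission_fraction,
            "power_reflection_fraction": self.power_reflection_fraction,
            "attenuation_loss_pct_per_layer": self.attenuation_loss_pct_per_layer,
            "standing_wave_ratio_min": self.standing_wave_ratio_min,
            "standing_wave_ratio_max": self.standing_wave_ratio_max,
            "critical_angle_long_deg": self.critical_angle_long_deg,
            "critical_angle_shear_deg": self.critical_angle_shear_deg,
            "beyond_critical_long": self.beyond_critical_long,
            "beyond_critical_shear": self.beyond_critical_shear,
            "bubble_radius_m": self.bubble_radius_m,
            "bubble_resonance_hz": self.bubble_resonance_hz,
            "mechanical_index": self.mechanical_index,
            "minimum_bath_volume_ml": self.minimum_bath_volume_ml,
            "reference_transmitted_pressure_pa": self.reference_transmitted_pressure_pa,
            "assumptions": list(self.assumptions),
        }
        return d

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent, sort_keys=True)


def evaluate_design(design: ChamberDesign,
                    materials: Optional[MaterialRegistry] = None,
                    n_gap_points: int = 21) -> DesignReport:
    """Run the full chamber evaluation pipeline.

    1. Solve the piston source amplitude so the free-field focal peak
       equals the calibrated focal pressure (hydrophone matching).
    2. Build the five-layer stack and solve it at the design incidence
       angle with the layered (lateral-wavenumber-conserving) model.
    3. Report the transmitted sample-layer peak amplitude, per-layer
       attenuation losses, the standing-wave excursion over the declared
       gap range, and critical-angle verdicts.
    4. Attach bubble resonance, mechanical index at the transmitted
       pressure, and the classical-bath minimum volume for comparison.

    Zero transmitted power (incidence beyond every open branch) is
    reported, not raised.
    """
    materials = materials if materials is not None else default_materials()

    # (1) free-field calibration
    spec_unit = design.transducer(materials, source_amplitude=1.0)
    z_focus = piston.last_axial_maximum(spec_unit, step=1e-5)
    peak_unit = piston.on_axis_flat(spec_unit, z_focus)
    p0 = design.calibration_focal_pressure_pa / peak_unit

    # (2) layered solve at the design angle
    stack = design.stack(materials)
    theta = design.incidence_angle_deg
    sol = (multilayer.solve_normal(stack, design.frequency_hz) if theta == 0.0
           else multilayer.solve_oblique(stack, design.frequency_hz, theta))
    sample_ratio = sol.max_pressure_in_layer(2)
    transmitted_peak = sample_ratio * design.calibration_focal_pressure_pa

    # (3) per-layer attenuation and standing-wave excursion
    losses = {}
    for j, (medium, d) in enumerate(stack.layers[1:-1], start=1):
        losses[f"layer{j}_{medium.name}"] = 100.0 * multilayer.power_loss_through(
            medium, d, design.frequency_hz)
    gaps = np.linspace(*design.gap_range_m, n_gap_points)
    sweep = multilayer.sample_amplitude_vs_gap(stack, gaps, design.frequency_hz,
                                               theta_i=theta)
    sw_min = float(sweep["amplitude_ratio"].min())
    sw_max = float(sweep["amplitude_ratio"].max())

    bath = materials[design.bath_material]
    slide = materials[design.slide_material]
    crit = planewave.critical_angles(bath, slide)
    beyond_long = None if crit.longitudinal is None else theta >= crit.longitudinal
    beyond_shear = None if crit.shear is None else theta >= crit.shear

    # (4) bubble response and bath comparison
    params = bubble_mod.BubbleParameters(R0=design.bubble_radius_m)
    f0 = bubble_mod.resonance_frequency(params)
    mi = bubble_mod.mechanical_index(bubble_mod.ExposureSetting(
        pnp_kpa=transmitted_peak / 1e3, f_hz=design.frequency_hz))
    bath_ml = minimum_bath_volume(design.transducer_external_radius_m,
                                  design.focal_distance_m)

    assumptions = (
        f"element radius a = {design.element_radius_m*1e3:.2f} mm inferred so "
        f"a^2/lambda matches the {design.focal_distance_m*1e3:.0f} mm focal "
        "distance (active aperture not printed on the transducer datasheet)",
        "free-field flat-piston model (no tube walls); the reference "
        "transmitted pressure of 380 kPa comes from a bounded finite-element "
        "model and is NOT claimed by this pipeline (model difference)",
        "focal-zone plane-wave approximation: the layered oblique solve "
        "conserves the lateral wavenumber, no beam-spread correction at the "
        "60 mm scale",
        "attenuation losses per layer quoted along the layer normal",
        "design incidence angle treated as a geometric constant",
        "classical-bath comparison cites a Clinicell internal volume quoted "
        "as 'about 12.5 mL' and elsewhere 'about 10 mL'",
    )

    return DesignReport(
        free_field_focal_pressure_pa=design.calibration_focal_pressure_pa,
        focal_distance_m=z_focus,
        source_amplitude_pa=p0,
        transmitted_sample_peak_pa=transmitted_peak,
        transmitted_amplitude_ratio=sample_ratio,
        power_transmission_fraction=sol.power_transmission,
        power_reflection_fraction=sol.power_reflection,
        attenuation_loss_pct_per_layer=losses,
        standing_wave_ratio_min=sw_min,
        standing_wave_ratio_max=sw_max,
        critical_angle_long_deg=crit.longitudinal,
        critical_angle_shear_deg=crit.shear,
        beyond_critical_long=beyond_long,
        beyond_critical_shear=beyond_shear,
        bubble_radius_m=design.bubble_radius_m,
        bubble_resonance_hz=f0,
        mechanical_index=mi,
        minimum_bath_volume_ml=bath_ml,
        reference_transmitted_pressure_pa=380e3,
        assumptions=assumptions,
    )


@dataclass(frozen=True)
class SensitivityComparison:
    """Gap-sweep excursions for two candidate wall materials."""
    excursion_a: float
    excursion_b: float
    material_a: str
    material_b: str

    @property
    def more_sensitive(self) -> str:
        return self.material_a if self.excursion_a >= self.excursion_b else self.material_b


def material_sensitivity_sweep(design: ChamberDesign,
                               L_range: Sequence[float],
                               materials: Optional[MaterialRegistry] = None,
                               material_a: str = "glass",
                               material_b: str = "polystyrene",
                               theta_i: float = 0.0) -> SensitivityComparison:
    """Compare the standing-wave sensitivity to the gap L for two wall
    materials (slide and coverslip set together).

    Reports the (max - min) excursion of the sample-layer peak amplitude
    over ``L_range`` for each material.  Glass walls, with their larger
    impedance contrast to the cell medium, show a larger excursion than
    polystyrene ones.
    """
    materials = materials if materials is not None else default_materials()
    L = list(L_range)
    if len(L) == 0:
        raise ValidationError("L_range must be non-empty")

    def excursion(wall: str) -> float:
        stack = design.stack(materials, slide=wall, coverslip=wall)
        sweep = multilayer.sample_amplitude_vs_gap(
            stack, L, design.frequency_hz, theta_i=theta_i)
        return float(sweep["amplitude_ratio"].max() - sweep["amplitude_ratio"].min())

    return SensitivityComparison(
        excursion_a=excursion(material_a), excursion_b=excursion(material_b),
        material_a=material_a, material_b=material_b)


# ----------------------------------------------------------------------
# config I/O

def design_from_config(config: dict) -> ChamberDesign:
    """Build a ChamberDesign from a nested config mapping.

    Sections: ``transducer``, ``chamber``, ``calibration``, ``bubble``
    (all optional; missing keys keep the defaults).
    """
    tr = config.get("transducer", {})
    ch = config.get("chamber", {})
    cal = config.get("calibration", {})
    bu = config.get("bubble", {})
    kwargs: dict = {}

    def put(key, value):
        if value is not None:
            kwargs[key] = value

    put("frequency_hz", tr.get("frequency_hz"))
    put("element_radius_m", tr.get("element_radius_m"))
    put("transducer_external_radius_m", tr.get("external_radius_m"))
    put("focal_distance_m", tr.get("focal_distance_m"))
    put("incidence_angle_deg", ch.get("incidence_angle_deg"))
    put("bath_material", ch.get("bath_material"))
    put("slide_material", ch.get("slide_material"))
    put("slide_thickness_m", ch.get("slide_thickness_m"))
    put("sample_material", ch.get("sample_material"))
    put("coverslip_material", ch.get("coverslip_material"))
    put("coverslip_thickness_m", ch.get("coverslip_thickness_m"))
    put("backing_material", ch.get("backing_material"))
    if "sample_volume_m3" in ch or "contact_area_m2" in ch:
        kwargs["gap_m"] = None
        put("sample_volume_m3", ch.get("sample_volume_m3"))
        put("contact_area_m2", ch.get("contact_area_m2"))
    else:
        put("gap_m", ch.get("gap_m"))
    if "gap_range_m" in ch:
        kwargs["gap_range_m"] = tuple(ch["gap_range_m"])
    put("calibration_focal_pressure_pa", cal.get("focal_pressure_pa"))
    put("bubble_radius_m", bu.get("radius_m"))
    return ChamberDesign(**kwargs)


def load_design(path) -> ChamberDesign:
    """Load a YAML chamber config file."""
    with open(path) as fh:
        config = yaml.safe_load(fh) or {}
    return design_from_config(config)
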