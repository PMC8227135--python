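import json
import math

import numpy as np
import pytest
import yaml
from click.testing import CliRunner

import sonochamber as sc
from sonochamber.cli import main as cli_main


class TestGapFromVolume:
    def test_square_coverslip_drop(self):
        # 3.24 uL under an 18 x 18 mm coverslip -> 10 um
        assert sc.gap_from_volume(3.24e-9, 0.018 ** 2) == pytest.approx(10e-6)

    def test_zero_volume(self):
        assert sc.gap_from_volume(0.0, 1e-4) == 0.0

    def test_circular_coverslip_drop(self):
        area = math.pi * (25.2e-3 / 2) ** 2
        assert sc.gap_from_volume(10e-9, area) == pytest.approx(20e-6, rel=5e-3)

    def test_nonpositive_area_rejected(self):
        with pytest.raises(sc.ValidationError):
            sc.gap_from_volume(1e-9, 0.0)


class TestMinimumBathVolume:
    def test_transducer_and_focal_distance_bath(self):
        # 12.5 mm external radius, 6 cm focal distance
        assert sc.minimum_bath_volume(12.5e-3, 60e-3) == 30

    def test_degenerate_dimensions(self):
        assert sc.minimum_bath_volume(0.0, 0.1) == 0
        assert sc.minimum_bath_volume(0.05, 0.0) == 0

    def test_ceiling_of_cylinder_volume(self):
        assert sc.minimum_bath_volume(10e-3, 50e-3) == 16   # ceil(15.7 mL)

    def test_monotone_in_radius_and_height(self):
        vols = [sc.minimum_bath_volume(r, 0.06) for r in np.linspace(0, 0.02, 9)]
        assert vols == sorted(vols)
        vols = [sc.minimum_bath_volume(0.0125, h) for h in np.linspace(0, 0.1, 9)]
        assert vols == sorted(vols)


class TestDesignValidation:
    def test_gap_and_volume_are_exclusive(self):
        with pytest.raises(sc.ValidationError):
            sc.ChamberDesign(gap_m=10e-6, sample_volume_m3=1e-9,
                             contact_area_m2=1e-4)
        with pytest.raises(sc.ValidationError):
            sc.ChamberDesign(gap_m=None)

    def test_gap_derived_from_volume(self):
        d = sc.ChamberDesign(gap_m=None, sample_volume_m3=3.24e-9,
                             contact_area_m2=0.018 ** 2)
        assert d.gap == pytest.approx(10e-6)


@pytest.fixture(scope="module")
def report(registry):
    return sc.evaluate_design(sc.ChamberDesign(), registry)


class TestEvaluateDesign:
    def test_transmitted_amplitude_below_free_field_calibration(self, report):
        assert 0.0 < report.transmitted_sample_peak_pa < 500e3

    def test_design_angle_sits_beyond_both_glass_critical_angles(self, report):
        assert report.beyond_critical_long and report.beyond_critical_shear
        assert report.critical_angle_shear_deg == pytest.approx(25.80, abs=0.05)

    def test_focal_calibration(self, report):
        assert report.free_field_focal_pressure_pa == 500e3
        assert report.focal_distance_m == pytest.approx(60e-3, rel=0.01)
        # peak gain of a flat piston is 2 p0
        assert report.source_amplitude_pa == pytest.approx(250e3, rel=1e-3)

    def test_bath_comparison_attached(self, report):
        assert report.minimum_bath_volume_ml == 30

    def test_every_assumption_echoed(self, report):
        assert len(report.assumptions) > 0

    def test_no_walls_homogeneous_path_transmits_calibration(self, lossless):
        design = sc.ChamberDesign(slide_material="water",
                                  coverslip_material="water",
                                  backing_material="water")
        rep = sc.evaluate_design(design, lossless)
        assert rep.transmitted_sample_peak_pa == pytest.approx(500e3, rel=1e-9)

    def test_normal_incidence_matches_brute_force_oracle(self, lossless):
        design = sc.ChamberDesign(incidence_angle_deg=0.0)
        rep = sc.evaluate_design(design, lossless)
        stack = design.stack(lossless)
        bf = sc.brute_force_five_layer(stack, design.frequency_hz)
        assert rep.transmitted_amplitude_ratio == pytest.approx(
            bf.max_pressure_in_layer(2), rel=1e-9)

    def test_pipeline_and_library_agree(self, registry, report):
        design = sc.ChamberDesign()
        sol = sc.solve_oblique(design.stack(registry), design.frequency_hz,
                               design.incidence_angle_deg)
        assert report.transmitted_amplitude_ratio == pytest.approx(
            sol.max_pressure_in_layer(2), rel=1e-12)

    def test_unknown_material_raises_keyerror(self):
        with pytest.raises(KeyError, match="vibranium"):
            sc.evaluate_design(sc.ChamberDesign(slide_material="vibranium"))


class TestMaterialSensitivity:
    def test_glass_more_sensitive_than_polystyrene(self, lossless):
        lam = lossless["water"].c_long / 1e6
        comp = sc.material_sensitivity_sweep(
            sc.ChamberDesign(), np.linspace(1e-6, lam / 2, 80), lossless)
        assert comp.excursion_a > comp.excursion_b
        assert comp.more_sensitive == "glass"

    def test_water_walls_with_water_backing_insensitive(self, lossless):
        design = sc.ChamberDesign(backing_material="water")
        comp = sc.material_sensitivity_sweep(
            design, np.linspace(10e-6, 20e-6, 5), lossless,
            material_a="water", material_b="water")
        assert comp.excursion_a == pytest.approx(0.0, abs=1e-9)

    def test_single_point_range_has_zero_excursion(self, registry):
        comp = sc.material_sensitivity_sweep(sc.ChamberDesign(), [15e-6], registry)
        assert comp.excursion_a == 0.0 and comp.excursion_b == 0.0

    def test_empty_range_rejected(self, registry):
        with pytest.raises(sc.ValidationError):
            sc.material_sensitivity_sweep(sc.ChamberDesign(), [], registry)


class TestConfig:
    def test_defaults_round_trip_through_yaml(self, tmp_path):
        config = {
            "transducer": {"frequency_hz": 1e6, "element_radius_m": 9.43e-3},
            "chamber": {"incidence_angle_deg": 26.5, "gap_m": 15e-6},
            "calibration": {"focal_pressure_pa": 500e3},
            "bubble": {"radius_m": 1.5e-6},
        }
        path = tmp_path / "design.yaml"
        path.write_text(yaml.safe_dump(config))
        assert sc.load_design(path) == sc.ChamberDesign()

    def test_volume_form_in_config(self):
        d = sc.design_from_config({"chamber": {
            "sample_volume_m3": 3.24e-9, "contact_area_m2": 0.018 ** 2}})
        assert d.gap == pytest.approx(10e-6)


class TestCli:
    def test_evaluate_writes_report(self, tmp_path):
        runner = CliRunner()
        out = tmp_path / "report.json"
        result = runner.invoke(cli_main, ["evaluate", "--out", str(out)])
        assert result.exit_code == 0, result.output
        report = json.loads(out.read_text())
        assert report["minimum_bath_volume_ml"] == 30
        assert report["transmitted_sample_peak_pa"] < 500e3

    def test_unknown_material_fails_with_name(self, tmp_path):
        runner = CliRunner()
        cfg = tmp_path / "bad.yaml"
        cfg.write_text("chamber:\n  slide_material: vibranium\n")
        result = runner.invoke(cli_main, ["evaluate", "--config", str(cfg),
                                          "--out", str(tmp_path / "r.json")])
        assert result.exit_code != 0
        assert "vibranium" in result.output

    def test_repeat_runs_are_byte_identical(self, tmp_path):
        runner = CliRunner()
        a, b = tmp_path / "a.json", tmp_path / "b.json"
        assert runner.invoke(cli_main, ["--seed", "3", "evaluate",
                                        "--out", str(a)]).exit_code == 0
        assert runner.invoke(cli_main, ["--seed", "3", "evaluate",
                                        "--out", str(b)]).exit_code == 0
        assert a.read_bytes() == b.read_bytes()

    def test_materials_listing(self):
        result = CliRunner().invoke(cli_main, ["materials"])
        assert result.exit_code == 0
        assert "water" in result.output and "glass" in result.output

    def test_bubble_subcommand_reports_resonance_and_mi(self):
        result = CliRunner().invoke(cli_main, ["bubble", "--radius-um", "3",
                                               "--pnp-kpa", "380"])
        assert result.exit_code == 0
        payload = json.loads(result.output)
        assert payload["mechanical_index"] == pytest.approx(0.38)
        assert payload["resonance_frequency_hz"] > 0

    def test_sweep_gap_writes_csv(self, tmp_path):
        out = tmp_path / "sweep.csv"
        result = CliRunner().invoke(cli_main, [
            "sweep-gap", "--n", "5", "--out", str(out)])
        assert result.exit_code == 0, result.output
        header = out.read_text().splitlines()[0]
        assert header == "L_um,amplitude_ratio"
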