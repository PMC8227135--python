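import cmath
import math

import numpy as np
import pytest

import sonochamber as sc
from sonochamber.materials import attenuation_at

from conftest import chamber_stack

F = 1.0e6


def two_media(m1, m2):
    return sc.LayerStack.from_sequence([(m1, sc.HALF_SPACE), (m2, sc.HALF_SPACE)])


def oblique_fluid_transfer(stack, f, theta_i):
    """Independent fluid-branch oblique oracle: 2x2 transfer matrix with
    the angle-dependent impedance rho*omega/kz.  Lossless media only."""
    media, ds = stack.media, stack.thicknesses
    omega = 2 * math.pi * f
    kx = (omega / media[0].c_long) * math.sin(math.radians(theta_i))
    kz, Z = [], []
    for m in media:
        k = omega / m.c_long
        kzj = cmath.sqrt(k * k - kx * kx)
        if kzj.imag > 0 or (kzj.imag == 0 and kzj.real < 0):
            kzj = -kzj
        kz.append(kzj)
        Z.append(m.density * omega / kzj)
    M = np.eye(2, dtype=complex)
    for j in range(1, len(media) - 1):
        kd = kz[j] * ds[j]
        M = M @ np.array([[np.cos(kd), 1j * Z[j] * np.sin(kd)],
                          [1j * np.sin(kd) / Z[j], np.cos(kd)]])
    X = M[0, 0] + M[0, 1] / Z[-1]
    Y = Z[0] * (M[1, 0] + M[1, 1] / Z[-1])
    T, R = 2.0 / (X + Y), (X - Y) / (X + Y)
    t_pow = abs(T) ** 2 * (1.0 / Z[-1]).conjugate().real / (1.0 / Z[0]).conjugate().real
    return R, T, t_pow


class TestStackValidation:
    def test_needs_two_half_spaces(self, water):
        with pytest.raises(sc.ValidationError):
            sc.LayerStack.from_sequence([(water, sc.HALF_SPACE)])

    def test_interior_layers_must_be_finite(self, water, glass):
        with pytest.raises(sc.ValidationError):
            sc.LayerStack.from_sequence([
                (water, sc.HALF_SPACE), (glass, sc.HALF_SPACE),
                (water, sc.HALF_SPACE)])

    def test_ends_must_be_half_spaces(self, water, glass):
        with pytest.raises(sc.ValidationError):
            sc.LayerStack.from_sequence([(water, 1e-3), (glass, sc.HALF_SPACE)])


class TestSolveNormal:
    def test_single_interface_matches_intensity_coefficient(self, lossless):
        water, glass = lossless["water"], lossless["glass"]
        sol = sc.solve_normal(two_media(water, glass), F)
        expected = sc.normal_coeffs(sc.impedance(water), sc.impedance(glass)).Ti
        assert sol.power_transmission == pytest.approx(expected, rel=1e-9)

    def test_chamber_stack_matches_brute_force_oracle(self, default_stack):
        tm = sc.solve_normal(default_stack, F)
        bf = sc.brute_force_five_layer(default_stack, F)
        assert tm.pressure_reflection == pytest.approx(bf.pressure_reflection, rel=1e-10)
        assert tm.pressure_transmission == pytest.approx(bf.pressure_transmission, rel=1e-10)
        for wa, wb in zip(tm.waves, bf.waves):
            assert abs(wa.p_down - wb.p_down) < 1e-10
            assert abs(wa.p_up - wb.p_up) < 1e-10

    def test_identity_layer_leaves_coefficients_unchanged(self, lossless):
        # exact invariance needs lossless media: an attenuating pad absorbs
        water, glass = lossless["water"], lossless["glass"]
        base = two_media(water, glass)
        padded = sc.LayerStack.from_sequence([
            (water, sc.HALF_SPACE), (water, 3.7e-3), (glass, sc.HALF_SPACE)])
        a, b = sc.solve_normal(base, F), sc.solve_normal(padded, F)
        assert abs(a.pressure_transmission) == pytest.approx(
            abs(b.pressure_transmission), rel=1e-12)
        assert a.power_transmission == pytest.approx(b.power_transmission, rel=1e-12)

    def test_zero_thickness_layer_elided(self, water, glass, air):
        with_zero = sc.LayerStack.from_sequence([
            (water, sc.HALF_SPACE), (glass, 0.0), (air, sc.HALF_SPACE)])
        a = sc.solve_normal(with_zero, F)
        b = sc.solve_normal(two_media(water, air), F)
        assert a.pressure_transmission == pytest.approx(b.pressure_transmission, rel=1e-12)

    def test_reciprocity_of_lossless_power_transmission(self, lossless_stack):
        fwd = sc.solve_normal(lossless_stack, F)
        rev = sc.solve_normal(lossless_stack.reversed(), F)
        assert fwd.power_transmission == pytest.approx(rev.power_transmission, rel=1e-9)

    def test_air_backing_reflects_nearly_everything(self, lossless_stack):
        sol = sc.solve_normal(lossless_stack, F)
        assert sol.power_reflection > 0.99

    @pytest.mark.parametrize("seed", range(40))
    def test_oracle_equivalence_and_energy_on_random_stacks(self, seed):
        stack = sc.generate_random_stack(seed, 5)
        tm = sc.solve_normal(stack, F)
        bf = sc.brute_force_five_layer(stack, F)
        scale = max(abs(tm.pressure_transmission), abs(tm.pressure_reflection), 1.0)
        assert abs(tm.pressure_reflection - bf.pressure_reflection) < 1e-9 * scale
        assert abs(tm.pressure_transmission - bf.pressure_transmission) < 1e-9 * scale
        assert tm.power_transmission + tm.power_reflection == pytest.approx(1.0, abs=1e-9)


class TestSolveOblique:
    def test_zero_angle_reproduces_normal_solution(self, default_stack):
        nm = sc.solve_normal(default_stack, F)
        ob = sc.solve_oblique(default_stack, F, 0.0)
        assert ob.pressure_reflection == pytest.approx(nm.pressure_reflection, abs=1e-12)
        assert ob.pressure_transmission == pytest.approx(nm.pressure_transmission, abs=1e-12)
        assert ob.max_pressure_in_layer(2) == pytest.approx(
            nm.max_pressure_in_layer(2), rel=1e-10)

    def test_small_angle_continuity(self, default_stack):
        nm = sc.solve_normal(default_stack, F)
        ob = sc.solve_oblique(default_stack, F, 1e-4)
        assert abs(ob.pressure_reflection - nm.pressure_reflection) < 1e-6

    @pytest.mark.parametrize("theta", [5.0, 15.0, 25.0, 40.0])
    def test_all_fluid_stack_matches_fluid_transfer_matrix(self, lossless, theta):
        w = lossless["water"]
        ps_fluid = lossless["polystyrene"].with_(c_shear=0.0)
        stack = sc.LayerStack.from_sequence([
            (w, sc.HALF_SPACE), (ps_fluid, 0.5e-3), (w, 20e-6),
            (ps_fluid, 0.3e-3), (w, sc.HALF_SPACE)])
        sol = sc.solve_oblique(stack, F, theta)
        R, T, t_pow = oblique_fluid_transfer(stack, F, theta)
        assert sol.pressure_reflection == pytest.approx(R, abs=1e-9)
        assert sol.pressure_transmission == pytest.approx(T, abs=1e-9)
        assert sol.power_transmission == pytest.approx(t_pow, rel=1e-9)

    @pytest.mark.parametrize("theta", [0.0, 10.0, 15.33, 25.81, 26.5, 45.0, 70.0, 85.0])
    def test_lossless_energy_conservation_with_elastic_walls(self, lossless_stack, theta):
        sol = sc.solve_oblique(lossless_stack, F, theta)
        assert sol.power_transmission + sol.power_reflection == pytest.approx(1.0, abs=1e-9)

    def test_shear_branch_transmits_beyond_longitudinal_critical(self, lossless):
        # between the two glass critical angles (15.3, 25.8 deg) the sample
        # still receives pressure through the shear branch of the slide
        stack = chamber_stack(lossless)
        sol = sc.solve_oblique(stack, F, 20.0)
        assert sol.max_pressure_in_layer(2) > 0.05

    def test_first_layer_must_be_fluid(self, glass, water):
        with pytest.raises(sc.ValidationError):
            sc.solve_oblique(two_media(glass, water), F, 10.0)


class TestGapSweep:
    def test_amplitude_periodic_in_half_wavelength(self, lossless_stack, water):
        # the analytic period is exactly lam/2; residual error comes from
        # sampling the in-layer maximum on a finite z grid
        lam = water.c_long / F
        base = sc.sample_amplitude_vs_gap(lossless_stack, [0.2 * lam], F, n_z=2001)
        shifted = sc.sample_amplitude_vs_gap(lossless_stack,
                                             [0.2 * lam + lam / 2], F, n_z=2001)
        assert base["amplitude_ratio"][0] == pytest.approx(
            shifted["amplitude_ratio"][0], rel=1e-5)

    def test_glass_walls_more_gap_sensitive_than_polystyrene(self, lossless):
        lam = lossless["water"].c_long / F
        gaps = np.linspace(1e-6, lam / 2, 120)
        def excursion(wall):
            sw = sc.sample_amplitude_vs_gap(chamber_stack(lossless, slide=wall,
                                                          coverslip=wall), gaps, F)
            return sw["amplitude_ratio"].max() - sw["amplitude_ratio"].min()
        assert excursion("glass") > excursion("polystyrene")

    def test_homogeneous_medium_is_gap_independent(self, lossless):
        stack = chamber_stack(lossless, slide="water", coverslip="water",
                              backing="water")
        sw = sc.sample_amplitude_vs_gap(stack, np.linspace(5e-6, 500e-6, 7), F)
        assert sw["amplitude_ratio"].std() < 1e-12
        assert sw["amplitude_ratio"].iloc[0] == pytest.approx(1.0, abs=1e-12)

    def test_empty_gap_range_rejected(self, default_stack):
        with pytest.raises(sc.ValidationError):
            sc.sample_amplitude_vs_gap(default_stack, [], F)


class TestPowerLoss:
    def test_lossless_medium_loses_nothing(self, lossless):
        assert sc.power_loss_through(lossless["glass"], 0.01, F) == 0.0

    def test_default_glass_meets_five_percent_bound_at_10mm(self, glass):
        assert sc.power_loss_through(glass, 10e-3, F) <= 0.05

    def test_exponential_composition(self, glass):
        survive_d = 1.0 - sc.power_loss_through(glass, 3e-3, F)
        survive_2d = 1.0 - sc.power_loss_through(glass, 6e-3, F)
        assert survive_2d == pytest.approx(survive_d ** 2, rel=1e-12)

    def test_matches_attenuation_coefficient(self, glass):
        a = attenuation_at(glass, F)
        assert sc.power_loss_through(glass, 2e-3, F) == pytest.approx(
            1.0 - math.exp(-2 * a * 2e-3), rel=1e-12)


class TestBruteForce:
    def test_identical_media_everywhere_transmit_unchanged(self, water):
        stack = sc.LayerStack.from_sequence(
            [(water.with_(alpha0_db_per_cm=0.0), d) for d in
             (sc.HALF_SPACE, 1e-3, 15e-6, 1e-3, sc.HALF_SPACE)])
        sol = sc.brute_force_five_layer(stack, F)
        assert abs(sol.pressure_transmission) == pytest.approx(1.0, abs=1e-12)
        assert abs(sol.pressure_reflection) == pytest.approx(0.0, abs=1e-12)

    def test_rigid_backing_reflects_totally(self, lossless):
        rigid = sc.AcousticMedium(name="rigid", density=1e9, c_long=1e5)
        stack = chamber_stack(lossless)
        layers = list(stack.layers)
        layers[-1] = (rigid, sc.HALF_SPACE)
        sol = sc.brute_force_five_layer(sc.LayerStack.from_sequence(layers), F)
        assert abs(sol.pressure_reflection) == pytest.approx(1.0, abs=1e-4)

    def test_wrong_layer_count_rejected(self, water, glass):
        with pytest.raises(sc.ValidationError):
            sc.brute_force_five_layer(two_media(water, glass), F)


class TestRandomStacks:
    def test_deterministic_for_a_seed(self):
        assert sc.generate_random_stack(7, 5) == sc.generate_random_stack(7, 5)
        assert sc.generate_random_stack(7, 5) != sc.generate_random_stack(8, 5)

    def test_two_layers_are_two_half_spaces(self):
        stack = sc.generate_random_stack(1, 2)
        assert len(stack.layers) == 2
        assert all(math.isinf(d) for d in stack.thicknesses)

    def test_too_few_layers_rejected(self):
        with pytest.raises(sc.ValidationError):
            sc.generate_random_stack(1, 1)
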