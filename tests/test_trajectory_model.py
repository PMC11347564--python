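import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oamtwist.beam_optics import BeamParameters
from oamtwist.trajectory_model import (
    Layer,
    MediumStack,
    TrajectoryStart,
    make_trajectory,
    phase_retardation,
    poynting_direction,
    predict_twist_series,
    refract_through_stack,
    sample_starts,
    stack_retardation,
    trajectory_length,
    trajectory_point,
)


class TestTrajectoryPoint:
    def test_start_point(self):
        start = TrajectoryStart(1.3, 0.7)
        assert trajectory_point(start, 0.0, 5) == (1.3, 0.7)

    def test_radius_at_half(self):
        start = TrajectoryStart(0.9, 0.0)
        r, _ = trajectory_point(start, 0.5, 3)
        assert r == pytest.approx(0.9 * math.sqrt(2))

    def test_asymptotic_azimuth(self):
        start = TrajectoryStart(1.1, 0.2)
        _, phi = trajectory_point(start, 1e9, 4)
        assert phi - 0.2 == pytest.approx(4 * math.pi / (4 * 1.1**2), rel=1e-8)

    def test_singular_axis_rejected(self):
        with pytest.raises(ValueError):
            trajectory_point(TrajectoryStart(0.0, 0.0), 1.0, 3)


class TestTrajectoryLength:
    def test_axial_ray_is_straight(self):
        start = TrajectoryStart(1e-9, 0.0)
        assert trajectory_length(start, 2.5, 0) == pytest.approx(2.5, rel=1e-9)

    def test_against_polyline_oracle(self):
        # brute-force chord sum over 10^6 segments of the closed-form spiral
        start = TrajectoryStart(1.58, 0.3)
        ell, zeta_s = 5, 1.0
        zs = np.linspace(0.0, zeta_s, 1_000_001)
        r = start.r0 * np.sqrt(1 + 4 * zs**2)
        ph = ell / (2 * start.r0**2) * np.arctan(2 * zs) + start.phi0
        x, y = r * np.cos(ph), r * np.sin(ph)
        oracle = float(np.sum(np.hypot(np.diff(x), np.diff(y))))
        ours = trajectory_length(start, zeta_s, ell, include_longitudinal=False)
        assert ours == pytest.approx(oracle, rel=1e-6)

    def test_monotone_in_zeta(self):
        start = TrajectoryStart(1.2, 0.0)
        l1 = trajectory_length(start, 1.0, 3)
        l2 = trajectory_length(start, 2.0, 3)
        assert l2 > l1

    def test_longitudinal_term_adds_path(self):
        start = TrajectoryStart(1.2, 0.0)
        transverse = trajectory_length(start, 1.0, 3, include_longitudinal=False)
        full = trajectory_length(start, 1.0, 3, include_longitudinal=True)
        assert full > transverse  # radical grows with the +1
        assert full > 1.0  # never shorter than the straight axial path

    def test_physical_scaling_reduces_to_thickness(self):
        # with the transverse terms scaled by 1/(k*w0) the 3-D arc length in
        # zeta units approaches zeta_s for a paraxial beam
        params = BeamParameters(640e-9, 1e-3, ell=5)
        start = TrajectoryStart(math.sqrt(2.5), 0.0)
        scale = 1.0 / (params.k * params.waist_w0)
        val = trajectory_length(start, 1e-3, 5, transverse_scale=scale)
        assert val == pytest.approx(1e-3, rel=1e-6)
        assert val >= 1e-3


class TestPoyntingDirection:
    def test_radial_component_vanishes_at_waist(self, beam_l3):
        p_rho, _, _ = poynting_direction(beam_l3, 1e-3, 0.3, 0.0)
        assert p_rho == 0.0

    def test_azimuthal_ratio(self, beam_l3):
        rho = 8e-4
        _, p_phi, p_z = poynting_direction(beam_l3, rho, 1.0, 0.4 * beam_l3.rayleigh_range)
        assert p_phi / p_z == pytest.approx(beam_l3.ell / (beam_l3.k * rho), rel=1e-12)

    def test_no_azimuthal_flow_without_charge(self):
        params = BeamParameters(640e-9, 1e-3, ell=0)
        _, p_phi, _ = poynting_direction(params, 5e-4, 0.0, 1.0)
        assert p_phi == 0.0

    def test_streamline_matches_closed_form(self, beam_l3):
        # integrate the direction field dr/dz = p_rho/p_z, r*dphi/dz = p_phi/p_z
        # and compare r(zeta) with the analytic spiral
        from scipy.integrate import solve_ivp

        w0, k = beam_l3.waist_w0, beam_l3.k
        r0 = math.sqrt(1.5)  # doughnut radius in w0 units

        def rhs(z, y):
            rho = y[0]
            p_rho, p_phi, p_z = poynting_direction(beam_l3, rho, 0.0, z)
            return [p_rho / p_z, p_phi / (p_z * rho)]

        zeta_end = 1.0
        z_end = zeta_end * k * w0**2
        sol = solve_ivp(rhs, (0, z_end), [r0 * w0, 0.0], rtol=1e-10, atol=1e-14)
        r_numeric = sol.y[0, -1] / w0
        r_analytic, _ = trajectory_point(TrajectoryStart(r0, 0.0), zeta_end, beam_l3.ell)
        assert r_numeric == pytest.approx(r_analytic, rel=0.01)


class TestPhaseRetardation:
    def test_one_wavelength(self):
        assert phase_retardation(640e-9, 1.0, 640e-9) == pytest.approx(2 * math.pi)

    def test_zero_path(self):
        assert phase_retardation(0.0, 1.5, 640e-9) == 0.0

    def test_negative_path_rejected(self):
        with pytest.raises(ValueError):
            phase_retardation(-1e-6, 1.0, 640e-9)

    def test_cuvette_retardation_difference(self):
        # direct evaluation of the formula difference over the 3.6 mm interior
        d, lam = 3.6e-3, 640e-9
        diff = phase_retardation(d, 1.3330 + 3.69e-4, lam) - phase_retardation(d, 1.3330, lam)
        expected = 2 * math.pi * 3.69e-4 * d / lam
        assert diff == pytest.approx(expected, rel=1e-12)


class TestMediumStack:
    def test_cuvette_geometry(self):
        stack = MediumStack.cuvette()
        assert stack.total_thickness == pytest.approx(5.6e-3)
        assert len(stack.layers) == 3

    def test_invalid_layers_rejected(self):
        with pytest.raises(ValueError):
            Layer(d=-1e-3, n=1.5)
        with pytest.raises(ValueError):
            Layer(d=1e-3, n=0.9)
        with pytest.raises(ValueError):
            Layer(d=1e-3, n=1.5, g=1.0)


class TestRefraction:
    def test_axial_ray_unchanged(self, beam_l5):
        traj = make_trajectory(TrajectoryStart(1e-9, 0.0), 0, np.array([0.0, 1e-3]), beam_l5)
        out = refract_through_stack(traj, MediumStack.cuvette(), beam_l5)
        for rec, layer in zip(out.layer_paths, MediumStack.cuvette().layers):
            assert rec.delta_L == pytest.approx(layer.d, rel=1e-12)

    def test_snell_45_degrees(self):
        # asin(sin 45 / 1.5) = 28.1255 degrees, by direct Snell evaluation
        expected = math.degrees(math.asin(math.sin(math.radians(45.0)) / 1.5))
        assert expected == pytest.approx(28.1255, abs=1e-3)
        from oamtwist.trajectory_model import _layer_pathlengths

        stack = MediumStack((Layer(1e-3, 1.5),))
        sines, paths = _layer_pathlengths(np.array([math.sin(math.radians(45.0))]), stack)
        assert math.degrees(math.asin(sines[0])) == pytest.approx(expected, rel=1e-12)
        assert paths[0][0] == pytest.approx(1e-3 / math.cos(math.radians(expected)), rel=1e-12)

    def test_refracted_path_never_shorter_than_thickness(self, beam_l5):
        traj = make_trajectory(
            TrajectoryStart(math.sqrt(2.5), 0.4), 5, np.array([0.0, 1e-3]), beam_l5
        )
        out = refract_through_stack(traj, MediumStack.cuvette(), beam_l5)
        assert out.refracted
        for rec, layer in zip(out.layer_paths, MediumStack.cuvette().layers):
            assert rec.delta_L >= layer.d
            assert rec.delta_psi == pytest.approx(
                2 * math.pi * layer.n * rec.delta_L / beam_l5.wavelength, rel=1e-12
            )

    def test_total_internal_reflection_flagged(self, beam_l5):
        from oamtwist.trajectory_model import _layer_pathlengths

        stack = MediumStack((Layer(1e-3, 1.0),), n_ambient=2.0)
        with pytest.raises(ValueError, match="total internal reflection"):
            _layer_pathlengths(np.array([0.9]), stack)


class TestSampling:
    def test_starts_follow_annulus(self, beam_l5):
        rng = np.random.default_rng(0)
        r0, phi0 = sample_starts(beam_l5, 200_000, rng)
        # peak of the 2-D radial density of |LG_0^5|^2 is at sqrt(|l|/2 + 1/2)-ish;
        # check the doughnut radius is well inside the central mass
        assert abs(np.median(r0) - math.sqrt(2.5)) < 0.35
        assert phi0.min() >= 0 and phi0.max() < 2 * math.pi

    def test_deterministic_given_seed(self, beam_l5):
        a = sample_starts(beam_l5, 1000, np.random.default_rng(7))
        b = sample_starts(beam_l5, 1000, np.random.default_rng(7))
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])


class TestPredictTwist:
    def test_zero_delta_n_gives_zero_twist(self, beam_l5):
        pred = predict_twist_series(
            beam_l5, MediumStack.cuvette(), np.zeros(3), n_traj=30_000, seed=0
        )
        assert np.allclose(pred.theta_rad, 0.0, atol=1e-3)

    def test_monotone_and_linear(self, beam_l5):
        dn = np.linspace(0.0, 2e-5, 9)
        pred = predict_twist_series(beam_l5, MediumStack.cuvette(), dn, n_traj=60_000, seed=1)
        assert np.all(np.diff(pred.theta_rad) > 0)
        # linearity of the forward map within 2% (checked on the smooth guide)
        slope = pred.theta_guide_rad[-1] / dn[-1]
        fit = slope * dn
        assert np.max(np.abs(pred.theta_guide_rad - fit)) <= 0.02 * abs(pred.theta_guide_rad[-1])

    def test_sensitivity_floor_dn_1e_minus_6(self, beam_l5):
        dn = np.array([0.0, 1e-6])
        pred = predict_twist_series(beam_l5, MediumStack.cuvette(), dn, n_traj=60_000, seed=2)
        # a 1e-6 index change over the 3.6 mm cell must yield a resolvable twist
        assert pred.theta_guide_rad[1] > 1e-3
        assert pred.theta_rad[1] > 1e-3

    def test_phase_twist_consistent_across_charges(self, beam_l3, beam_l5):
        # the OAM phase twist ell*Theta follows one common trend for both beams
        # (the petal rotation itself scales as 1/ell); agreement within 10%
        dn = np.linspace(0.0, 2e-5, 5)
        p3 = predict_twist_series(beam_l3, MediumStack.cuvette(), dn, n_traj=60_000, seed=3)
        p5 = predict_twist_series(beam_l5, MediumStack.cuvette(), dn, n_traj=60_000, seed=3)
        psi3 = 3 * p3.theta_rad[-1]
        psi5 = 5 * p5.theta_rad[-1]
        assert psi3 == pytest.approx(psi5, rel=0.10)

    def test_small_ensemble_flagged(self, beam_l5):
        with pytest.warns(RuntimeWarning):
            pred = predict_twist_series(
                beam_l5, MediumStack.cuvette(), np.array([0.0, 1e-5]), n_traj=5_000, seed=0
            )
        assert pred.flagged

    def test_tiny_ensemble_rejected(self, beam_l5):
        with pytest.raises(ValueError):
            predict_twist_series(beam_l5, MediumStack.cuvette(), np.array([0.0]), n_traj=10)


class TestStackRetardation:
    def test_matches_plain_formula_for_axial_bundle(self):
        params = BeamParameters(640e-9, 1e-3, ell=0)
        stack = MediumStack.cuvette()
        psi = stack_retardation(np.array([1e-6]), params, stack)
        plain = sum(
            2 * math.pi * la.n * la.d / params.wavelength for la in stack.layers
        )
        assert psi[0] == pytest.approx(plain, rel=1e-9)

    @settings(max_examples=20, deadline=None)
    @given(r0=st.floats(0.3, 3.0))
    def test_never_below_straight_through(self, r0, beam_l5):
        stack = MediumStack.cuvette()
        psi = stack_retardation(np.array([r0]), beam_l5, stack)
        plain = sum(2 * math.pi * la.n * la.d / beam_l5.wavelength for la in stack.layers)
        assert psi[0] >= plain * (1 - 1e-12)
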