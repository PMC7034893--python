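"""Ventricle constitutive laws: geometry, passive energy, active ODEs."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad, solve_ivp

from fontan0d.ventricle import (
    ActivationTiming,
    ActiveLawParams,
    ActiveState,
    PassiveLawParams,
    VentricleGeometry,
    activation_value,
    active_rhs,
    cavity_volume,
    extension_from_volume,
    passive_energy,
    passive_tension,
    reference_geometry,
    starling_factor,
    ventricular_pressure,
    wall_radii,
)

LAM = st.floats(0.9, 1.4)


class TestGeometry:
    def test_cohort_typical_shell(self):
        # EDV 76 mL, wall mass 38 g, 50% reference rule, rho 1050 kg/m3
        g = reference_geometry(76e-6, 0.038, 0.5, 1050.0)
        assert g.V0 == pytest.approx(38e-6)
        assert g.Vw == pytest.approx(36.19e-6, rel=1e-3)
        assert g.R0 == pytest.approx(20.85e-3, rel=1e-3)
        assert g.d0 == pytest.approx(5.21e-3, rel=1e-2)
        # the sphere-shell identities hold exactly
        assert g.V0 == pytest.approx(4 / 3 * math.pi * g.R0**3, rel=1e-12)
        assert g.Vw == pytest.approx(
            4 / 3 * math.pi * ((g.R0 + g.d0) ** 3 - g.R0**3), rel=1e-12
        )

    def test_thin_shell_limit(self):
        g = reference_geometry(76e-6, 1e-6, 0.5, 1050.0)
        assert g.d0 < 1e-4  # vanishing mass -> vanishing wall thickness

    @pytest.mark.parametrize(
        "kw,field",
        [
            (dict(edv=-1e-6, myo_mass=0.038), "edv"),
            (dict(edv=76e-6, myo_mass=0.0), "myo_mass"),
            (dict(edv=76e-6, myo_mass=0.038, v0_ratio=1.5), "v0_ratio"),
        ],
    )
    def test_rejects_bad_inputs_naming_field(self, kw, field):
        with pytest.raises(ValueError, match=field):
            reference_geometry(**kw)

    def test_inconsistent_shell_rejected(self):
        with pytest.raises(ValueError, match="V0 inconsistent"):
            VentricleGeometry(V0=1e-6, Vw=1e-6, R0=0.01, d0=0.001)

    def test_cavity_volume_roundtrip(self):
        g = reference_geometry(76e-6, 0.038)
        assert cavity_volume(g, 1.0) == pytest.approx(g.V0, rel=1e-15)
        lam = (76e-6 / 38e-6) ** (1 / 3)
        assert cavity_volume(g, lam) == pytest.approx(76e-6, rel=1e-12)
        for v in (20e-6, 38e-6, 90e-6):
            assert cavity_volume(g, extension_from_volume(g, v)) == pytest.approx(
                v, rel=1e-12
            )

    def test_wall_volume_conserved_under_deformation(self):
        g = reference_geometry(76e-6, 0.038)
        for lam in (0.9, 1.0, 1.2, 1.35):
            r_in, r_out, _, _ = wall_radii(g, lam)
            vw = 4 / 3 * math.pi * (r_out**3 - r_in**3)
            assert vw == pytest.approx(g.Vw, rel=1e-12)


class TestPassiveLaw:
    def test_reference_energy(self):
        p = PassiveLawParams(C0=100.0, C1=10.0, C2=100.0, C3=10.0)
        assert passive_energy(p, 1.0) == pytest.approx(200.0, rel=1e-12)

    def test_energy_against_explicit_invariants(self):
        # independent evaluation: J1 = 2*1.44 + 1.2**-4, J4 = 1.44
        p = PassiveLawParams(C0=100.0, C1=10.0, C2=100.0, C3=10.0)
        j1 = 2 * 1.44 + 1.2**-4
        expected = 100.0 * math.exp(10.0 * (j1 - 3.0) ** 2) + 100.0 * math.exp(
            10.0 * 0.44**2
        )
        assert passive_energy(p, 1.2) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(1064.558, rel=1e-4)  # frozen check

    def test_energy_minimum_at_reference(self):
        p = PassiveLawParams()
        w1 = passive_energy(p, 1.0)
        assert passive_energy(p, 1.2) > w1
        assert passive_energy(p, 0.9) > w1

    def test_tension_zero_at_reference(self):
        assert abs(passive_tension(PassiveLawParams(), 1.0)) < 1e-9

    @settings(deadline=None, max_examples=40)
    @given(lam=LAM)
    def test_tension_matches_finite_difference_of_energy(self, lam):
        # sigma_p = (lam/2) dWe/dlam under the declared stress convention
        p = PassiveLawParams()
        h = 1e-6
        dwe = (passive_energy(p, lam + h) - passive_energy(p, lam - h)) / (2 * h)
        assert passive_tension(p, lam) == pytest.approx(
            0.5 * lam * dwe, rel=1e-6, abs=1e-4
        )

    def test_tension_monotone_on_inflation(self):
        p = PassiveLawParams()
        grid = np.linspace(1.0, 1.4, 50)
        vals = [passive_tension(p, x) for x in grid]
        assert np.all(np.diff(vals) > 0)

    def test_stiffness_scale_is_linear(self):
        p1 = PassiveLawParams(stiffness_scale=1.0)
        p2 = PassiveLawParams(stiffness_scale=2.0)
        for lam in (1.05, 1.2, 1.3):
            assert passive_tension(p2, lam) == pytest.approx(
                2.0 * passive_tension(p1, lam), rel=1e-12
            )


class TestStarling:
    def test_optimum_and_support(self):
        p = ActiveLawParams()
        assert starling_factor(p, p.starling_opt) == 1.0
        assert starling_factor(p, p.starling_opt + p.starling_width) == 0.0
        assert starling_factor(p, p.starling_opt - p.starling_width) == 0.0

    @settings(deadline=None, max_examples=50)
    @given(e=st.floats(0.5, 2.0))
    def test_bounded(self, e):
        assert 0.0 <= starling_factor(ActiveLawParams(), e) <= 1.0


class TestActivation:
    TIMING = ActivationTiming(T0=0.857, PQ=0.12, QRS=0.08, ST=0.30)

    def test_plateau_reaches_maximum_rate(self):
        p = ActiveLawParams()
        t = self.TIMING.av_delay + self.TIMING.QRS + 0.5 * self.TIMING.ST
        assert activation_value(t, self.TIMING, p) == 35.0

    def test_zero_before_av_delay_and_in_late_diastole(self):
        p = ActiveLawParams()
        assert activation_value(0.05, self.TIMING, p) == 0.0
        assert activation_value(self.TIMING.T0 - 1e-4, self.TIMING, p) == 0.0

    def test_reduced_modulo_cycle(self):
        p = ActiveLawParams()
        t = self.TIMING.av_delay + 0.5 * self.TIMING.QRS
        assert activation_value(t + 3 * self.TIMING.T0, self.TIMING, p) == pytest.approx(
            activation_value(t, self.TIMING, p)
        )

    def test_positive_part_integral_closed_form(self):
        # rise triangle + plateau + positive part of the fall ramp
        p = ActiveLawParams()
        tm = self.TIMING
        pos, _ = quad(
            lambda t: max(activation_value(t, tm, p), 0.0), 0.0, tm.T0, limit=400
        )
        expected = p.u_max * (
            tm.QRS / 2 + tm.ST + 0.5 * tm.QRS * p.u_max / (p.u_max + p.u_relax)
        )
        assert pos == pytest.approx(expected, rel=1e-3)


class TestActiveRHS:
    def test_quiescence(self):
        s = ActiveState(kc=0.0, tau_c=0.0, e_fib=1.0)
        assert active_rhs(s, 0.0, 0.0, ActiveLawParams()) == (0.0, 0.0)

    def test_fixed_point_is_starling_scaled_contractility(self):
        # under sustained activation at frozen extension, tau_c -> n0*sigma0;
        # at the optimal extension this is sigma0 itself (e.g. 75 kPa)
        p = ActiveLawParams(sigma0=75e3)
        s = ActiveState(kc=2 * 75e3, tau_c=75e3, e_fib=p.starling_opt)
        dkc, dtau = active_rhs(s, 35.0, 0.0, p)
        assert dkc == pytest.approx(0.0, abs=1e-9)
        assert dtau == pytest.approx(0.0, abs=1e-9)

    def test_monotone_approach_never_overshoots(self):
        p = ActiveLawParams(sigma0=60e3)
        e = p.starling_opt
        n0 = 1.0
        tau, kc = 0.0, 0.0
        dt = 1e-4
        prev = -1.0
        for _ in range(3000):
            dkc, dtau = active_rhs(ActiveState(kc, tau, e), 35.0, 0.0, p)
            kc += dt * dkc
            tau += dt * dtau
            assert tau >= prev
            assert tau <= n0 * p.sigma0 * (1 + 1e-12)
            prev = tau
        assert tau == pytest.approx(n0 * p.sigma0, rel=1e-3)

    def test_euler_matches_adaptive_integrator_over_burst(self):
        # one activation burst with a prescribed extension history
        p = ActiveLawParams(sigma0=60e3)
        tm = ActivationTiming(T0=0.857)

        def efib(t):
            return 1.2 - 0.1 * math.sin(2 * math.pi * t / tm.T0)

        def defib(t):
            return -0.1 * 2 * math.pi / tm.T0 * math.cos(2 * math.pi * t / tm.T0)

        def rhs(t, y):
            s = ActiveState(max(y[0], 0.0), max(y[1], 0.0), efib(t))
            u = activation_value(t, tm, p)
            return active_rhs(s, u, defib(t), p)

        sol = solve_ivp(rhs, (0, tm.T0), [0.0, 0.0], rtol=1e-10, atol=1e-6)
        kc, tau = 0.0, 0.0
        dt = 1e-5
        for k in range(int(tm.T0 / dt)):
            d = rhs(k * dt, (kc, tau))
            kc += dt * d[0]
            tau += dt * d[1]
        assert kc == pytest.approx(sol.y[0, -1], rel=1e-3, abs=1.0)
        assert tau == pytest.approx(sol.y[1, -1], rel=1e-3, abs=1.0)


class TestVentricularPressure:
    GEOM = reference_geometry(76e-6, 0.038)
    PASSIVE = PassiveLawParams(stiffness_scale=1.1)

    def test_zero_at_reference_without_active_stress(self):
        s = ActiveState(0.0, 0.0, 1.0)
        assert ventricular_pressure(self.GEOM, self.PASSIVE, s, 1.0) == pytest.approx(
            0.0, abs=1e-9
        )

    def test_linear_in_active_stress(self):
        lam = 1.1
        p1 = ventricular_pressure(
            self.GEOM, self.PASSIVE, ActiveState(0, 10e3, lam), lam
        )
        p2 = ventricular_pressure(
            self.GEOM, self.PASSIVE, ActiveState(0, 20e3, lam), lam
        )
        p0 = ventricular_pressure(self.GEOM, self.PASSIVE, ActiveState(0, 0, lam), lam)
        assert p2 - p0 == pytest.approx(2.0 * (p1 - p0), rel=1e-12)

    def test_passive_inflation_curve_monotone(self):
        s = ActiveState(0.0, 0.0, 1.0)
        grid = np.linspace(1.0, 1.35, 40)
        pv = [ventricular_pressure(self.GEOM, self.PASSIVE, s, x) for x in grid]
        assert np.all(np.diff(pv) > 0)

    def test_similarity_invariance(self):
        # scaling all lengths leaves the pressure-extension relation unchanged
        big = reference_geometry(8 * 76e-6, 8 * 0.038)
        s = ActiveState(0.0, 15e3, 1.15)
        for lam in (1.0, 1.1, 1.25):
            assert ventricular_pressure(big, self.PASSIVE, s, lam) == pytest.approx(
                ventricular_pressure(self.GEOM, self.PASSIVE, s, lam), rel=1e-9
            )

    def test_doubling_stiffness_doubles_passive_pressure(self):
        s = ActiveState(0.0, 0.0, 1.0)
        p2 = PassiveLawParams(stiffness_scale=2.2)
        for lam in (1.05, 1.2, 1.3):
            assert ventricular_pressure(self.GEOM, p2, s, lam) == pytest.approx(
                2.0 * ventricular_pressure(self.GEOM, self.PASSIVE, s, lam), rel=1e-12
            )
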