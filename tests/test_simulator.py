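"""Closed-loop integration: valves, assembled dynamics, beat summaries."""

import math
import warnings
from dataclasses import replace

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from conftest import MMHG, make_default_model
from fontan0d.simulator import (
    BeatTrace,
    ValveParams,
    assemble_rhs,
    beat_summary,
    run_to_periodic,
    valve_flows,
)
from fontan0d.ventricle import ActiveState, ventricular_pressure


class TestValves:
    VP = ValveParams()

    def test_zero_gradient_zero_flow(self):
        assert valve_flows(5000.0, 5000.0, 5000.0, self.VP) == (0.0, 0.0)

    def test_linear_forward_regime(self):
        q_out, q_in = valve_flows(
            5000.0 + self.VP.K_ar * 1e-5, 5000.0, 0.0, self.VP
        )
        assert q_out == pytest.approx(1e-5, rel=1e-12)
        assert q_in == 0.0

    def test_reverse_gradients_give_no_flow(self):
        q_out, q_in = valve_flows(2000.0, 9000.0, 1000.0, self.VP)
        assert q_out == 0.0 and q_in == 0.0

    def test_smoothed_diode_is_continuous_and_small_below_eps(self):
        vp = ValveParams(eps=10.0)
        q, _ = valve_flows(5000.0 + 5.0, 5000.0, 0.0, vp)
        assert 0.0 < q < 10.0 / vp.K_ar


class TestAssembledDynamics:
    def test_quiescent_equilibrium(self):
        model = make_default_model()
        ven = replace(model.venous, Patr_amp=0.0)
        model = replace(model, venous=ven)
        msfp = model.venous.msfp(model.wk)
        # inflate the relaxed ventricle to the filling pressure
        from scipy.optimize import brentq

        lam = brentq(
            lambda x: ventricular_pressure(
                model.geom, model.passive, ActiveState(0, 0, 1.0), x
            )
            - msfp,
            1.0 + 1e-9,
            1.8,
        )
        state = (lam, 0.0, 0.0, msfp, msfp)
        # late diastole: no activation, no kick
        d = assemble_rhs(state, 0.98 * model.timing.T0, model, msfp)
        assert np.allclose(d, 0.0, atol=1e-6)

    def test_integrator_matches_assembled_rhs_via_scipy(self):
        # one beat at frozen venous baseline: the fast inlined stepper must
        # agree with an adaptive integration of the composed right-hand side
        model = make_default_model()
        pve = 4.0 * MMHG
        # integrate scipy from the stepper's periodic state over one cycle
        # and require a near-closed orbit
        res = run_to_periodic(
            model, mode="imposed", pve_const=pve, edv_init=76e-6, max_beats=30,
            min_beats=3, tol=1e-3,
        )
        y0 = list(res.state)
        t0 = 0.0
        sol = solve_ivp(
            lambda t, y: assemble_rhs(tuple(y), t % model.timing.T0, model, pve),
            (t0, model.timing.T0),
            y0,
            rtol=1e-8,
            atol=[1e-8, 1e-3, 1e-3, 1e-3, 1e-3],
            max_step=1e-3,
        )
        end = sol.y[:, -1]
        # periodic orbit: the adaptive integration of the composed rhs lands
        # back near the fixed-step solution (valve-corner crossings limit
        # the agreement to the sub-percent level)
        assert end[0] == pytest.approx(y0[0], rel=1e-2)
        assert end[3] == pytest.approx(y0[3], rel=1e-2)
        assert end[4] == pytest.approx(y0[4], rel=1e-2)

    def test_forced_beat_has_ejection_and_filling(self, rest_result):
        tr = rest_result.trace
        assert tr.Qout.max() > 1e-4  # m3/s, > 100 mL/s peak ejection
        assert tr.Qin.max() > 1e-5
        # volume falls while ejecting
        i = int(np.argmax(tr.Qout))
        assert tr.V[i + 5] < tr.V[i - 5]

    def test_per_beat_volume_conservation(self, rest_result):
        tr = rest_result.trace
        filled = np.trapezoid(tr.Qin, tr.t)
        ejected = np.trapezoid(tr.Qout, tr.t)
        sv = (tr.V.max() - tr.V.min())
        assert abs(filled - ejected) <= 0.005 * sv

    def test_pv_loop_counterclockwise(self, rest_result):
        tr = rest_result.trace
        area = -np.trapezoid(tr.Pv, tr.V)  # ∮ P dV over the closed loop
        assert area > 0  # positive stroke work

    def test_nan_guard_aborts_with_context(self):
        model = make_default_model()
        bad = replace(model, valves=ValveParams(K_ar=1e-12, K_av=1e-12))
        with pytest.raises(RuntimeError, match="beat"):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                run_to_periodic(bad, max_beats=10)


class TestClosedLoopBehavior:
    def test_equilibrium_output_matches_venous_return(self, rest_result):
        tr = rest_result.trace
        q_mean = np.trapezoid(tr.Qout, tr.t) / (tr.t[-1] - tr.t[0])
        assert q_mean == pytest.approx(rest_result.Qve_bar, rel=0.01)

    def test_inotropy_raises_stroke_volume(self):
        base = make_default_model()
        up = replace(base, active=replace(base.active, sigma0=base.active.sigma0 * 1.1))
        kw = dict(mode="imposed", pve_const=5 * MMHG, edv_init=76e-6, max_beats=20)
        sv0 = run_to_periodic(base, **kw).summary.SV
        sv1 = run_to_periodic(up, **kw).summary.SV
        assert sv1 > sv0

    def test_afterload_lowers_output_and_raises_pressure(self, rest_result):
        base = make_default_model()
        stiffer = replace(base, wk=replace(base.wk, Rd=base.wk.Rd * 1.1))
        res = run_to_periodic(stiffer, max_beats=60)
        assert res.summary.CO < rest_result.summary.CO
        assert res.summary.peak_Par > rest_result.summary.peak_Par

    def test_no_pump_settles_at_msfp(self):
        model = make_default_model()
        model = replace(
            model,
            active=replace(model.active, sigma0=1.0),
            venous=replace(model.venous, Patr_amp=0.0),
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = run_to_periodic(model, max_beats=30, edv_init=50e-6)
        msfp = model.venous.msfp(model.wk)
        assert res.summary.CO < 0.05
        assert res.Pve_bar == pytest.approx(msfp, rel=0.02)

    def test_dt_refinement_stable(self, rest_result):
        fine = run_to_periodic(make_default_model(), max_beats=60, dt=2.5e-4)
        for field in ("EDV", "ESV", "CO", "peak_Pv", "peak_Par", "EDP"):
            a = getattr(rest_result.summary, field)
            b = getattr(fine.summary, field)
            assert b == pytest.approx(a, rel=2e-3), field

    def test_stress_raises_rate_and_output(self, rest_result):
        model = make_default_model().at_stress(
            dob_wk=1.40, contractility_factor=1.8, veff_factor=1.45,
            hr_stress=120.0, st_stress=0.15,
        )
        res = run_to_periodic(model, edv_init=rest_result.summary.EDV * 1e-6,
                              max_beats=60)
        assert res.converged
        assert res.summary.CO > rest_result.summary.CO
        assert res.summary.peak_Pv > rest_result.summary.peak_Pv


class TestBeatSummary:
    @staticmethod
    def _trace(t, pv, par, v, qout=None, qin=None):
        n = len(t)
        z = np.zeros(n)
        return BeatTrace(
            t=t, Pv=pv, Par=par, Pd=z.copy(), V=v,
            Qout=z.copy() if qout is None else qout,
            Qin=z.copy() if qin is None else qin,
            Ppreload=z.copy(),
        )

    def test_sinusoidal_volume_gives_double_amplitude_sv(self):
        t = np.linspace(0, 1, 1001)
        amp = 10e-6
        v = 60e-6 + amp * np.sin(2 * np.pi * t)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            s = beat_summary(self._trace(t, np.ones_like(t), np.ones_like(t), v),
                             hr=60.0)
        assert s.SV == pytest.approx(2 * amp * 1e6, rel=1e-4)

    def test_ejection_fraction_definition(self):
        # EDV 76, ESV 35 -> EF ~ 54%
        t = np.linspace(0, 1, 101)
        v = np.where(t < 0.5, 76e-6, 35e-6)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            s = beat_summary(self._trace(t, np.ones_like(t), np.ones_like(t), v),
                             hr=70.0)
        assert s.EF == pytest.approx(53.9, abs=0.1)
        assert s.SV == pytest.approx(41.0, abs=1e-6)

    def test_max_dpdt_on_ramp(self):
        t = np.linspace(0, 1, 1001)
        slope_pa = 800.0 * MMHG  # 800 mmHg/s
        pv = slope_pa * t
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            s = beat_summary(
                self._trace(t, pv, np.ones_like(t), 50e-6 + 1e-6 * t), hr=60.0
            )
        assert s.max_dpdt == pytest.approx(800.0, rel=1e-6)

    def test_notch_is_first_local_minimum_after_peak(self):
        t = np.linspace(0, 1, 1001)
        base = np.interp(
            t, [0, 0.1, 0.35, 0.45, 0.55, 0.65, 1.0], [45, 50, 90, 71, 70, 65, 52]
        )
        par = (base - 8 * np.exp(-((t - 0.5) / 0.02) ** 2)) * MMHG
        qout = np.where(t < 0.45, 1e-4, 0.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            s = beat_summary(
                self._trace(t, par * 0.9, par, 50e-6 + 1e-6 * np.sin(np.pi * t),
                            qout=qout),
                hr=60.0,
            )
        expected = float(par[470:530].min()) / MMHG  # ~62.5 mmHg at the dip
        assert s.notch_height == pytest.approx(expected, rel=0.01)

    def test_simulated_beat_notch_below_peak(self, rest_result):
        s = rest_result.summary
        assert s.notch_height < s.peak_Par
        assert s.EDP < s.peak_Pv
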