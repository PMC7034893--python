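"""Six-step personalization: per-stage twins and the full protocol."""

import math
import warnings
from dataclasses import replace

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from conftest import MMHG, make_default_model
from fontan0d.calibration import (
    CalibrationConfig,
    diastolic_decay_tau,
    fit_contractility,
    fit_passive,
    fit_venous,
    fit_windkessel,
    run_full_calibration,
    simulate_windkessel_periodic,
    targets_from_record,
)
from fontan0d.circulation import WindkesselParams
from fontan0d.simulator import run_to_periodic
from fontan0d.synthetic import replace_traces
from fontan0d.ventricle import PassiveLawParams, reference_geometry
from fontan0d.xmr import PatientRecord


def _pulse_flow(t0=0.857, dt=1e-3, sv=41e-6, t_ej=0.3):
    """One cycle of half-sine ejection flow with the given stroke volume."""
    t = np.arange(0, t0 + dt / 2, dt)
    q = np.where(t < t_ej, np.sin(np.pi * np.minimum(t, t_ej) / t_ej), 0.0)
    q *= sv / np.trapezoid(q, t)
    return t, q


class TestWindkesselForward:
    WK = WindkesselParams.with_proximal_rc(Rp=0.19e8, Rd=1.25e8, Cd=2.00e-8)

    def test_periodic_propagator_matches_scipy(self):
        t, q = _pulse_flow()
        pve = 546.0
        par = simulate_windkessel_periodic(self.WK, q, 1e-3, pve)

        def rhs(tt, y):
            qq = np.interp(tt % 0.857, t, q)
            return [
                (qq - (y[0] - y[1]) / self.WK.Rp) / self.WK.Cp,
                ((pve - y[1]) / self.WK.Rd - (y[1] - y[0]) / self.WK.Rp) / self.WK.Cd,
            ]

        # integrate transients away with an independent adaptive solver
        sol = solve_ivp(rhs, (0, 12 * 0.857), [par[0], par[0]], rtol=1e-9,
                        atol=1e-6, max_step=1e-3, dense_output=True)
        last = sol.sol(12 * 0.857 - 0.857 + t)[0]
        assert np.max(np.abs(last - par)) / np.max(par) < 2e-3

    def test_mono_exponential_decay_constant_recovered_exactly(self):
        tau_true = 2.5
        t = np.linspace(0, 0.857, 858)
        pve = 546.0
        p = pve + 4000.0 * np.exp(-t / tau_true)
        q = np.where(t < 0.25, 1.0, 0.0)  # ejection marker only
        assert diastolic_decay_tau(t, p, q, pve) == pytest.approx(tau_true, rel=1e-9)

    def test_decay_requires_decaying_segment(self):
        t = np.linspace(0, 0.857, 858)
        q = np.where(t < 0.25, 1.0, 0.0)
        with pytest.raises(ValueError, match="decay"):
            diastolic_decay_tau(t, 546.0 + 100.0 * t, q, 546.0)


class TestWindkesselFit:
    def test_twin_recovery_within_two_percent(self):
        wk = WindkesselParams.with_proximal_rc(Rp=0.19e8, Rd=1.25e8, Cd=2.00e-8)
        t, q = _pulse_flow()
        pve = 546.0
        par = simulate_windkessel_periodic(wk, q, 1e-3, pve)
        fit = fit_windkessel(q, par, 1e-3, pve)
        assert fit.Rp == pytest.approx(wk.Rp, rel=0.02)
        assert fit.Rd == pytest.approx(wk.Rd, rel=0.02)
        assert fit.Cd == pytest.approx(wk.Cd, rel=0.02)
        assert fit.Rp * fit.Cp == pytest.approx(0.005, rel=1e-9)


class TestPassiveFit:
    GEOM = reference_geometry(76e-6, 0.038)

    def test_twin_recovery(self):
        from fontan0d.calibration import _quasi_static_volume

        truth = PassiveLawParams(stiffness_scale=1.3)
        edp = 9.0 * MMHG
        edv = _quasi_static_volume(self.GEOM, truth, edp)
        s = fit_passive(self.GEOM, PassiveLawParams(), edp, edv)
        assert s == pytest.approx(1.3, abs=0.01)

    def test_monotone_edpvr(self):
        from fontan0d.calibration import _quasi_static_volume

        p = PassiveLawParams(stiffness_scale=1.3)
        assert _quasi_static_volume(self.GEOM, p, 18 * MMHG) > _quasi_static_volume(
            self.GEOM, p, 9 * MMHG
        )

    def test_unreachable_target_raises(self):
        with pytest.raises(ValueError, match="not bracketed|asymptotic"):
            fit_passive(self.GEOM, PassiveLawParams(), 0.1 * MMHG, 300e-6)


class TestContractilityFit:
    def test_twin_recovery_within_three_percent(self):
        model = make_default_model()
        truth_sigma0 = 30e3
        edp = 9.4 * MMHG
        patr = 2.4 * MMHG
        pve = 4.0 * MMHG
        res = run_to_periodic(
            replace(model, active=replace(model.active, sigma0=truth_sigma0)),
            mode="imposed", pve_const=edp - patr, pve_drain=pve,
            edv_init=76e-6, max_beats=30,
        )
        sv_target = res.summary.SV
        fit = fit_contractility(
            model.geom, model.passive, model.active, model.timing, model.wk,
            target_sv_mL=sv_target, edp_pa=edp, patr_amp_pa=patr,
            pve_drain_pa=pve, edv_init_m3=76e-6,
        )
        assert fit == pytest.approx(truth_sigma0, rel=0.03)

    def test_unreachable_stroke_volume_raises(self):
        model = make_default_model()
        with pytest.raises(ValueError, match="not bracketed"):
            fit_contractility(
                model.geom, model.passive, model.active, model.timing, model.wk,
                target_sv_mL=500.0, edp_pa=9 * MMHG, patr_amp_pa=2.4 * MMHG,
                pve_drain_pa=4 * MMHG,
            )


class TestVenousFit:
    WK = WindkesselParams.with_proximal_rc(Rp=0.19e8, Rd=1.25e8, Cd=2.00e-8)

    def test_cohort_typical_values(self):
        # working point (2.9 L/min, 4.1 mmHg), MSFP 20 mmHg
        v = fit_venous(4.833e-5, 546.0, self.WK, 2.4 * MMHG, 20 * MMHG)
        assert v.Cve == pytest.approx(3.70e-8, rel=0.02)
        assert v.Veff == pytest.approx(1.52e-4, rel=0.02)

    def test_roundtrip_through_working_point(self):
        from fontan0d.circulation import venous_pressure

        co, pw = 4.833e-5, 546.0
        v = fit_venous(co, pw, self.WK, 0.0, 20 * MMHG)
        assert venous_pressure(v, self.WK, co) == pytest.approx(pw, rel=1e-9)
        assert venous_pressure(v, self.WK, 0.0) == pytest.approx(20 * MMHG, rel=1e-12)

    def test_inconsistent_working_point_raises(self):
        # a steeper working-point slope than Rd*Cd/Cd implies Cve <= 0
        with pytest.raises(ValueError, match="Cve|inconsistent"):
            fit_venous(1e-6, 2500.0, self.WK, 0.0, 20 * MMHG)

    def test_pressure_outside_range_raises(self):
        with pytest.raises(ValueError, match="working-point"):
            fit_venous(4.8e-5, 3000.0, self.WK, 0.0, 20 * MMHG)


class TestFullProtocol:
    def test_deterministic(self, synthetic_record):
        cfg = CalibrationConfig()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r1 = run_full_calibration(synthetic_record, cfg)
            r2 = run_full_calibration(synthetic_record, cfg)
        assert r1.passive.stiffness_scale == r2.passive.stiffness_scale
        assert r1.active.sigma0 == r2.active.sigma0
        assert r1.wk == r2.wk
        assert r1.stress.dob_wk == r2.stress.dob_wk
        assert r1.stress.veff_factor == r2.stress.veff_factor

    def test_stages_are_frozen_once_fit(self, twin):
        # the passive stage result equals the standalone fit on the same
        # targets: later stages never feed back into it
        rep = twin["report"]
        tg = rep.targets
        s = fit_passive(
            rep.geometry, rep.config.passive_baseline,
            tg.EDP_mmHg * MMHG, tg.EDV_mL * 1e-6, rep.config,
        )
        assert rep.passive.stiffness_scale == pytest.approx(s, rel=1e-12)

    def test_identity_stress(self, synthetic_record):
        # a "stress" state identical to rest must yield unit factors
        rec = synthetic_record
        clone = replace_traces(rec, {"rest": rec.traces["rest"],
                                     "stress": rec.traces["rest"].copy()})
        clone.meta["stress"] = dict(clone.meta["rest"])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rep = run_full_calibration(clone)
        assert rep.stress.dob_wk == pytest.approx(1.0, abs=0.03)
        assert rep.stress.contractility_factor == pytest.approx(1.0, abs=0.05)
        assert rep.stress.veff_factor == pytest.approx(1.0, abs=0.05)
        assert rep.stress.qvemax_change_pct == pytest.approx(0.0, abs=5.0)

    def test_missing_stress_with_both_raises(self, synthetic_record):
        rec = synthetic_record
        only_rest = replace_traces(rec, {"rest": rec.traces["rest"]})
        with pytest.raises(ValueError, match="stress"):
            run_full_calibration(only_rest, states="both")

    def test_partial_report_attached_on_stage_failure(self, synthetic_record):
        rec = synthetic_record
        broken = replace_traces(
            rec, {k: v.copy() for k, v in rec.traces.items()}
        )
        broken.meta["rest"] = dict(broken.meta["rest"])
        broken.meta["rest"]["EDV_mL"] = 5.0  # tiny heart: a later stage fails
        broken.meta["rest"]["ESV_mL"] = 2.0
        with pytest.raises(ValueError, match="calibration stage") as excinfo:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                run_full_calibration(broken)
        partial = excinfo.value.report
        assert partial.converged["windkessel"] is True
        assert False in partial.converged.values()
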