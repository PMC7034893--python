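"""Closed-loop heart-circulation simulator.

Couples the spherical ventricle, ideal-diode valves, the two-stage
Windkessel and the Guytonian venous return into one ODE system and
integrates beats to a periodic regime with fixed-step explicit RK4
(default dt = 0.5 ms).

State vector: (lam, kc, tau_c, Par, Pd).  The ventricular pressure is an
algebraic output of (lam, tau_c) through the Laplace equilibrium, so no DAE
solver is needed.  The averaged venous flow (and with it the preload) is
recomputed continuously from the sliding flow history during integration.

Two preload modes are supported:

* ``closed``  — the preload follows the venous-return law of the averaged
  ejected flow (full closed loop),
* ``imposed`` — the preload baseline is a prescribed constant venous
  pressure (plus the atrial kick), as used when calibrating contractility
  with the measured end-diastolic pressure imposed.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .circulation import (
    FlowHistory,
    VenousLawParams,
    WindkesselParams,
    WindkesselState,
    apply_stress_scaling,
    preload_pressure,
    venous_pressure,
    windkessel_rhs,
)
from .ventricle import (
    ActivationTiming,
    ActiveLawParams,
    ActiveState,
    PassiveLawParams,
    VentricleGeometry,
    activation_value,
    active_rhs,
    ventricular_pressure,
)

__all__ = [
    "ValveParams",
    "HeartCirculationModel",
    "BeatSummary",
    "SimulationResult",
    "valve_flows",
    "assemble_rhs",
    "run_to_periodic",
    "beat_summary",
]

logger = logging.getLogger(__name__)

MMHG = 133.322


@dataclass(frozen=True)
class ValveParams:
    """Ideal-diode valve resistances.

    Defaults keep the peak transvalvular gradient below ~2 mmHg at
    physiological peak flows (no stenosis).  ``eps`` > 0 replaces the flow
    ramp corner by a C1 quadratic over [0, eps] Pa.
    """

    K_ar: float = 8e5  # aortic forward resistance (Pa s/m3)
    K_av: float = 6e5  # inflow forward resistance (Pa s/m3)
    eps: float = 0.0  # regularization width (Pa)

    def __post_init__(self) -> None:
        if self.K_ar <= 0 or self.K_av <= 0:
            raise ValueError("ValveParams: K_ar and K_av must be > 0")
        if self.eps < 0:
            raise ValueError("ValveParams: eps must be >= 0")


@dataclass(frozen=True)
class HeartCirculationModel:
    """Parameter bundle of the full closed-loop model."""

    geom: VentricleGeometry
    passive: PassiveLawParams
    active: ActiveLawParams
    timing: ActivationTiming
    wk: WindkesselParams
    venous: VenousLawParams
    valves: ValveParams = field(default_factory=ValveParams)

    def at_stress(
        self,
        dob_wk: float,
        contractility_factor: float,
        veff_factor: float,
        hr_stress: float,
        st_stress: float | None = None,
    ) -> "HeartCirculationModel":
        """Dobutamine-stress variant of this model.

        Vessels are rescaled by ``dob_wk`` (time constants preserved),
        contractility multiplied, the effective circulating volume multiplied
        by ``veff_factor``, the cycle shortened to the stress heart rate
        (bpm) and the ST segment optionally shortened.
        """
        wk2, ve2 = apply_stress_scaling(self.wk, self.venous, dob_wk)
        ve2 = replace(ve2, Veff=ve2.Veff * veff_factor)
        act2 = replace(self.active, sigma0=self.active.sigma0 * contractility_factor)
        t = self.timing
        timing2 = ActivationTiming(
            T0=60.0 / hr_stress,
            PQ=t.PQ,
            QRS=t.QRS,
            ST=st_stress if st_stress is not None else t.ST,
        )
        return replace(self, wk=wk2, venous=ve2, active=act2, timing=timing2)


@dataclass
class BeatSummary:
    """Per-beat clinical summary (clinical units at the boundary)."""

    EDV: float  # mL
    ESV: float  # mL
    SV: float  # mL
    EF: float  # %
    CO: float  # L/min
    peak_Pv: float  # mmHg
    peak_Par: float  # mmHg
    EDP: float  # mmHg
    max_dpdt: float  # mmHg/s
    notch_height: float  # mmHg (NaN if no dicrotic feature)


@dataclass
class BeatTrace:
    """Uniformly sampled arrays of one or more beats (SI units)."""

    t: np.ndarray
    Pv: np.ndarray
    Par: np.ndarray
    Pd: np.ndarray
    V: np.ndarray
    Qout: np.ndarray
    Qin: np.ndarray
    Ppreload: np.ndarray

    def to_frame(self):
        """Tidy clinical-unit DataFrame (one row per sample)."""
        import pandas as pd

        return pd.DataFrame(
            {
                "time_s": self.t,
                "Pv_mmHg": self.Pv / MMHG,
                "Par_mmHg": self.Par / MMHG,
                "Pd_mmHg": self.Pd / MMHG,
                "V_mL": self.V * 1e6,
                "Qout_mL_s": self.Qout * 1e6,
                "Qin_mL_s": self.Qin * 1e6,
                "Ppreload_mmHg": self.Ppreload / MMHG,
            }
        )


@dataclass
class SimulationResult:
    trace: BeatTrace  # last simulated beat
    summaries: list[BeatSummary]  # one per simulated beat
    converged: bool
    n_beats: int
    state: tuple[float, float, float, float, float]  # (lam, kc, tau_c, Par, Pd)
    Qve_bar: float  # m3/s (averaged output at the end; NaN in imposed mode)
    Pve_bar: float  # Pa (venous/preload baseline at the end)

    @property
    def summary(self) -> BeatSummary:
        return self.summaries[-1]


def _smooth_pos(x: float, eps: float) -> float:
    if x <= 0.0:
        return 0.0
    if eps > 0.0 and x < eps:
        return x * x / (2.0 * eps)
    return x - 0.5 * eps


def valve_flows(
    Pv: float, Par: float, Ppreload: float, vp: ValveParams
) -> tuple[float, float]:
    """Ideal-diode valve flows (Q_out, Q_in) in m3/s.

    Q_out = max(Pv - Par, 0)/K_ar and Q_in = max(Ppreload - Pv, 0)/K_av,
    optionally smoothed over ``eps``.  Reverse gradients give zero flow
    (regurgitation-free).
    """
    if not (math.isfinite(Pv) and math.isfinite(Par) and math.isfinite(Ppreload)):
        raise ValueError("valve_flows: pressures must be finite")
    q_out = _smooth_pos(Pv - Par, vp.eps) / vp.K_ar
    q_in = _smooth_pos(Ppreload - Pv, vp.eps) / vp.K_av
    return q_out, q_in


def assemble_rhs(
    state: tuple[float, float, float, float, float],
    t: float,
    model: HeartCirculationModel,
    Pve_bar: float,
) -> np.ndarray:
    """Full-state time derivative, composed from the module operations.

    ``Pve_bar`` is the current venous/preload baseline (held fixed over an
    integrator step).  The cavity pressure is evaluated algebraically; the
    volume balance dV/dt = Q_in - Q_out drives lam through the sphere
    kinematics, and the ejected flow feeds the Windkessel.
    """
    lam, kc, tau_c, par, pd = state
    s = ActiveState(kc=kc, tau_c=tau_c, e_fib=lam)
    pv = ventricular_pressure(model.geom, model.passive, s, lam)
    pp = preload_pressure(Pve_bar, model.venous, t, model.timing)
    q_out, q_in = valve_flows(pv, par, pp, model.valves)
    dlam = (q_in - q_out) / (3.0 * model.geom.V0 * lam**2)
    u = activation_value(t, model.timing, model.active)
    dkc, dtau = active_rhs(s, u, dlam, model.active)
    dpar, dpd = windkessel_rhs(model.wk, WindkesselState(Par=par, Pd=pd), q_out, Pve_bar)
    out = np.array([dlam, dkc, dtau, dpar, dpd])
    if not np.all(np.isfinite(out)):
        raise RuntimeError(f"assemble_rhs: non-finite derivative at t={t}, state={state}")
    return out


def run_to_periodic(
    model: HeartCirculationModel,
    tol: float = 0.005,
    max_beats: int = 40,
    dt: float = 5e-4,
    mode: str = "closed",
    pve_const: float | None = None,
    pve_drain: float | None = None,
    co_init: float | None = None,
    edv_init: float | None = None,
    par_init: float | None = None,
    window_cycles: int = 6,
    min_beats: int | None = None,
    record_beats: int = 1,
) -> SimulationResult:
    """Integrate beats until two successive beats agree.

    Convergence: relative change of EDV and of peak ventricular pressure
    between successive beats both < ``tol``; in closed-loop mode additionally
    the beat-mean ejected flow must match the averaged venous return within
    1% (cardiac output / venous return equilibrium).

    ``edv_init`` seeds lam (default: inflate to 2*V0); ``par_init`` seeds the
    aortic pressure; ``co_init`` pre-fills the flow history (default 79% of
    Qvemax, a typical resting working point).  In ``imposed`` mode
    ``pve_const`` (Pa) is the fixed preload baseline, and the Windkessel
    distal bed also sees this venous pressure.
    """
    if not 0.0 < tol <= 0.05:
        raise ValueError("run_to_periodic: tol must be in (0, 0.05]")
    if max_beats < 10:
        raise ValueError("run_to_periodic: max_beats must be >= 10")
    if mode not in ("closed", "imposed"):
        raise ValueError(f"run_to_periodic: unknown mode {mode!r}")
    if mode == "imposed" and pve_const is None:
        raise ValueError("run_to_periodic: imposed mode requires pve_const")
    if min_beats is None:
        # flush the pre-filled flow history before accepting equilibrium
        min_beats = window_cycles + 2 if mode == "closed" else 3

    geom, passive, active, timing = model.geom, model.passive, model.active, model.timing
    wk, ven, valves = model.wk, model.venous, model.valves

    # --- cached scalars for the fast inner loop
    V0, R0, d0 = geom.V0, geom.R0, geom.d0
    shell = (R0 + d0) ** 3 - R0**3
    C0 = passive.stiffness_scale * passive.C0
    C2 = passive.stiffness_scale * passive.C2
    C1, C3 = passive.C1, passive.C3
    sigma0, k0, alpha = active.sigma0, active.k0, active.alpha
    umax, urelax, relax_dur = active.u_max, active.u_relax, active.relax_dur
    sopt, swidth = active.starling_opt, active.starling_width
    T0, PQ, QRS, ST, avd = timing.T0, timing.PQ, timing.QRS, timing.ST, timing.av_delay
    Rp, Cp, Rd, Cd = wk.Rp, wk.Cp, wk.Rd, wk.Cd
    Kar, Kav, eps = valves.K_ar, valves.K_av, valves.eps
    patr = ven.Patr_amp
    exp, sin, cos, pi = math.exp, math.sin, math.cos, math.pi

    n_steps = max(int(round(T0 / dt)), 8)
    dt = T0 / n_steps  # integer number of steps per beat

    # --- flow history / averaged output (closed mode)
    stride = 4
    hist_dt = stride * dt
    window = window_cycles * T0
    if mode == "closed":
        qmax = ven.qve_max(wk)
        if co_init is None:
            co_init = 0.79 * qmax
        hist = FlowHistory(window, hist_dt, fill_value=co_init)
        m = hist.n
        w = np.exp(-hist_dt * np.arange(m - 1, -1, -1) / T0)
        w[0] *= 0.5
        w[-1] *= 0.5
        wsum = float(w.sum())
        qbuf = hist._q
        qbar = float(np.dot(w, qbuf) / wsum)  # buffer starts ordered
        ctot = Cd + ven.Cve
        pve_bar = max(ven.Veff / ctot - qbar * Rd * Cd / ctot, 0.0)
    else:
        hist = None
        qbar = math.nan
        pve_bar = float(pve_const)
    # venous pressure seen by the distal Windkessel bed: in closed-loop mode
    # it follows the venous law (= pve_bar); in imposed mode it may be the
    # measured venous pressure while the preload baseline is the imposed EDP
    drain = float(pve_drain) if pve_drain is not None else pve_bar

    # --- initial state
    if edv_init is None:
        edv_init = 2.0 * V0
    lam = (edv_init / V0) ** (1.0 / 3.0)
    kc = tau = 0.0
    if par_init is None:
        q_guess = co_init if mode == "closed" else 0.8 * 5e-5
        par_init = pve_bar + q_guess * Rd
    par = pd = float(par_init)

    bump_start = avd - PQ

    def rhs(tc: float, lam: float, kc: float, tau: float, par: float, pd: float, pvb: float, pdr: float):
        # tc is time within the cycle, in [0, T0)
        # ventricular pressure (Laplace, midwall)
        r_in = R0 * lam
        r_out = (r_in * r_in * r_in + shell) ** (1.0 / 3.0)
        l2 = lam * lam
        j1 = 2.0 * l2 + 1.0 / (l2 * l2)
        j4 = l2
        a1 = j1 - 3.0
        a4 = j4 - 1.0
        dwe = (
            C0 * exp(C1 * a1 * a1) * 2.0 * C1 * a1 * (4.0 * lam - 4.0 / (l2 * l2 * lam))
            + C2 * exp(C3 * a4 * a4) * 2.0 * C3 * a4 * 2.0 * lam
        )
        sigma = 0.5 * lam * dwe + max(tau, 0.0) * l2
        pv = 2.0 * (r_out - r_in) * sigma / (0.5 * (r_in + r_out))
        # preload with atrial kick
        ppl = pvb
        if bump_start <= tc < avd:
            ppl += patr * sin(pi * (tc - bump_start) / PQ)
        # valve flows
        x = pv - par
        if x <= 0.0:
            q_out = 0.0
        elif eps > 0.0 and x < eps:
            q_out = x * x / (2.0 * eps) / Kar
        else:
            q_out = (x - 0.5 * eps) / Kar
        x = ppl - pv
        if x <= 0.0:
            q_in = 0.0
        elif eps > 0.0 and x < eps:
            q_in = x * x / (2.0 * eps) / Kav
        else:
            q_in = (x - 0.5 * eps) / Kav
        dlam = (q_in - q_out) / (3.0 * V0 * l2)
        # activation
        ta = tc - avd
        if ta < 0.0:
            u = 0.0
        elif ta < QRS:
            u = umax * ta / QRS
        elif ta < QRS + ST:
            u = umax
        elif ta < 2.0 * QRS + ST:
            u = umax - (umax + urelax) * (ta - QRS - ST) / QRS
        elif ta < 2.0 * QRS + ST + relax_dur:
            u = -urelax
        else:
            u = 0.0
        # Frank-Starling
        xs = (lam - sopt) / swidth
        n0 = 0.0 if xs <= -1.0 or xs >= 1.0 else 0.5 * (1.0 + cos(pi * xs))
        up = u if u > 0.0 else 0.0
        decay = abs(u) + alpha * abs(dlam)
        dkc = -decay * kc + n0 * k0 * up
        dtau = -decay * tau + n0 * sigma0 * up + kc * dlam
        # Windkessel
        dpar = (q_out - (par - pd) / Rp) / Cp
        dpd = ((pdr - pd) / Rd - (pd - par) / Rp) / Cd
        return dlam, dkc, dtau, dpar, dpd, q_out, q_in, pv, ppl

    nrec = n_steps + 1
    rec_t = np.empty(nrec)
    rec = {k: np.empty(nrec) for k in ("Pv", "Par", "Pd", "V", "Qout", "Qin", "Ppreload")}

    summaries: list[BeatSummary] = []
    last_traces: list[BeatTrace] = []
    prev_edv = prev_ppk = None
    converged = False
    hr = 60.0 / T0
    t_abs = 0.0
    beat = 0
    half = 0.5 * dt
    sixth = dt / 6.0

    for beat in range(1, max_beats + 1):
        d0_ = rhs(0.0, lam, kc, tau, par, pd, pve_bar, drain)
        rec_t[0] = t_abs
        rec["Pv"][0], rec["Ppreload"][0] = d0_[7], d0_[8]
        rec["Par"][0], rec["Pd"][0] = par, pd
        rec["V"][0] = V0 * lam**3
        rec["Qout"][0], rec["Qin"][0] = d0_[5], d0_[6]
        q_in_int = q_out_int = 0.0
        qbar_sum = pve_sum = 0.0
        n_qbar = 0
        for k in range(n_steps):
            tc = k * dt
            k1 = rhs(tc, lam, kc, tau, par, pd, pve_bar, drain)
            k2 = rhs(
                tc + half,
                lam + half * k1[0], kc + half * k1[1], tau + half * k1[2],
                par + half * k1[3], pd + half * k1[4], pve_bar, drain,
            )
            k3 = rhs(
                tc + half,
                lam + half * k2[0], kc + half * k2[1], tau + half * k2[2],
                par + half * k2[3], pd + half * k2[4], pve_bar, drain,
            )
            k4 = rhs(
                tc + dt,
                lam + dt * k3[0], kc + dt * k3[1], tau + dt * k3[2],
                par + dt * k3[3], pd + dt * k3[4], pve_bar, drain,
            )
            lam += sixth * (k1[0] + 2.0 * k2[0] + 2.0 * k3[0] + k4[0])
            kc += sixth * (k1[1] + 2.0 * k2[1] + 2.0 * k3[1] + k4[1])
            tau += sixth * (k1[2] + 2.0 * k2[2] + 2.0 * k3[2] + k4[2])
            par += sixth * (k1[3] + 2.0 * k2[3] + 2.0 * k3[3] + k4[3])
            pd += sixth * (k1[4] + 2.0 * k2[4] + 2.0 * k3[4] + k4[4])
            # project transient numerical undershoots back to the physical range
            if kc < 0.0:
                kc = 0.0
            if tau < 0.0:
                tau = 0.0
            if not (0.2 < lam < 3.0) or not math.isfinite(par):
                raise RuntimeError(
                    f"run_to_periodic: solution left physical range at beat {beat}, "
                    f"t={t_abs + tc + dt:.4f}s (lam={lam!r}, Par={par!r}, Pd={pd!r})"
                )
            tcn = (k + 1) * dt
            out = rhs(tcn, lam, kc, tau, par, pd, pve_bar, drain)
            # step-mean valve flows (RK4 weights): these are the fluxes that
            # actually moved the cavity volume; instantaneous end-of-step
            # samples alias to zero when the solution rides the valve-opening
            # manifold during ejection
            qo = (k1[5] + 2.0 * k2[5] + 2.0 * k3[5] + k4[5]) / 6.0
            qi = (k1[6] + 2.0 * k2[6] + 2.0 * k3[6] + k4[6]) / 6.0
            i = k + 1
            rec_t[i] = t_abs + tcn
            rec["Pv"][i], rec["Ppreload"][i] = out[7], out[8]
            rec["Par"][i], rec["Pd"][i] = par, pd
            rec["V"][i] = V0 * lam**3
            rec["Qout"][i], rec["Qin"][i] = qo, qi
            q_out_int += qo * dt
            q_in_int += qi * dt
            if hist is not None and (k + 1) % stride == 0:
                hist.push(t_abs + tcn, qo)
                i0 = hist._i
                qbar = (
                    float(np.dot(w[: m - i0], qbuf[i0:]))
                    + float(np.dot(w[m - i0 :], qbuf[:i0]))
                ) / wsum
                pve_bar = max(ven.Veff / ctot - qbar * Rd * Cd / ctot, 0.0)
                drain = pve_bar
            qbar_sum += qbar
            pve_sum += pve_bar
            n_qbar += 1
        t_abs += T0
        # beat means: for a periodic flow the cycle average of the
        # exponential-kernel output equals the plain beat-mean flow
        qbar_beat = qbar_sum / n_qbar if hist is not None else math.nan
        pve_beat = pve_sum / n_qbar if hist is not None else pve_bar

        trace = BeatTrace(
            t=rec_t.copy(),
            Pv=rec["Pv"].copy(),
            Par=rec["Par"].copy(),
            Pd=rec["Pd"].copy(),
            V=rec["V"].copy(),
            Qout=rec["Qout"].copy(),
            Qin=rec["Qin"].copy(),
            Ppreload=rec["Ppreload"].copy(),
        )
        last_traces.append(trace)
        if len(last_traces) > record_beats:
            last_traces.pop(0)
        summ = beat_summary(trace, hr=hr)
        summaries.append(summ)
        edv, ppk = summ.EDV, summ.peak_Pv
        if prev_edv is not None and beat >= min_beats:
            ok = (
                abs(edv - prev_edv) / max(prev_edv, 1e-12) < tol
                and abs(ppk - prev_ppk) / max(prev_ppk, 1e-12) < tol
            )
            if ok and hist is not None:
                q_mean = q_out_int / T0
                if qbar_beat <= 1e-9:  # zero-flow (no-pump) equilibrium
                    ok = q_mean <= 1e-9
                else:
                    ok = abs(q_mean - qbar_beat) <= 0.01 * qbar_beat
            if ok:
                converged = True
                break
        prev_edv, prev_ppk = edv, ppk

    if not converged:
        warnings.warn(
            f"run_to_periodic: not periodic after {beat} beats "
            f"(EDV={summ.EDV:.2f} mL); returning best-effort result",
            RuntimeWarning,
        )
    if record_beats > 1 and len(last_traces) > 1:
        trace = BeatTrace(
            **{
                # drop the duplicated boundary sample of subsequent beats
                k: np.concatenate(
                    [getattr(last_traces[0], k)]
                    + [getattr(b, k)[1:] for b in last_traces[1:]]
                )
                for k in ("t", "Pv", "Par", "Pd", "V", "Qout", "Qin", "Ppreload")
            }
        )
    return SimulationResult(
        trace=trace,
        summaries=summaries,
        converged=converged,
        n_beats=beat,
        state=(lam, kc, tau, par, pd),
        Qve_bar=qbar_beat,
        Pve_bar=pve_beat,
    )


def beat_summary(trace: BeatTrace, hr: float) -> BeatSummary:
    """Clinical summary of (at least) one uniformly sampled beat.

    EDV/ESV are the volume extrema; EDP is the ventricular pressure at end
    diastole (maximum volume); max dp/dt is the largest forward difference of
    Pv while the aortic valve is still closed (isovolumic contraction); the
    dicrotic-notch height is the aortic pressure at the first local minimum
    after its peak, falling back to the end-ejection pressure when the notch
    is only a shoulder.
    """
    v = trace.V
    pv = trace.Pv
    par = trace.Par
    t = trace.t
    if len(t) < 3:
        raise ValueError("beat_summary: need at least one sampled beat")
    dt = t[1] - t[0]
    edv = float(v.max()) * 1e6
    esv = float(v.min()) * 1e6
    sv = edv - esv
    ef = 100.0 * sv / edv if edv > 0 else math.nan
    co = sv * hr / 1000.0  # mL/beat * bpm -> L/min
    i_ed = int(np.argmax(v))
    edp = float(pv[i_ed]) / MMHG
    peak_pv = float(pv.max()) / MMHG
    peak_par = float(par.max()) / MMHG

    dpv = np.diff(pv) / dt
    q_out = trace.Qout
    q_pk = float(q_out.max())
    if q_pk <= 0:
        warnings.warn("beat_summary: no ejection phase detected", RuntimeWarning)
        max_dpdt = float(dpv.max()) / MMHG if np.any(dpv > 0) else math.nan
        return BeatSummary(edv, esv, sv, ef, co, peak_pv, peak_par, edp,
                           max_dpdt, math.nan)
    iso = (q_out[:-1] <= 0.01 * q_pk) & (dpv > 0)
    max_dpdt = float(dpv[iso].max()) / MMHG if np.any(iso) else float(dpv.max()) / MMHG

    # dicrotic notch: first local minimum of Par after its peak
    i_pk = int(np.argmax(par))
    notch = math.nan
    seg = par[i_pk:]
    if len(seg) > 2:
        interior = (seg[1:-1] < seg[:-2]) & (seg[1:-1] <= seg[2:])
        idx = np.nonzero(interior)[0]
        if idx.size:
            notch = float(seg[idx[0] + 1]) / MMHG
    if math.isnan(notch):
        # shoulder fallback: Par when ejection ends (flow < 2% of peak)
        i_qpk = int(np.argmax(q_out))
        after = np.nonzero(q_out[i_qpk:] < 0.02 * q_pk)[0]
        if after.size:
            notch = float(par[i_qpk + after[0]]) / MMHG
    return BeatSummary(edv, esv, sv, ef, co, peak_pv, peak_par, edp, max_dpdt, notch)
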