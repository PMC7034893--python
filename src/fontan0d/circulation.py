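"""Afterload, venous return and stress scaling.

The afterload is a two-stage Windkessel: a fast proximal RC block
(aorta and first-order branches, time constant Rp*Cp = 5 ms at rest) in
series with a slow distal RC block representing the combined systemic and
pulmonary beds of the Fontan circulation:

    Cp dPar/dt + (Par - Pd)/Rp = Q
    Cd dPd/dt  + (Pd - Par)/Rp = (Pve - Pd)/Rd

The circuit is closed Guyton-style: blood conservation between the distal
arterial and venous compartments gives a linear venous-return law

    Pve_bar = Veff/(Cd + Cve) - Qve_bar * Rd*Cd/(Cd + Cve) = f(Qve_bar)

whose intercepts are the mean systemic filling pressure MSFP = f(0) and the
maximum achievable venous return Qvemax (f(Qvemax) = 0; the law is clamped
there, modeling caval collapse at negative terminal venous pressure).  The
venous flow is identified with the cardiac output averaged over a sliding
6-cycle reading frame with an exponential kernel of timescale T0.

Pharmacological (dobutamine) stress rescales the vessels: resistances are
multiplied by a common factor DOB_WK and capacitances divided by it, leaving
both RC time constants unchanged.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np

from .ventricle import ActivationTiming

__all__ = [
    "WindkesselParams",
    "WindkesselState",
    "VenousLawParams",
    "FlowHistory",
    "windkessel_rhs",
    "averaged_output",
    "venous_pressure",
    "preload_pressure",
    "apply_stress_scaling",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class WindkesselParams:
    """Two-stage Windkessel parameters (SI)."""

    Rp: float  # proximal resistance (Pa s / m3)
    Cp: float  # proximal capacitance (m3 / Pa)
    Rd: float  # distal resistance (Pa s / m3)
    Cd: float  # distal capacitance (m3 / Pa)

    def __post_init__(self) -> None:
        for name in ("Rp", "Cp", "Rd", "Cd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"WindkesselParams.{name} must be > 0")

    @classmethod
    def with_proximal_rc(
        cls, Rp: float, Rd: float, Cd: float, rc_proximal: float = 0.005
    ) -> "WindkesselParams":
        """Construct with Cp slaved to the proximal time constant (5 ms at rest)."""
        return cls(Rp=Rp, Cp=rc_proximal / Rp, Rd=Rd, Cd=Cd)


@dataclass
class WindkesselState:
    """Node pressures of the Windkessel (Pa)."""

    Par: float  # proximal (aortic) pressure
    Pd: float  # distal pressure

    def __post_init__(self) -> None:
        if not (math.isfinite(self.Par) and math.isfinite(self.Pd)):
            raise ValueError("WindkesselState pressures must be finite")


@dataclass(frozen=True)
class VenousLawParams:
    """Linear venous-return law parameters (SI).

    MSFP and Qvemax are derived properties, recomputed from (Veff, Cve) and
    the Windkessel each time, never stored.
    """

    Veff: float  # effective circulating volume (m3)
    Cve: float  # venous capacitance (m3/Pa)
    Patr_amp: float = 0.0  # atrial-contraction pressure amplitude (Pa)

    def __post_init__(self) -> None:
        if self.Veff <= 0:
            raise ValueError("VenousLawParams.Veff must be > 0")
        if self.Cve <= 0:
            raise ValueError("VenousLawParams.Cve must be > 0")
        if self.Patr_amp < 0:
            raise ValueError("VenousLawParams.Patr_amp must be >= 0")

    def msfp(self, wk: WindkesselParams) -> float:
        """Mean systemic filling pressure Veff/(Cd+Cve) (Pa)."""
        return self.Veff / (wk.Cd + self.Cve)

    def qve_max(self, wk: WindkesselParams) -> float:
        """Maximum achievable venous return Veff/(Rd Cd) (m3/s)."""
        return self.Veff / (wk.Rd * wk.Cd)


class FlowHistory:
    """Ring buffer of uniformly sampled ejected flow for output averaging.

    Stores the most recent ``span`` seconds of (time, flow) samples at fixed
    sample interval; used to evaluate the exponential-kernel average of the
    cardiac output over the 6-cycle reading frame.
    """

    def __init__(self, span: float, sample_dt: float, fill_value: float = 0.0):
        if span <= 0 or sample_dt <= 0:
            raise ValueError("FlowHistory: span and sample_dt must be > 0")
        self.sample_dt = sample_dt
        self.n = max(int(round(span / sample_dt)) + 1, 2)
        self._q = np.full(self.n, fill_value, dtype=float)
        self._i = 0  # index of the oldest sample
        self._t_last = 0.0
        self._filled = fill_value != 0.0

    @property
    def span(self) -> float:
        return (self.n - 1) * self.sample_dt

    def push(self, t: float, q: float) -> None:
        self._q[self._i] = q
        self._i = (self._i + 1) % self.n
        self._t_last = t

    def ordered(self) -> tuple[np.ndarray, np.ndarray]:
        """Samples oldest to newest with their times."""
        q = np.concatenate([self._q[self._i :], self._q[: self._i]])
        t = self._t_last - self.sample_dt * np.arange(self.n - 1, -1, -1)
        return t, q


def windkessel_rhs(
    p: WindkesselParams, s: WindkesselState, Q: float, Pve: float
) -> tuple[float, float]:
    """Time derivatives (dPar/dt, dPd/dt) of the two-stage Windkessel."""
    dpar = (Q - (s.Par - s.Pd) / p.Rp) / p.Cp
    dpd = ((Pve - s.Pd) / p.Rd - (s.Pd - s.Par) / p.Rp) / p.Cd
    return dpar, dpd


def averaged_output(
    h: FlowHistory, T0: float, window_cycles: int = 6
) -> float:
    """Exponential-kernel average of ejected flow over the reading frame.

    Q_bar = int_{t-dt}^{t} exp(-(t-tau)/T0) Q dtau / (same integral of 1),
    with dt = window_cycles * T0, evaluated by trapezoidal quadrature on the
    stored samples.  If the history spans less than the reading frame the
    plain mean of the available samples is returned (logged).
    """
    t, q = h.ordered()
    window = window_cycles * T0
    if h.span < window:
        logger.info(
            "FlowHistory spans %.3f s < reading frame %.3f s; using plain mean",
            h.span,
            window,
        )
        return float(np.mean(q))
    mask = t >= t[-1] - window * (1.0 + 1e-12) - 1e-12  # float-safe boundary
    t, q = t[mask], q[mask]
    w = np.exp(-(t[-1] - t) / T0)
    num = np.trapezoid(w * q, t)
    den = np.trapezoid(w, t)
    return float(num / den)


def venous_pressure(
    v: VenousLawParams, wk: WindkesselParams, Qve_bar: float
) -> float:
    """Linear venous-return law Pve_bar = f(Qve_bar), clamped at 0 (Pa).

    f(0) = MSFP; f(Qvemax) = 0; negative terminal venous pressures do not
    occur (caval collapse), so the averaged flow is effectively capped at
    Qvemax.
    """
    if Qve_bar < 0:
        raise ValueError("venous_pressure: Qve_bar must be >= 0")
    ctot = wk.Cd + v.Cve
    pve = v.Veff / ctot - Qve_bar * wk.Rd * wk.Cd / ctot
    return max(pve, 0.0)


def preload_pressure(
    Pve_bar: float,
    v: VenousLawParams,
    t: float,
    timing: ActivationTiming,
) -> float:
    """Ventricular preload: venous pressure plus the atrial kick (Pa).

    The atrial contraction adds a half-sine bump of amplitude ``Patr_amp``
    and width PQ, ending at the onset of ventricular activation
    (``timing.av_delay``); outside that window the preload equals the venous
    pressure.
    """
    t = t % timing.T0
    start = timing.av_delay - timing.PQ
    if start <= t < timing.av_delay:
        bump = math.sin(math.pi * (t - start) / timing.PQ)
        return Pve_bar + v.Patr_amp * bump
    return Pve_bar


def apply_stress_scaling(
    wk: WindkesselParams, v: VenousLawParams, dob_wk: float
) -> tuple[WindkesselParams, VenousLawParams]:
    """Dobutamine rescaling of the vascular system.

    Resistances are multiplied by ``dob_wk``; the three capacitances (Cp, Cd,
    Cve) are divided by it, so Rp*Cp and Rd*Cd are preserved to machine
    precision.  ``Veff`` is deliberately NOT rescaled: MSFP = Veff/(Cd+Cve)
    therefore rises by the factor ``dob_wk`` under stress; venous-return
    augmentation is handled separately through an explicit Veff factor.
    """
    if dob_wk <= 0:
        raise ValueError("apply_stress_scaling: dob_wk must be > 0")
    wk2 = WindkesselParams(
        Rp=wk.Rp * dob_wk, Cp=wk.Cp / dob_wk, Rd=wk.Rd * dob_wk, Cd=wk.Cd / dob_wk
    )
    v2 = replace(v, Cve=v.Cve / dob_wk)
    return wk2, v2
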