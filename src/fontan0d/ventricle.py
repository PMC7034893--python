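"""Spherical reduced-order ventricle.

The ventricular wall is an incompressible thick spherical shell.  The cavity
deforms homothetically: the radial extension ``lam`` scales the inner radius,
so cavity volume is ``V0 * lam**3``.  The fiber extension ``e_fib`` (sarcomere
length ratio L/L0) is identified with ``lam``.

Three constitutive ingredients act in the wall:

* a passive hyperelastic potential of Holzapfel-Ogden type, written in the
  reduced invariants J1, J4 of the right Cauchy-Green tensor,
* an active sarcomere model: a pair of ODEs for active stiffness ``kc`` and
  active stress ``tau_c`` driven by an electrical activation rate ``u`` and
  modulated by a Frank-Starling factor ``n0(e_fib)``,
* a quasi-static thin-shell (midwall Laplace) equilibrium mapping total
  in-plane Cauchy stress to cavity pressure.

Stress conventions (required for the finite-difference oracle of the passive
tension to be well defined): under incompressible equibiaxial deformation the
in-plane passive Cauchy stress is ``sigma_p = (lam/2) * dWe/dlam`` and the
active Cauchy stress is the push-forward ``sigma_a = tau_c * lam**2``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

__all__ = [
    "VentricleGeometry",
    "PassiveLawParams",
    "ActiveLawParams",
    "ActivationTiming",
    "ActiveState",
    "reference_geometry",
    "cavity_volume",
    "extension_from_volume",
    "wall_radii",
    "passive_energy",
    "passive_tension",
    "starling_factor",
    "activation_value",
    "active_rhs",
    "ventricular_pressure",
]

_FOUR_THIRDS_PI = 4.0 * math.pi / 3.0


@dataclass(frozen=True)
class VentricleGeometry:
    """Reference (stress-free) spherical-shell geometry, SI units.

    Invariants: ``V0 = 4/3 pi R0^3`` and ``Vw = 4/3 pi ((R0+d0)^3 - R0^3)``.
    """

    V0: float  # reference cavity volume (m3)
    Vw: float  # myocardial wall volume (m3)
    R0: float  # reference inner radius (m)
    d0: float  # reference wall thickness (m)
    rho_myo: float = 1050.0  # tissue density (kg/m3)

    def __post_init__(self) -> None:
        for name in ("V0", "Vw", "R0", "d0", "rho_myo"):
            if getattr(self, name) <= 0:
                raise ValueError(f"VentricleGeometry.{name} must be > 0")
        if not math.isclose(self.V0, _FOUR_THIRDS_PI * self.R0**3, rel_tol=1e-9):
            raise ValueError("VentricleGeometry: V0 inconsistent with R0")
        vw = _FOUR_THIRDS_PI * ((self.R0 + self.d0) ** 3 - self.R0**3)
        if not math.isclose(self.Vw, vw, rel_tol=1e-9):
            raise ValueError("VentricleGeometry: Vw inconsistent with (R0, d0)")


@dataclass(frozen=True)
class PassiveLawParams:
    """Coefficients of We = C0 exp(C1 (J1-3)^2) + C2 exp(C3 (J4-1)^2).

    ``stiffness_scale`` is the dimensionless relative passive stiffness
    multiplier applied to C0 and C2 only; it is the per-patient calibrated
    quantity, while (C0..C3) form a fixed population baseline pre-set to give
    a Klotz-like end-diastolic pressure-volume relationship.
    """

    C0: float = 70.0  # Pa
    C1: float = 2.0  # dimensionless
    C2: float = 70.0  # Pa
    C3: float = 5.0  # dimensionless
    stiffness_scale: float = 1.0

    def __post_init__(self) -> None:
        for name in ("C0", "C1", "C2", "C3", "stiffness_scale"):
            if getattr(self, name) <= 0:
                raise ValueError(f"PassiveLawParams.{name} must be > 0")

    def scaled(self, s: float) -> "PassiveLawParams":
        return replace(self, stiffness_scale=self.stiffness_scale * s)


@dataclass(frozen=True)
class ActiveLawParams:
    """Sarcomere active-contraction parameters.

    ``sigma0`` is the asymptotic active stress (contractility, Pa); the
    asymptotic active stiffness is slaved to it, ``k0 = k0_ratio * sigma0``.
    ``alpha`` is the cross-bridge destruction rate due to rapid length
    changes.  The activation rate has maximum ``u_max`` (35 1/s, the rate of
    active stress generation) and relaxation magnitude ``u_relax``.  The
    Frank-Starling factor ``n0`` is a raised-cosine bump equal to 1 at
    ``starling_opt`` with half-support ``starling_width``.
    """

    sigma0: float = 60e3  # Pa
    k0_ratio: float = 2.0
    alpha: float = 0.5
    u_max: float = 35.0  # 1/s
    u_relax: float = 35.0  # 1/s, magnitude of the relaxation-phase rate
    relax_dur: float = 0.2  # s, duration of the sustained relaxation phase
    starling_opt: float = 1.15
    starling_width: float = 0.35

    def __post_init__(self) -> None:
        if self.sigma0 <= 0:
            raise ValueError("ActiveLawParams.sigma0 must be > 0")
        if self.k0_ratio <= 0:
            raise ValueError("ActiveLawParams.k0_ratio must be > 0")
        if self.u_max <= 0:
            raise ValueError("ActiveLawParams.u_max must be > 0")
        if self.u_relax < 0:
            raise ValueError("ActiveLawParams.u_relax must be >= 0")
        if self.starling_width <= 0:
            raise ValueError("ActiveLawParams.starling_width must be > 0")

    @property
    def k0(self) -> float:
        """Asymptotic active stiffness (Pa)."""
        return self.k0_ratio * self.sigma0


@dataclass(frozen=True)
class ActivationTiming:
    """Cycle and ECG-segment durations (s).

    The cycle is laid out with atrial systole first: the atrial pressure bump
    occupies ``[av_delay - PQ, av_delay]`` and ventricular depolarization
    starts at ``av_delay`` (defaults to PQ, so atrial systole starts at 0).
    """

    T0: float
    PQ: float = 0.12
    QRS: float = 0.08
    ST: float = 0.30
    av_delay: float | None = None

    def __post_init__(self) -> None:
        for name in ("T0", "PQ", "QRS", "ST"):
            if getattr(self, name) <= 0:
                raise ValueError(f"ActivationTiming.{name} must be > 0")
        if self.PQ + self.QRS + self.ST >= self.T0:
            raise ValueError("ActivationTiming: PQ + QRS + ST must be < T0")
        if self.av_delay is None:
            object.__setattr__(self, "av_delay", self.PQ)


@dataclass
class ActiveState:
    """Instantaneous active rheology state."""

    kc: float = 0.0  # active stiffness (Pa)
    tau_c: float = 0.0  # active stress (Pa)
    e_fib: float = 1.0  # fiber extension L/L0

    def __post_init__(self) -> None:
        if self.kc < 0 or self.tau_c < 0:
            raise ValueError("ActiveState: kc and tau_c must be >= 0")
        if self.e_fib <= 0:
            raise ValueError("ActiveState: e_fib must be > 0")


# ---------------------------------------------------------------------------
# geometry


def reference_geometry(
    edv: float, myo_mass: float, v0_ratio: float = 0.5, rho: float = 1050.0
) -> VentricleGeometry:
    """Build the reference shell from end-diastolic volume and wall mass.

    The stress-free cavity volume is taken as ``v0_ratio`` (default 50%) of
    the end-diastolic volume; the wall volume is mass/density.  Radii follow
    from the two sphere-shell identities.

    Parameters are SI: edv (m3), myo_mass (kg), rho (kg/m3).
    """
    if edv <= 0:
        raise ValueError("reference_geometry: edv must be > 0")
    if myo_mass <= 0:
        raise ValueError("reference_geometry: myo_mass must be > 0")
    if not 0 < v0_ratio < 1:
        raise ValueError("reference_geometry: v0_ratio must be in (0, 1)")
    if rho <= 0:
        raise ValueError("reference_geometry: rho must be > 0")
    v0 = v0_ratio * edv
    vw = myo_mass / rho
    r0 = (v0 / _FOUR_THIRDS_PI) ** (1.0 / 3.0)
    r_out = ((v0 + vw) / _FOUR_THIRDS_PI) ** (1.0 / 3.0)
    return VentricleGeometry(V0=v0, Vw=vw, R0=r0, d0=r_out - r0, rho_myo=rho)


def cavity_volume(geom: VentricleGeometry, lam: float) -> float:
    """Cavity volume at radial extension ``lam``: V = V0 lam^3."""
    if lam <= 0:
        raise ValueError("cavity_volume: lam must be > 0")
    return geom.V0 * lam**3


def extension_from_volume(geom: VentricleGeometry, volume: float) -> float:
    """Exact inverse of :func:`cavity_volume`."""
    if volume <= 0:
        raise ValueError("extension_from_volume: volume must be > 0")
    return (volume / geom.V0) ** (1.0 / 3.0)


def wall_radii(geom: VentricleGeometry, lam: float) -> tuple[float, float, float, float]:
    """Deformed (inner, outer, midwall, thickness) radii at extension lam.

    The wall is incompressible: the deformed outer radius conserves Vw.
    """
    r_in = geom.R0 * lam
    shell = (geom.R0 + geom.d0) ** 3 - geom.R0**3  # = 3 Vw / 4 pi
    r_out = (r_in**3 + shell) ** (1.0 / 3.0)
    return r_in, r_out, 0.5 * (r_in + r_out), r_out - r_in


# ---------------------------------------------------------------------------
# passive law


def _invariants(lam: float) -> tuple[float, float]:
    # incompressible equibiaxial sphere deformation
    return 2.0 * lam**2 + lam**-4, lam**2


def passive_energy(p: PassiveLawParams, lam: float) -> float:
    """Hyperelastic energy density We(lam) (Pa)."""
    if lam <= 0:
        raise ValueError("passive_energy: lam must be > 0")
    j1, j4 = _invariants(lam)
    s = p.stiffness_scale
    return s * p.C0 * math.exp(p.C1 * (j1 - 3.0) ** 2) + s * p.C2 * math.exp(
        p.C3 * (j4 - 1.0) ** 2
    )


def passive_tension(p: PassiveLawParams, lam: float) -> float:
    """In-plane passive Cauchy stress sigma_p = (lam/2) dWe/dlam (Pa)."""
    if lam <= 0:
        raise ValueError("passive_tension: lam must be > 0")
    j1, j4 = _invariants(lam)
    dj1 = 4.0 * lam - 4.0 * lam**-5
    dj4 = 2.0 * lam
    s = p.stiffness_scale
    dwe = (
        s * p.C0 * math.exp(p.C1 * (j1 - 3.0) ** 2) * 2.0 * p.C1 * (j1 - 3.0) * dj1
        + s * p.C2 * math.exp(p.C3 * (j4 - 1.0) ** 2) * 2.0 * p.C3 * (j4 - 1.0) * dj4
    )
    return 0.5 * lam * dwe


# ---------------------------------------------------------------------------
# active law


def starling_factor(p: ActiveLawParams, e_fib: float) -> float:
    """Frank-Starling modulation n0(e_fib) in [0, 1].

    Raised-cosine bump: 1 at the optimal extension, 0 outside
    ``[opt - width, opt + width]``.
    """
    if e_fib <= 0:
        raise ValueError("starling_factor: e_fib must be > 0")
    x = (e_fib - p.starling_opt) / p.starling_width
    if abs(x) >= 1.0:
        return 0.0
    return 0.5 * (1.0 + math.cos(math.pi * x))


def activation_value(t: float, timing: ActivationTiming, p: ActiveLawParams) -> float:
    """Electrical activation rate u(t) (1/s) at time ``t`` within the cycle.

    Trapezoidal profile: zero until the atrio-ventricular delay, linear rise
    over QRS to ``u_max``, plateau over ST, linear fall to ``-u_relax`` over a
    second QRS-length ramp (repolarization), a sustained relaxation plateau
    at ``-u_relax`` for ``relax_dur`` (clipped to the cycle: at fast heart
    rates relaxation is incomplete), then zero in late diastole.  Times
    outside [0, T0) are reduced modulo T0.
    """
    t = t % timing.T0
    t0 = timing.av_delay
    if t < t0:
        return 0.0
    t -= t0
    if t < timing.QRS:
        return p.u_max * t / timing.QRS
    t -= timing.QRS
    if t < timing.ST:
        return p.u_max
    t -= timing.ST
    if t < timing.QRS:
        return p.u_max - (p.u_max + p.u_relax) * t / timing.QRS
    t -= timing.QRS
    if t < p.relax_dur:
        return -p.u_relax
    return 0.0


def active_rhs(
    s: ActiveState, u: float, defib_dt: float, p: ActiveLawParams
) -> tuple[float, float]:
    """Time derivatives (dkc/dt, dtau_c/dt) of the sarcomere model.

    kc'    = -(|u| + alpha |e'|) kc    + n0 k0 |u|+
    tau_c' = -(|u| + alpha |e'|) tau_c + n0 sigma0 |u|+ + kc e'

    with |u|+ = max(u, 0) and n0 = starling_factor(e_fib).
    """
    n0 = starling_factor(p, s.e_fib)
    up = max(u, 0.0)
    decay = abs(u) + p.alpha * abs(defib_dt)
    dkc = -decay * s.kc + n0 * p.k0 * up
    dtau = -decay * s.tau_c + n0 * p.sigma0 * up + s.kc * defib_dt
    return dkc, dtau


# ---------------------------------------------------------------------------
# equilibrium


def ventricular_pressure(
    geom: VentricleGeometry,
    pp: PassiveLawParams,
    s: ActiveState,
    lam: float,
) -> float:
    """Cavity pressure from quasi-static midwall Laplace equilibrium (Pa).

    Pv = 2 d(lam) sigma_tot / R_mid(lam), where the total in-plane Cauchy
    stress is sigma_tot = sigma_p(lam) + tau_c lam^2.  Inertia and wall
    viscosity are neglected.
    """
    if lam <= 0:
        raise ValueError("ventricular_pressure: lam must be > 0")
    _, _, r_mid, d = wall_radii(geom, lam)
    if r_mid <= 0:
        raise ValueError("ventricular_pressure: collapsed wall (mid radius <= 0)")
    sigma = passive_tension(pp, lam) + s.tau_c * lam**2
    return 2.0 * d * sigma / r_mid
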