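"""Synthetic XMR patients and twin experiments.

The generator runs the forward closed-loop model from a known ground-truth
parameter set (a :class:`TruthSpec`), records rest and stress traces in the
same format as real exam data, computes the scalar metadata *from the
simulation* (never copied from the truth), optionally adds multiplicative
measurement noise, and hands the result to the calibration pipeline.  A
*twin experiment* then compares recovered parameters against the truth —
the package's primary self-validation.

The default truth mimics a Fontan child of the published cohort: resting
CO ~ 2.9 L/min, EDV ~ 76-80 mL, EF ~ 53%, Windkessel and venous-capacitance
values in the cohort envelopes, MSFP 20 mmHg.  Contractility and its stress
factor are expressed in this package's stress convention (in-plane Cauchy
stress of a midwall Laplace shell), where the cohort-equivalent resting
range is ~20-40 kPa with a contractile reserve of ~1.6-2.0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import units
from .calibration import CalibrationConfig, CalibrationReport, run_full_calibration
from .circulation import VenousLawParams, WindkesselParams
from .simulator import HeartCirculationModel, SimulationResult, run_to_periodic
from .ventricle import (
    ActivationTiming,
    ActiveLawParams,
    PassiveLawParams,
    reference_geometry,
)
from .xmr import PatientRecord

__all__ = [
    "TruthSpec",
    "DEFAULT_RANGES",
    "sample_parameter_set",
    "generate_patient",
    "twin_experiment",
    "stable_cohort",
    "recovery_table",
    "RECOVERED_PARAMETERS",
]

MMHG = units.MMHG_PA

#: parameters whose recovery the twin experiment scores
RECOVERED_PARAMETERS = (
    "stiffness_scale",
    "sigma0",
    "Rp",
    "Rd",
    "Cd",
    "dob_wk",
    "contractility_factor",
    "veff_factor",
)


@dataclass(frozen=True)
class TruthSpec:
    """Ground-truth parameter set of a synthetic patient."""

    # heart: edv0/mass set the heart's *shape* (wall-to-cavity ratio); the
    # generator rescales the overall size (V0 and wall volume together, which
    # leaves the pressure-extension relation invariant) so that the emergent
    # resting EDV equals 2*V0 — the 50% reference rule the calibration assumes
    edv0_mL: float = 76.0
    mass_g: float = 38.0
    stiffness_scale: float = 1.1
    sigma0_kPa: float = 28.0
    # timing
    HR_rest_bpm: float = 70.0
    PQ_s: float = 0.12
    QRS_s: float = 0.08
    ST_s: float = 0.30
    # vessels (SI)
    Rp: float = 0.19e8
    Rd: float = 1.25e8
    Cd: float = 2.00e-8
    Cve: float = 3.70e-8
    msfp_mmHg: float = 20.0
    Patr_amp_mmHg: float = 2.4
    # stress factors
    dob_wk: float = 1.40
    contractility_factor: float = 1.8
    veff_factor: float = 1.45
    HR_stress_bpm: float = 120.0
    ST_stress_s: float = 0.15
    # measurement noise
    noise_sd: float = 0.0
    seed: int = 0

    def windkessel(self, rc_proximal: float = 0.005) -> WindkesselParams:
        return WindkesselParams(Rp=self.Rp, Cp=rc_proximal / self.Rp, Rd=self.Rd, Cd=self.Cd)

    def venous(self) -> VenousLawParams:
        veff = self.msfp_mmHg * MMHG * (self.Cd + self.Cve)
        return VenousLawParams(
            Veff=veff, Cve=self.Cve, Patr_amp=self.Patr_amp_mmHg * MMHG
        )

    def as_dict(self) -> dict[str, float]:
        d = {k: getattr(self, k) for k in RECOVERED_PARAMETERS if hasattr(self, k)}
        d["sigma0"] = self.sigma0_kPa * 1e3
        d["stiffness_scale"] = self.stiffness_scale
        return d


#: default sampling envelopes (uniform) for random truth sets; vessel and
#: stiffness ranges follow the published cohort, contractility ranges are in
#: this package's stress convention
DEFAULT_RANGES: dict[str, tuple[float, float]] = {
    "edv0_mL": (55.0, 110.0),
    "mass_g": (27.0, 78.0),
    "stiffness_scale": (1.0, 1.8),
    "sigma0_kPa": (20.0, 40.0),
    "HR_rest_bpm": (59.0, 82.0),
    "Rp": (0.17e8, 0.43e8),
    "Rd": (0.93e8, 1.9e8),
    "Cd": (0.9e-8, 2.0e-8),
    "Cve": (1.6e-8, 3.7e-8),
    "Patr_amp_mmHg": (1.5, 3.0),
    "dob_wk": (0.9, 1.4),
    "contractility_factor": (1.5, 2.0),
    "veff_factor": (1.25, 1.6),
    "HR_stress_bpm": (110.0, 130.0),
    "ST_stress_s": (0.13, 0.18),
}


def sample_parameter_set(
    ranges: dict[str, tuple[float, float]] | None = None,
    seed: int = 0,
    **fixed,
) -> TruthSpec:
    """Draw a reproducible random TruthSpec, uniform over the given ranges.

    ``ranges`` overrides entries of :data:`DEFAULT_RANGES`; ``fixed`` pins
    fields to exact values (e.g. ``noise_sd=0.02``).
    """
    r = dict(DEFAULT_RANGES)
    if ranges:
        r.update(ranges)
    for name, (lo, hi) in r.items():
        if not hi >= lo:
            raise ValueError(f"sample_parameter_set: empty range for {name}")
    rng = np.random.default_rng(seed)
    draws = {name: float(rng.uniform(lo, hi)) for name, (lo, hi) in sorted(r.items())}
    draws.update(fixed)
    return TruthSpec(seed=seed, **draws)


def _state_metadata(res: SimulationResult, hr: float, patr_amp_mmHg: float) -> dict:
    s = res.summary
    return {
        "EDV_mL": s.EDV,
        "ESV_mL": s.ESV,
        "HR_bpm": hr,
        "CO_L_min": s.CO,
        "EDP_mmHg": s.EDP,
        "peak_Pv_mmHg": s.peak_Pv,
        # "measured" preload: mean venous pressure plus the atrial kick
        "preload_mmHg": res.Pve_bar / MMHG + patr_amp_mmHg,
    }


def _trace_frame(res: SimulationResult) -> pd.DataFrame:
    tr = res.trace
    return pd.DataFrame(
        {
            "time_s": tr.t - tr.t[0],
            "Pao_Pa": tr.Par,
            "Pv_Pa": tr.Pv,
            "V_m3": tr.V,
            "Q_m3_s": tr.Qout,
        }
    )


def generate_patient(
    truth: TruthSpec,
    patient_id: str = "SYN",
    config: CalibrationConfig = CalibrationConfig(),
    record_beats: int = 3,
    sample_dt: float = 0.004,
) -> tuple[PatientRecord, dict]:
    """Forward-simulate a synthetic patient at rest and under stress.

    Returns ``(record, info)``: the record carries resampled (and, if
    ``truth.noise_sd > 0``, noise-corrupted) traces plus metadata computed
    from the *noiseless* simulation; ``info`` holds the truth dictionary,
    the noiseless record and the converged simulation results.

    The twin is made geometrically self-consistent with the 50% reference
    rule the calibration assumes: the heart *size* (V0 and wall volume
    together, a similarity transformation that leaves the pressure-extension
    relation untouched) is solved so that the emergent resting end-diastolic
    extension is exactly 2^(1/3), i.e. EDV = 2 V0.  Larger hearts pump more,
    which lowers the venous pressure along the return line and deflates end
    diastole, so the extension is monotone decreasing in size.
    """
    from scipy.optimize import brentq

    passive = replace(config.passive_baseline, stiffness_scale=truth.stiffness_scale)
    active = replace(config.active_defaults, sigma0=truth.sigma0_kPa * 1e3)
    timing = ActivationTiming(
        T0=60.0 / truth.HR_rest_bpm, PQ=truth.PQ_s, QRS=truth.QRS_s, ST=truth.ST_s
    )
    wk = truth.windkessel(config.rc_proximal_s)
    venous = truth.venous()
    patr_amp = truth.Patr_amp_mmHg

    def build(size: float) -> HeartCirculationModel:
        geom = reference_geometry(
            size * truth.edv0_mL * 1e-6,
            size * truth.mass_g * 1e-3,
            config.v0_ratio,
            config.rho_myo,
        )
        return HeartCirculationModel(
            geom=geom, passive=passive, active=active, timing=timing,
            wk=wk, venous=venous, valves=config.valves,
        )

    def rest_run(size: float, n_rec: int) -> SimulationResult:
        return run_to_periodic(
            build(size),
            tol=config.periodic_tol,
            max_beats=config.max_beats,
            dt=config.dt,
            window_cycles=config.window_cycles,
            record_beats=n_rec,
        )

    lam_target = 2.0 ** (1.0 / 3.0)

    def lam_err(size: float) -> float:
        res = rest_run(size, 1)
        if not res.converged:
            raise RuntimeError(
                f"generate_patient: rest loop not periodic at size factor {size:.2f}"
            )
        v0 = size * truth.edv0_mL * config.v0_ratio
        return (res.summary.EDV / v0) ** (1.0 / 3.0) - lam_target

    # scan for a sign change over plausible sizes, tolerating non-viable
    # extremes, then refine
    pts = []
    for size in np.geomspace(0.45, 2.4, 7):
        try:
            pts.append((size, lam_err(size)))
        except RuntimeError:
            continue
    bracket = next(
        ((s1, s2) for (s1, e1), (s2, e2) in zip(pts, pts[1:]) if e1 * e2 <= 0),
        None,
    )
    if bracket is None:
        raise RuntimeError(
            "generate_patient: cannot satisfy the 50% reference-volume rule by "
            "rescaling the heart size (no sign change over sizes 0.45-2.4; "
            f"errors {[round(e, 3) for _, e in pts]})"
        )
    size = brentq(lam_err, *bracket, xtol=1e-4)
    res_rest = rest_run(size, record_beats)
    model = build(size)
    geom = model.geom
    if not res_rest.converged:
        raise RuntimeError("generate_patient: rest simulation did not become periodic")

    model_stress = model.at_stress(
        dob_wk=truth.dob_wk,
        contractility_factor=truth.contractility_factor,
        veff_factor=truth.veff_factor,
        hr_stress=truth.HR_stress_bpm,
        st_stress=truth.ST_stress_s,
    )
    res_stress = run_to_periodic(
        model_stress,
        tol=config.periodic_tol,
        max_beats=config.max_beats,
        dt=config.dt,
        edv_init=res_rest.summary.EDV * 1e-6,
        window_cycles=config.window_cycles,
        record_beats=record_beats,
    )
    if not res_stress.converged:
        raise RuntimeError("generate_patient: stress simulation did not become periodic")

    def to_grid(df: pd.DataFrame) -> pd.DataFrame:
        from .xmr import resample_trace

        return resample_trace(df, dt=sample_dt)

    clean = PatientRecord(
        id=patient_id,
        condition="fontan",
        mass_g=size * truth.mass_g,
        Patr_amp_mmHg=patr_amp,
        PQ_s=truth.PQ_s,
        QRS_s=truth.QRS_s,
        ST_s=truth.ST_s,
        traces={
            "rest": to_grid(_trace_frame(res_rest)),
            "stress": to_grid(_trace_frame(res_stress)),
        },
        meta={
            "rest": _state_metadata(res_rest, truth.HR_rest_bpm, patr_amp),
            "stress": _state_metadata(res_stress, truth.HR_stress_bpm, patr_amp),
        },
    )
    clean.validate()

    record = clean
    if truth.noise_sd > 0:
        rng = np.random.default_rng(truth.seed)
        noisy_traces = {}
        for state, df in clean.traces.items():
            df = df.copy()
            for c in ("Pao_Pa", "Pv_Pa", "V_m3", "Q_m3_s"):
                df[c] = df[c] * (1.0 + truth.noise_sd * rng.standard_normal(len(df)))
            noisy_traces[state] = df
        record = replace_traces(clean, noisy_traces)

    info = {
        "truth": truth.as_dict(),
        "truth_spec": truth,
        "clean_record": clean,
        "rest_result": res_rest,
        "stress_result": res_stress,
        "geometry": geom,
    }
    return record, info


def replace_traces(rec: PatientRecord, traces: dict[str, pd.DataFrame]) -> PatientRecord:
    out = PatientRecord(
        id=rec.id,
        condition=rec.condition,
        mass_g=rec.mass_g,
        Patr_amp_mmHg=rec.Patr_amp_mmHg,
        PQ_s=rec.PQ_s,
        QRS_s=rec.QRS_s,
        ST_s=rec.ST_s,
        traces=traces,
        meta={k: dict(v) for k, v in rec.meta.items()},
    )
    return out


def twin_experiment(
    truth: TruthSpec,
    config: CalibrationConfig = CalibrationConfig(),
    patient_id: str = "TWIN",
) -> dict:
    """Generate a synthetic patient, calibrate it, and score the recovery.

    Returns a dict with the truth, the recovered values, the per-parameter
    relative errors (fractions) over :data:`RECOVERED_PARAMETERS`, and the
    full :class:`CalibrationReport`.
    """
    record, info = generate_patient(truth, patient_id=patient_id, config=config)
    report = run_full_calibration(record, config)
    recovered = {
        "stiffness_scale": report.passive.stiffness_scale,
        "sigma0": report.active.sigma0,
        "Rp": report.wk.Rp,
        "Rd": report.wk.Rd,
        "Cd": report.wk.Cd,
        "dob_wk": report.stress.dob_wk,
        "contractility_factor": report.stress.contractility_factor,
        "veff_factor": report.stress.veff_factor,
    }
    true_vals = info["truth"]
    errors = {
        k: (recovered[k] - true_vals[k]) / true_vals[k] for k in RECOVERED_PARAMETERS
    }
    return {
        "truth": true_vals,
        "recovered": recovered,
        "rel_errors": errors,
        "max_abs_rel_error": max(abs(v) for v in errors.values()),
        "report": report,
        "record": record,
        "info": info,
    }


def stable_cohort(
    n: int,
    seed: int = 0,
    spread: float = 0.15,
    config: CalibrationConfig = CalibrationConfig(),
    max_tries: int = 60,
) -> list[tuple[TruthSpec, PatientRecord, dict]]:
    """Generate ``n`` viable synthetic patients around the default truth.

    Each candidate perturbs every physiological field of the default
    :class:`TruthSpec` by a uniform multiplicative factor within
    ``1 +/- spread`` and is kept only if the forward generator succeeds
    (periodic rest and stress loops, 50% reference rule satisfiable).
    Candidates whose closed loop self-oscillates — circulations a
    homeostatic system would not sustain — are rejected, so the cohort
    represents stable physiologies.  Deterministic given ``seed``.
    """
    base = TruthSpec()
    pert_fields = [
        "edv0_mL", "mass_g", "stiffness_scale", "sigma0_kPa", "HR_rest_bpm",
        "Rp", "Rd", "Cd", "Cve", "Patr_amp_mmHg",
        "dob_wk", "contractility_factor", "veff_factor",
        "HR_stress_bpm", "ST_stress_s",
    ]
    rng = np.random.default_rng(seed)
    out = []
    tries = 0
    while len(out) < n and tries < max_tries:
        tries += 1
        kw = {
            f: getattr(base, f) * (1.0 + rng.uniform(-spread, spread))
            for f in pert_fields
        }
        truth = TruthSpec(**kw, seed=seed)
        try:
            rec, info = generate_patient(
                truth, patient_id=f"SYN{len(out) + 1:02d}", config=config
            )
        except RuntimeError:
            continue
        out.append((truth, rec, info))
    if len(out) < n:
        raise RuntimeError(
            f"stable_cohort: only {len(out)}/{n} viable patients in {tries} tries"
        )
    return out


def recovery_table(result: dict) -> pd.DataFrame:
    """Tidy one-row-per-parameter recovery table of a twin experiment."""
    rows = [
        {
            "parameter": k,
            "truth": result["truth"][k],
            "recovered": result["recovered"][k],
            "rel_error_pct": 100.0 * result["rel_errors"][k],
        }
        for k in RECOVERED_PARAMETERS
    ]
    return pd.DataFrame(rows)
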