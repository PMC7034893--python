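"""Cohort-level tables, validation correlations and diagram exports.

Collects per-patient :class:`~fontan0d.calibration.CalibrationReport` objects
into tidy tables (rest parameters; stress factors), computes the two
validation correlations used to judge the personalization —

* distal Windkessel resistance Rd versus the vascular resistance measured
  directly from the data ((mean Pao - Pve)/CO),
* calibrated contractility versus the measured ventricular max dp/dt,

each as an ordinary R^2 of the fitted line — and exports the per-patient
venous-return (Guyton) line endpoints (MSFP, Qvemax) and pressure-volume
loop data for plotting.
"""

from __future__ import annotations

import logging
import math
import warnings

import numpy as np
import pandas as pd

from . import units
from .calibration import CalibrationReport
from .xmr import PatientRecord, derived_measures, rsquared

__all__ = [
    "cohort_tables",
    "validation_correlations",
    "guyton_endpoints",
    "pv_loop_frame",
]

logger = logging.getLogger(__name__)


def cohort_tables(reports: list[CalibrationReport]) -> dict[str, pd.DataFrame]:
    """Rest-parameter and stress-factor tables, one row per patient."""
    rest_rows, stress_rows = [], []
    for rep in reports:
        row = rep.parameter_table()
        rest_rows.append(
            {
                k: row.get(k)
                for k in (
                    "patient", "Rp_1e8", "Rd_1e8", "Cd_1e-8", "Cve_1e-8",
                    "stiffness_scale", "sigma0_kPa",
                )
            }
        )
        if rep.stress is not None:
            stress_rows.append(
                {
                    "patient": rep.patient_id,
                    "sigma0_rest_kPa": rep.active.sigma0 / 1e3,
                    "contractility_factor": rep.stress.contractility_factor,
                    "Rd_rest_1e8": rep.wk.Rd / 1e8,
                    "dob_wk": rep.stress.dob_wk,
                    "qvemax_change_pct": rep.stress.qvemax_change_pct,
                }
            )
    return {
        "rest": pd.DataFrame(rest_rows),
        "stress": pd.DataFrame(stress_rows),
    }


def validation_correlations(
    reports: list[CalibrationReport],
    records: dict[str, PatientRecord] | list[PatientRecord],
) -> dict[str, float]:
    """R^2 of the model-vs-measurement validation scatter plots.

    ``Rd_vs_resistance``: calibrated distal resistance against the
    data-derived vascular resistance at rest.  ``sigma0_vs_max_dpdt``:
    calibrated contractility against measured max dp/dt, pooling rest and
    stress points.  Needs at least 3 patients; raises otherwise.
    """
    if isinstance(records, list):
        records = {r.id: r for r in records}
    if len(reports) < 3:
        raise ValueError("validation_correlations: need >= 3 calibrated patients")
    rd, res_meas = [], []
    sig, dpdt = [], []
    for rep in reports:
        rec = records[rep.patient_id]
        m = derived_measures(rec, "rest")
        if "resistance_Pa_s_m3" in m:
            rd.append(rep.wk.Rd)
            res_meas.append(m["resistance_Pa_s_m3"])
        sig.append(rep.active.sigma0)
        dpdt.append(m["max_dpdt_mmHg_s"])
        if rep.stress is not None and "stress" in rec.traces:
            ms = derived_measures(rec, "stress")
            sig.append(rep.active.sigma0 * rep.stress.contractility_factor)
            dpdt.append(ms["max_dpdt_mmHg_s"])
    out = {}
    out["Rd_vs_resistance"] = rsquared(res_meas, rd)
    out["sigma0_vs_max_dpdt"] = rsquared(dpdt, sig)
    return out


def guyton_endpoints(reports: list[CalibrationReport]) -> pd.DataFrame:
    """Venous-return line endpoints per patient and state (clinical units).

    MSFP in mmHg and Qvemax in L/min for the rest law and, where a stress
    calibration exists, for the stress-adapted law.
    """
    rows = []
    for rep in reports:
        rows.append(
            {
                "patient": rep.patient_id,
                "state": "rest",
                "msfp_mmHg": rep.venous.msfp(rep.wk) / units.MMHG_PA,
                "qvemax_L_min": rep.venous.qve_max(rep.wk) / units.LMIN_M3S,
            }
        )
        if rep.stress is not None:
            model_s = rep.stress_model()
            rows.append(
                {
                    "patient": rep.patient_id,
                    "state": "stress",
                    "msfp_mmHg": model_s.venous.msfp(model_s.wk) / units.MMHG_PA,
                    "qvemax_L_min": model_s.venous.qve_max(model_s.wk)
                    / units.LMIN_M3S,
                }
            )
    return pd.DataFrame(rows)


def pv_loop_frame(trace) -> pd.DataFrame:
    """Pressure-volume loop data (V in mL vs Pv in mmHg) from a beat trace."""
    return pd.DataFrame(
        {
            "V_mL": np.asarray(trace.V) * 1e6,
            "Pv_mmHg": np.asarray(trace.Pv) / units.MMHG_PA,
        }
    )


def report_to_dict(rep: CalibrationReport) -> dict:
    """JSON-serializable snapshot of a calibration report (SI parameters)."""
    out = {
        "patient_id": rep.patient_id,
        "residuals": dict(rep.residuals),
        "converged": dict(rep.converged),
    }
    if rep.geometry is not None:
        out["geometry"] = {
            "V0": rep.geometry.V0, "Vw": rep.geometry.Vw,
            "R0": rep.geometry.R0, "d0": rep.geometry.d0,
            "rho_myo": rep.geometry.rho_myo,
        }
    if rep.passive is not None:
        out["stiffness_scale"] = rep.passive.stiffness_scale
    if rep.active is not None:
        out["sigma0"] = rep.active.sigma0
    if rep.wk is not None:
        out["wk"] = {"Rp": rep.wk.Rp, "Cp": rep.wk.Cp, "Rd": rep.wk.Rd, "Cd": rep.wk.Cd}
    if rep.venous is not None:
        out["venous"] = {
            "Veff": rep.venous.Veff, "Cve": rep.venous.Cve,
            "Patr_amp": rep.venous.Patr_amp,
        }
    if rep.timing is not None:
        out["timing"] = {
            "T0": rep.timing.T0, "PQ": rep.timing.PQ,
            "QRS": rep.timing.QRS, "ST": rep.timing.ST,
        }
    if rep.stress is not None:
        out["stress"] = {
            "dob_wk": rep.stress.dob_wk,
            "contractility_factor": rep.stress.contractility_factor,
            "veff_factor": rep.stress.veff_factor,
            "st_stress_s": rep.stress.st_stress_s,
            "hr_stress_bpm": rep.stress.hr_stress_bpm,
            "qvemax_change_pct": rep.stress.qvemax_change_pct,
            "residuals": dict(rep.stress.residuals),
        }
    return out
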