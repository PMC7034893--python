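"""Reading, writing and summarizing XMR-style hemodynamic trace files.

The on-disk format mirrors the plain-text supplementary files of combined
catheterization + CMR (XMR) exams: one tab-delimited table with a header,
one row per time sample, columns identifying the subject and physiological
state (rest / stress) and the four signals — aortic pressure, ventricular
pressure, ventricular volume, aortic flow.  A *dialect* mapping allows
files with different column names or units to be ingested without code
changes.  Scalar metadata (EDV, mass, heart rate, preload, ECG timings, ...)
travels in a JSON sidecar.

Everything is converted to SI on read; clinical units (mmHg, mL, mL/s,
L/min) appear only at the boundaries.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

from . import units

__all__ = [
    "DEFAULT_DIALECT",
    "PatientRecord",
    "read_xmr_traces",
    "write_traces",
    "resample_trace",
    "derived_measures",
    "rsquared",
]

logger = logging.getLogger(__name__)

#: canonical internal (SI) trace columns
TRACE_COLUMNS = ("time_s", "Pao_Pa", "Pv_Pa", "V_m3", "Q_m3_s")

DEFAULT_DIALECT = {
    "sep": "\t",
    "columns": {
        "subject": "subject_id",
        "state": "state",
        "time": "time_s",
        "Pao": "Pao_mmHg",
        "Pv": "Pv_mmHg",
        "V": "V_mL",
        "Q": "Q_mL_s",
    },
    "units": {"time": "s", "pressure": "mmHg", "volume": "mL", "flow": "mL_s"},
}

_PRESSURE_FACTORS = {"mmHg": units.MMHG_PA, "Pa": 1.0, "kPa": 1e3}
_VOLUME_FACTORS = {"mL": 1e-6, "m3": 1.0, "L": 1e-3}
_FLOW_FACTORS = {"mL_s": 1e-6, "m3_s": 1.0, "L_min": units.LMIN_M3S}
_TIME_FACTORS = {"s": 1.0, "ms": 1e-3}


@dataclass
class PatientRecord:
    """One subject of an XMR exam: traces and scalar metadata.

    ``traces`` maps state name ('rest', 'stress') to a DataFrame with the SI
    columns ``time_s, Pao_Pa, Pv_Pa, V_m3, Q_m3_s``; ``meta`` maps state to
    per-state scalars in clinical units (EDV_mL, ESV_mL, HR_bpm,
    preload_mmHg, EDP_mmHg, peak_Pv_mmHg, CO_L_min).  Patient-level scalars
    (wall mass, atrial-kick amplitude, ECG segment durations) sit on the
    record itself.
    """

    id: str
    condition: str = "fontan"  # fontan | biventricular
    mass_g: float = float("nan")
    Patr_amp_mmHg: float = float("nan")
    PQ_s: float = float("nan")
    QRS_s: float = float("nan")
    ST_s: float = float("nan")
    traces: dict[str, pd.DataFrame] = field(default_factory=dict)
    meta: dict[str, dict[str, float]] = field(default_factory=dict)

    def validate(self) -> None:
        if self.condition not in ("fontan", "biventricular"):
            raise ValueError(f"PatientRecord {self.id}: unknown condition {self.condition!r}")
        for state, df in self.traces.items():
            missing = [c for c in TRACE_COLUMNS if c not in df.columns]
            if missing:
                raise ValueError(
                    f"PatientRecord {self.id}/{state}: missing columns {missing}"
                )
            t = df["time_s"].to_numpy()
            if len(t) < 3:
                raise ValueError(f"PatientRecord {self.id}/{state}: trace too short")
            dt = np.diff(t)
            if np.any(dt <= 0):
                raise ValueError(
                    f"PatientRecord {self.id}/{state}: time not strictly increasing"
                )
            med = float(np.median(dt))
            gaps = int(np.sum(dt > 2.0 * med))
            if gaps:
                logger.warning(
                    "PatientRecord %s/%s: %d sampling gaps > 2x median step",
                    self.id, state, gaps,
                )


def _unit_factor(kind: str, unit: str, table: dict[str, float]) -> float:
    try:
        return table[unit]
    except KeyError:
        raise ValueError(f"read_xmr_traces: unknown {kind} unit {unit!r}") from None


def read_xmr_traces(
    path: str | Path,
    dialect: dict | None = None,
    metadata_path: str | Path | None = None,
) -> dict[str, PatientRecord]:
    """Read an XMR-style trace file into validated patient records.

    ``dialect`` overrides :data:`DEFAULT_DIALECT` (column names, units,
    separator); ``metadata_path`` points to the JSON sidecar of scalar
    metadata keyed by subject id.
    """
    d = dict(DEFAULT_DIALECT)
    if dialect:
        d = {**d, **dialect}
        d["columns"] = {**DEFAULT_DIALECT["columns"], **dialect.get("columns", {})}
        d["units"] = {**DEFAULT_DIALECT["units"], **dialect.get("units", {})}
    cols = d["columns"]
    df = pd.read_csv(path, sep=d["sep"])
    required = [cols[k] for k in ("subject", "state", "time", "Pao", "Pv", "V", "Q")]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"read_xmr_traces: missing required columns {missing}")

    ft = _unit_factor("time", d["units"]["time"], _TIME_FACTORS)
    fp = _unit_factor("pressure", d["units"]["pressure"], _PRESSURE_FACTORS)
    fv = _unit_factor("volume", d["units"]["volume"], _VOLUME_FACTORS)
    fq = _unit_factor("flow", d["units"]["flow"], _FLOW_FACTORS)

    meta_all: dict = {}
    if metadata_path is not None:
        meta_all = json.loads(Path(metadata_path).read_text())

    records: dict[str, PatientRecord] = {}
    for (sid, state), g in df.groupby([cols["subject"], cols["state"]], sort=False):
        sid = str(sid)
        rec = records.get(sid)
        if rec is None:
            rec = PatientRecord(id=sid)
            m = meta_all.get(sid, {})
            for key in ("condition",):
                if key in m:
                    rec.condition = m[key]
            for key in ("mass_g", "Patr_amp_mmHg", "PQ_s", "QRS_s", "ST_s"):
                if key in m:
                    setattr(rec, key, float(m[key]))
            rec.meta = {k: dict(v) for k, v in m.get("states", {}).items()}
            records[sid] = rec
        rec.traces[str(state)] = pd.DataFrame(
            {
                "time_s": g[cols["time"]].to_numpy(float) * ft,
                "Pao_Pa": g[cols["Pao"]].to_numpy(float) * fp,
                "Pv_Pa": g[cols["Pv"]].to_numpy(float) * fp,
                "V_m3": g[cols["V"]].to_numpy(float) * fv,
                "Q_m3_s": g[cols["Q"]].to_numpy(float) * fq,
            }
        )
    for rec in records.values():
        rec.validate()
    return records


def write_traces(
    records: dict[str, PatientRecord] | list[PatientRecord],
    path: str | Path,
    metadata_path: str | Path | None = None,
) -> None:
    """Write records in the default dialect (tab-delimited, clinical units).

    Numeric values are written with 9 significant digits so a read/write
    round trip preserves values to ~1e-9 relative.
    """
    if isinstance(records, dict):
        records = list(records.values())
    frames = []
    meta_all: dict = {}
    for rec in records:
        for state, df in rec.traces.items():
            frames.append(
                pd.DataFrame(
                    {
                        "subject_id": rec.id,
                        "state": state,
                        "time_s": df["time_s"],
                        "Pao_mmHg": df["Pao_Pa"] / units.MMHG_PA,
                        "Pv_mmHg": df["Pv_Pa"] / units.MMHG_PA,
                        "V_mL": df["V_m3"] * 1e6,
                        "Q_mL_s": df["Q_m3_s"] * 1e6,
                    }
                )
            )
        meta_all[rec.id] = {
            "condition": rec.condition,
            "mass_g": rec.mass_g,
            "Patr_amp_mmHg": rec.Patr_amp_mmHg,
            "PQ_s": rec.PQ_s,
            "QRS_s": rec.QRS_s,
            "ST_s": rec.ST_s,
            "states": rec.meta,
        }
    out = pd.concat(frames, ignore_index=True)
    out.to_csv(path, sep="\t", index=False, float_format="%.9g")
    if metadata_path is not None:
        Path(metadata_path).write_text(json.dumps(meta_all, indent=1))


def resample_trace(df: pd.DataFrame, dt: float = 0.004) -> pd.DataFrame:
    """Resample an SI trace to a uniform grid by monotone cubic interpolation.

    PCHIP preserves monotone segments (no overshoot at sharp valve events)
    and keeps beat integrals of flow within ~0.1%.
    """
    t = df["time_s"].to_numpy()
    tu = np.arange(t[0], t[-1] + 0.5 * dt, dt)
    tu = tu[tu <= t[-1]]
    out = {"time_s": tu}
    for c in df.columns:
        if c == "time_s":
            continue
        out[c] = PchipInterpolator(t, df[c].to_numpy())(tu)
    return pd.DataFrame(out)


def _savgol_like_derivative(y: np.ndarray, dt: float) -> np.ndarray:
    """5-sample quadratic (Savitzky-Golay) smoothed first derivative."""
    w = np.array([-2.0, -1.0, 0.0, 1.0, 2.0]) / (10.0 * dt)
    d = np.convolve(y, w[::-1], mode="valid")
    # pad ends with one-sided differences to keep the length
    head = [(y[1] - y[0]) / dt, (y[2] - y[0]) / (2 * dt)]
    tail = [(y[-1] - y[-3]) / (2 * dt), (y[-1] - y[-2]) / dt]
    return np.concatenate([head, d, tail])


def derived_measures(rec: PatientRecord, state: str) -> dict[str, float]:
    """Data-side clinical measures for one state (clinical units).

    EDV/ESV/SV/EF from the volume trace, CO from SV and the metadata heart
    rate, max dp/dt from the smoothed derivative of the ventricular
    pressure, and the measured vascular resistance
    (mean Pao - Pve) / CO in Pa s/m3, with the venous pressure taken as
    preload minus the atrial-kick amplitude.
    """
    if state not in rec.traces:
        raise ValueError(f"derived_measures: no {state!r} traces for {rec.id}")
    df = rec.traces[state]
    meta = rec.meta.get(state, {})
    hr = float(meta.get("HR_bpm", math.nan))
    t = df["time_s"].to_numpy()
    if math.isfinite(hr) and (t[-1] - t[0]) < 60.0 / hr:
        raise ValueError("derived_measures: trace shorter than one beat")
    v = df["V_m3"].to_numpy() * 1e6
    pv = df["Pv_Pa"].to_numpy() / units.MMHG_PA
    pao = df["Pao_Pa"].to_numpy() / units.MMHG_PA
    edv, esv = float(v.max()), float(v.min())
    sv = edv - esv
    ef = 100.0 * sv / edv
    co = sv * hr / 1000.0
    dt = float(np.median(np.diff(t)))
    max_dpdt = float(_savgol_like_derivative(pv, dt).max())
    out = {
        "EDV_mL": edv,
        "ESV_mL": esv,
        "SV_mL": sv,
        "EF_pct": ef,
        "CO_L_min": co,
        "max_dpdt_mmHg_s": max_dpdt,
        "peak_Pv_mmHg": float(pv.max()),
        "peak_Pao_mmHg": float(pao.max()),
    }
    preload = float(meta.get("preload_mmHg", math.nan))
    if math.isfinite(preload) and math.isfinite(rec.Patr_amp_mmHg) and co > 0:
        pve_pa = (preload - rec.Patr_amp_mmHg) * units.MMHG_PA
        mean_pao_pa = float(df["Pao_Pa"].mean())
        out["resistance_Pa_s_m3"] = (mean_pao_pa - pve_pa) / (co * units.LMIN_M3S)
    return out


def rsquared(x, y) -> float:
    """Coefficient of determination of the ordinary least-squares line y ~ x."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("rsquared: need equal-length 1-d series with >= 3 points")
    sxx = float(np.var(x))
    if sxx == 0.0:
        raise ValueError("rsquared: zero variance in x")
    syy = float(np.var(y))
    if syy == 0.0:
        return 1.0
    r = float(np.corrcoef(x, y)[0, 1])
    return r * r
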