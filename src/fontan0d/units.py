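"""Exact unit-conversion constants used at the package boundaries.

Internally everything is SI (Pa, m3, m3/s, s).  Clinical boundaries use
mmHg, mL, mL/s and L/min.  All conversions are single multiplications by
exact constants so that round trips are bit-stable.
"""

MMHG_PA = 133.322
"""Pa per mmHg (conventional exact value)."""

ML_M3 = 1e-6
"""m3 per mL."""

LMIN_M3S = 1e-3 / 60.0
"""m3/s per L/min."""


def mmhg_to_pa(p: float) -> float:
    return p * MMHG_PA


def pa_to_mmhg(p: float) -> float:
    return p / MMHG_PA


def ml_to_m3(v: float) -> float:
    return v * ML_M3


def m3_to_ml(v: float) -> float:
    return v / ML_M3


def lmin_to_m3s(q: float) -> float:
    return q * LMIN_M3S


def m3s_to_lmin(q: float) -> float:
    return q / LMIN_M3S


def mls_to_m3s(q: float) -> float:
    return q * 1e-6


def m3s_to_mls(q: float) -> float:
    return q / 1e-6
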