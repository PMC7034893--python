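"""Venous-return (Guyton) line and the circulatory operating point.

Prints the linear venous-return relation Pve = f(Qve) of the default
patient — its intercepts are the mean systemic filling pressure (zero-flow
pressure) and the maximum achievable venous return (caval-collapse limit) —
together with the operating point where the closed loop actually settles.
"""

import numpy as np

from fontan0d.circulation import venous_pressure
from fontan0d.synthetic import TruthSpec, generate_patient
from fontan0d.units import m3s_to_lmin, pa_to_mmhg

truth = TruthSpec()
record, info = generate_patient(truth)
wk, ven = truth.windkessel(), truth.venous()

print(f"MSFP   = {pa_to_mmhg(ven.msfp(wk)):5.1f} mmHg (venous pressure at zero flow)")
print(f"Qvemax = {m3s_to_lmin(ven.qve_max(wk)):5.2f} L/min (caval-collapse limit)")
print("\n   Qve (L/min)   Pve (mmHg)")
for q in np.linspace(0, ven.qve_max(wk), 6):
    print(f"   {m3s_to_lmin(q):8.2f}     {pa_to_mmhg(venous_pressure(ven, wk, q)):8.2f}")

res = info["rest_result"]
print(
    f"\noperating point: CO = {res.summary.CO:.2f} L/min at "
    f"Pve = {pa_to_mmhg(res.Pve_bar):.2f} mmHg"
)
print(
    "\nThe heart can only pump what the veins return: the closed loop "
    "settles where the\ncardiac-output curve crosses this line, here at "
    "~80% of the maximum venous return."
)
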