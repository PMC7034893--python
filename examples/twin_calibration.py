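"""Twin experiment: recover known ground truth from synthetic exam data.

A synthetic patient is forward-simulated from a known parameter set, its
traces and scalar metadata are handed (blind) to the six-step calibration
protocol, and the recovered parameters are compared with the truth.  This
is the package's primary self-validation.
"""

from fontan0d.synthetic import TruthSpec, recovery_table, twin_experiment

result = twin_experiment(TruthSpec())
print(recovery_table(result).to_string(index=False, float_format="%.4g"))
print(f"\nworst parameter error: {100 * result['max_abs_rel_error']:.2f}%")
print(
    "\nEach row compares a generating (true) parameter with the value the "
    "sequential\ncalibration recovered from the traces alone; errors of a "
    "few percent reflect the\nfeature tolerances of the individual stages "
    "(1 mmHg on pressures, 1 mL on volumes)."
)
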