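# fontan0d

A closed-loop, reduced-order (0D) biomechanical model of the heart and
circulation, with an automated patient-specific calibration pipeline, built
for interpreting combined catheterization + CMR (**XMR**) dobutamine-stress
exams in patients with **Fontan circulation** — a surgically created
single-ventricle circulation in which the systemic venous return flows
passively to the lungs. The package is for researchers in computational
cardiovascular physiology who want to turn per-patient pressure/volume/flow
traces into biophysical quantities that the exam cannot measure directly:
myocardial passive stiffness, contractility, contractile reserve under
inotropic stress, and vascular resistance.

## The model

The ventricle is a thick incompressible spherical shell. With radial
extension λ (cavity volume `V = V0 λ³`, fiber extension `e_fib = λ`), the
wall carries

* a passive hyperelastic stress from the potential
  `We = C0 exp(C1 (J1−3)²) + C2 exp(C3 (J4−1)²)`,
  with reduced invariants `J1 = 2λ² + λ⁻⁴`, `J4 = λ²` and a per-patient
  *relative stiffness* multiplying C0, C2;
* an active sarcomere stress τ_c and stiffness k_c evolving as

  ```
  k̇c = −(|u| + α|ė_fib|) kc + n0 k0 |u|₊
  τ̇c = −(|u| + α|ė_fib|) τc + n0 σ0 |u|₊ + kc ė_fib
  ```

  driven by an ECG-timed activation rate u (peak 35 s⁻¹) and modulated by a
  Frank–Starling factor `n0(e_fib) ∈ [0,1]`; σ0 is the contractility.

Cavity pressure follows from midwall Laplace equilibrium,
`Pv = 2 d σ_tot / R_mid`. Ideal-diode valves connect the ventricle to a
two-stage Windkessel afterload

```
Cp Ṗar + (Par − Pd)/Rp = Q,      Cd Ṗd + (Pd − Par)/Rp = (Pve − Pd)/Rd
```

and the loop is closed Guyton-style: the ejected flow, averaged over a
6-cycle exponential reading frame, sets the venous pressure through the
linear venous-return law

```
P̄ve = Veff/(Cd+Cve) − Q̄ve · Rd·Cd/(Cd+Cve)
```

whose intercepts are the mean systemic filling pressure (MSFP) and the
maximum achievable venous return Qvemax (caval collapse). Dobutamine stress
multiplies the resistances by a common factor DOB_WK and divides the
capacitances by it (RC time constants preserved), raises heart rate,
shortens the ST segment, multiplies σ0, and rescales Veff.

**Calibration** is a deterministic six-step sequence of bracketed 1-D
solves: (1) geometry from EDV and wall mass (reference volume = 50% of
resting EDV); (2) Windkessel from the imposed aortic flow — diastolic decay
constant, dicrotic pressure, peak systolic pressure; (3) relative passive
stiffness from (EDP, EDV); (4) contractility from the stroke volume with
the measured EDP imposed as preload; (5) the venous line through the
resting working point and an assumed MSFP of 20 mmHg; (6) the stress
factors (DOB_WK, contractile reserve, Veff factor) from the stress traces.

## Worked example

```bash
python examples/simulate_rest_and_stress.py
```

```
rest:   8 beats to periodicity
  EDV  76.9 mL  ESV  36.6 mL  EF 52.4 %  CO 2.82 L/min
  peak Pv  81.3 mmHg  EDP 10.4 mmHg  venous pressure  4.5 mmHg
stress: 8 beats to periodicity
  EDV  74.0 mL  ESV  39.6 mL  EF 46.4 %  CO 4.12 L/min  peak Pv 145.1 mmHg
```

A Fontan-typical resting state (output 2.8 L/min at a venous pressure of
4.5 mmHg, ~80% of the 3.65 L/min venous-return ceiling) and its dobutamine
response: cardiac output rises ~45% through rate and contractility while
end-diastolic volume is held up by the venous-return augmentation.

The twin experiment — the package's primary self-validation — forward
simulates a synthetic patient, hands its traces blind to the calibration,
and compares recovered with true parameters:

```bash
python examples/twin_calibration.py
```

```
           parameter    truth  recovered  rel_error_pct
     stiffness_scale      1.1      1.103         0.2698
              sigma0  2.8e+04  2.731e+04         -2.465
                  Rp  1.9e+07  1.921e+07           1.13
                  Rd 1.25e+08  1.247e+08        -0.2113
                  Cd    2e-08  2.009e-08         0.4427
              dob_wk      1.4      1.398        -0.1568
contractility_factor      1.8      1.748         -2.914
         veff_factor     1.45      1.409         -2.814
```

Every parameter returns within a few percent of truth. Other examples show
the Guyton diagram (`guyton_diagram.py`), the MSFP sensitivity sweep
(`msfp_sensitivity.py`) and a calibrated synthetic cohort with validation
correlations (`cohort_report.py`). A thin CLI (`fontan0d simulate |
calibrate | synth | report`) wraps the same functions for shell use.

## Layout

```
src/fontan0d/
  ventricle.py     spherical ventricle: passive law, sarcomere ODEs, Laplace
  circulation.py   Windkessel, flow averaging, venous-return law, stress scaling
  simulator.py     closed-loop RK4 integration, beat summaries
  calibration.py   the six-step personalization protocol
  xmr.py           trace-file IO (dialect-configurable), derived measures
  synthetic.py     ground-truth generator, twin experiments, cohorts
  reporting.py     cohort tables, validation correlations, Guyton exports
  cli.py           thin click CLI
docs/methods.md    model assumptions, parameters, numerical choices
```
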