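# Methods

This note records the model, its assumptions, the parameters that matter,
the numerical choices, and what the synthetic-data validation does and does
not demonstrate.

## Reduced-order ventricle

**Kinematics.** The ventricle is an incompressible thick spherical shell
described by one kinematic degree of freedom, the radial extension λ of the
inner radius: cavity volume `V = V0 λ³` with V0 the stress-free reference
volume. The deformed outer radius conserves wall volume. The sarcomere
(fiber) extension is identified with λ; this is exact for the cavity and a
midwall approximation for the fibers, consistent to the order of the
thin-shell equilibrium used below.

**Passive law.** `We = C0 exp(C1 (J1−3)²) + C2 exp(C3 (J4−1)²)` with the
incompressible equibiaxial invariants `J1 = 2λ² + λ⁻⁴`, `J4 = λ²`. The
in-plane passive Cauchy stress is defined as `σ_p = (λ/2) dWe/dλ`; this
definition is stated explicitly so that the finite-difference oracle tests
of the tension are unambiguous. The four coefficients form a fixed
population baseline — C0 = C2 = 70 Pa, C1 = 2, C3 = 5 — pre-set so that the
quasi-static pressure at the 50%-rule extension λ = 2^(1/3) is ≈ 9 mmHg for
a typical patient, i.e. an end-diastolic pressure–volume relationship with
a physiological knee. Per-patient stiffness enters only through the
dimensionless `stiffness_scale` multiplying C0 and C2; this is the quantity
the calibration identifies and the one comparable across patients.

**Active law.** The sarcomere ODEs for active stiffness k_c and stress τ_c
(see README) are driven by the activation rate u(t): a trapezoid rising
over QRS to u_max = 35 s⁻¹, holding over ST, falling over a second
QRS-length ramp to −u_relax (default 35 s⁻¹), then holding at −u_relax for
a sustained relaxation phase of duration `relax_dur` (default 0.2 s,
clipped by the cycle) before returning to zero in late diastole. The
sustained negative phase is required for complete diastolic relaxation: the
ODEs have no decay channel once u = 0 (other than the |ė| term), and
without it residual active stress poisons filling. At stress heart rates
the clipping makes relaxation incomplete — a real physiological phenomenon
the model therefore reproduces qualitatively. The Frank–Starling factor
`n0` is a raised cosine equal to 1 at extension 1.15 with half-support
0.35; the exact experimental shape is only known graphically, so both
numbers are exposed as parameters. k0 is slaved to σ0 with ratio 2
(configurable); α defaults to 0.5 (no published value; exposed).

**Equilibrium.** Quasi-static midwall Laplace: `Pv = 2 d σ_tot / R_mid`
with `σ_tot = σ_p + τ_c λ²` (the λ² being the push-forward of the active
stress to the deformed configuration). Inertia, wall viscosity and the
series elastic element of the full sarcomere rheology are omitted. Two
consequences worth naming: (i) pressure is invariant under geometric
similarity (all radii scaled), which the generator exploits; (ii) the
numerical value of σ0 in this dialect is *lower* than values quoted for
models that include a series element — the cohort-equivalent resting range
here is roughly 20–40 kPa with a contractile reserve of 1.6–2.0, and σ0
values should only be compared within this convention.

## Circulation and closure

Two-stage Windkessel (equations in the README) with Cp slaved to the
proximal time constant Rp·Cp = 5 ms at rest. Ideal-diode valves,
`Q = max(ΔP, 0)/K`, with K_ar = 8·10⁵ and K_av = 6·10⁵ Pa·s/m³ — peak
transvalvular gradients below ~2 mmHg (non-stenotic); an optional C¹
quadratic smoothing over an `eps` pressure width exists but defaults off.

The venous return is the ejected flow averaged with an exponential kernel
of timescale T0 over a sliding 6-cycle reading frame, mapped through the
linear venous law and clamped at zero pressure (caval collapse). Two
properties of this closure matter in practice:

* the kernel output of a pulsatile periodic flow oscillates within the beat
  (~±25% for a resting ejection waveform) and its *instantaneous* value at
  any fixed phase is biased; its cycle average equals the beat-mean flow,
  which is what the equilibrium check |CO − Q̄ve| ≤ 1% and the reported
  venous quantities use;
* the delayed feedback can destabilize the loop. When the cardiac demand
  approaches Qvemax the clamp engages within the beat and the loop can fall
  into sustained period-2 alternans or slow (~6-beat) limit cycles. These
  are genuine regimes of the stated closure, not integrator artifacts; the
  simulator reports them as non-periodic, and the calibration and cohort
  sampler treat non-periodic regimes as infeasible.

Dobutamine stress: resistances ×DOB_WK, all three capacitances ÷DOB_WK
(time constants preserved exactly). Veff is *not* rescaled by DOB_WK —
MSFP rises under stress — and venous-return augmentation is carried by an
explicit separate Veff factor, which is also what changes Qvemax.

## Integration

Fixed-step explicit RK4, dt = 0.5 ms, with the cavity pressure evaluated
algebraically from (λ, τ_c) — no DAE solver. The recorded and
history-fed valve flows are the RK4-weighted step means: during ejection
the solution rides the valve-opening manifold and instantaneous
end-of-step samples alias toward zero, which would corrupt both the traces
and the venous feedback. The averaged venous flow is refreshed every 2 ms
from a ring buffer holding the 6-cycle frame (trapezoidal quadrature with
precomputed kernel weights). Periodicity is declared when successive-beat
EDV and peak pressure change by <0.5% and (closed loop) the beat-mean
ejected flow matches the averaged venous return within 1%; the flow
history is pre-filled with a working-point guess (79% of Qvemax) and the
equilibrium check is deferred until the frame has been flushed. Halving dt
changes beat summaries by <0.2%.

## Calibration: choices within the protocol

* *Windkessel (step 2).* Features taken from the beat-folded trace
  (ensemble average of all recorded cycles, which suppresses uncorrelated
  noise): the diastolic decay constant by linear regression of
  log(Par − Pve) over late diastole; the dicrotic feature as the aortic
  pressure at end-ejection (flow < 2% of peak) — the ideal-diode model
  produces a shoulder rather than a true local minimum, so this surrogate
  is the like-for-like feature on both data and simulation; the peak
  systolic pressure. Cd is obtained in closed form by matching the slow
  eigenvalue of the Windkessel matrix to the fitted decay constant (the
  naive Cd = τ/Rd carries a ~1% proximal-capacitance bias). Rd is solved on
  the dicrotic pressure with Rp nested on the peak; the decoupled system is
  linear, so each candidate is evaluated by exact per-step propagation of
  its periodic orbit — no transient beats.
* *Passive (step 3).* Quasi-static inflation to the measured EDP must give
  the measured EDV; geometric bisection on the stiffness scale, refined to
  a 0.5% bracket (a steep EDPVR makes the 0.5 mL volume tolerance alone
  under-determine the scale).
* *Contractility (step 4).* The measured EDP (minus the atrial-kick
  amplitude, which the model re-adds with its PQ-timed half-sine) is
  imposed as the preload baseline while the distal bed drains at the
  measured venous pressure; Brent solve of σ0 on the stroke volume.
  Because this stage never touches the venous law, the contractility and
  (below) the contractile reserve are exactly independent of the assumed
  MSFP.
* *Venous line (step 5).* Through (0, MSFP_assumed) and the resting working
  point; the working-point venous pressure is the measured preload minus
  the atrial-kick amplitude. MSFP defaults to 20 mmHg.
* *Stress (step 6).* DOB_WK from the decoupled Windkessel driven by the
  measured stress flow, matching the measured peak ventricular pressure
  (peak aortic ≈ peak ventricular in the absence of aortic stenosis). The
  ST duration is solved so the simulated pressure-wave width (interval
  above half of peak-minus-EDP) matches the data; the width is
  non-monotone in ST — over-long activation at stress heart rates
  collapses filling — so the solve scans a grid, discards collapsed beats
  and refines on the healthy branch, with one ST↔σ0 refinement pass. The
  stress contractility is solved on the ESV in the preload-imposed
  configuration (MSFP independence, as above; the price is a small
  systematic bias, ~3% in the twin, from the surrogate's slightly
  different filling dynamics at stress rates). The Veff factor is solved
  on the stress EDV in the *closed loop*, with candidates screened for
  periodicity and, when the target EDV is unreachable on the stable
  branch, clamped to the closest stable factor with a warning.

Stages are frozen once fit. The whole protocol is deterministic; there is
no randomness anywhere in calibration.

## Synthetic data and twin experiments

The generator forward-simulates rest and stress from a known truth,
resamples the traces to a 4 ms grid, and computes all scalar metadata from
the noiseless simulation (the "measured preload" is the beat-mean venous
pressure plus the atrial-kick amplitude). Noise, when requested, is
multiplicative Gaussian on the trace samples (default 2%), seeded and
applied after the metadata are extracted — mimicking post-processed
clinical scalars alongside raw noisy waveforms. Beat timings are left
clean; no imaging artifacts, respiration or arrhythmia are emulated, so
noisy-twin results bound only the sensor-noise pathway, not model
discrepancy on real data.

Geometric self-consistency: the calibration assumes V0 = EDV/2, so the
generator solves the heart *size* (V0 and wall volume co-scaled — a
similarity transform that leaves the pressure–extension relation
untouched) so that the emergent resting EDV equals 2·V0. Larger hearts
pump more, depress the venous pressure along the return line and deflate
end diastole, making the emergent extension monotone in size and the solve
well-posed. The truth's EDV/mass fields therefore set the heart's *shape*
(wall-to-cavity ratio); the record carries the realized mass.

`sample_parameter_set` draws uniformly from cohort-anchored envelopes
(resistances, capacitances, stiffness from the published patient tables;
contractility in this package's stress convention). Independent draws from
these envelopes are *not* guaranteed to yield stable circulations — many
combinations put the working point at the venous-return ceiling, where the
closure self-oscillates — and the generator rejects them with explicit
errors. `stable_cohort` provides screened cohorts (±15% perturbations of
the default patient, rejection-sampled on forward-generator success),
representing the homeostatically stable physiologies a real cohort
consists of.

Twin results with the default conditions: every recovered parameter within
~3% of truth noiseless; with 2% trace noise the median worst-parameter
error over seeds is ~8% (the decay-constant/Cd pathway is the most
noise-sensitive). The MSFP sweep (15/20/25 mmHg) leaves contractility and
reserve exactly unchanged and moves the Qvemax-change estimate by <5
percentage points. Problem sizes used throughout the tests and the
acceptance script: one noiseless twin, a 3-point MSFP sweep, and 5 noise
seeds — each twin is a full generate-and-calibrate cycle of a few hundred
simulated beats.

## Known limitations

* No series elastic element: isovolumic phases are sharper than measured
  waveforms, and σ0 values are dialect-specific (see above).
* One lumped distal bed: systemic and pulmonary resistances are not
  separated, so Rd is their combination.
* The linear venous law with a hard collapse clamp creates instability
  regions near Qvemax; real venous beds saturate smoothly.
* The preload-imposed contractility stage carries a small systematic bias
  at stress heart rates (quantified by the twin, ~3%).
* The file dialect layer covers column naming and units only; beat
  detection assumes traces recorded from a cycle boundary, as the
  generator and typical exports provide.
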