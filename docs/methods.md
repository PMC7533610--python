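# Methods

## The model

`cardioinverse` couples a lumped-parameter (0D) model of the closed
circulation to a carotid-baroreflex feedback loop, and inverts its systemic
and pulmonary arterial pressure outputs back to the four parameters that
characterize left-ventricular (LV) systolic function.

### Circulation

The circulation is a closed loop of vascular compartments (systemic
arteries; splanchnic and extrasplanchnic peripheral and venous beds;
pulmonary arteries, peripheral bed and veins) around four heart chambers.
Each vascular compartment obeys mass conservation,
`dV_i/dt = Q_in − Q_out`, with a linear compliance `P_i = (V_i − Vu_i)/C_i`;
the two arterial compartments additionally carry an inertance, so their
outflow obeys the momentum balance
`P_in − P_out = R Q + L dQ/dt`.  Non-inertial branches reduce to the Ohmic
`Q = ΔP/R`.  Atria are passive compliance chambers.  Ventricles follow a
time-varying-elastance law mixing the end-systolic line with an exponential
end-diastolic pressure–volume relation (EDPVR):

    P_iso(V, t) = φ(t) · E(t) · (V − Vu) + (1 − φ(t)) · P0 · (exp(kE · V) − 1)

with a squared-sine activation `φ` spanning a systole of duration
`T_sys = T_sys0 − k_sys / T`.  Ejection sees a viscous resistance
proportional to the isovolumic pressure (`R_v = k_r · P_iso`); valves are
ideal diodes that open only on a positive pressure gradient, so all four
valve flows are non-negative by construction.

State variables are compartment **volumes** (plus the two inertial flows),
so total blood volume is conserved exactly up to integrator round-off; the
splanchnic and extrasplanchnic peripheral beds share one node pressure and
are stored as a combined volume, with the individual volumes recovered from
the shared pressure.

### Baroreflex

Carotid pressure, rate-sensitized by a lead term (`τ_z`) and low-pass
filtered (`τ_p`), drives a sigmoidal afferent firing rate.  Sympathetic
activity decays exponentially with afferent firing; vagal activity rises
sigmoidally.  Seven sympathetic effectors (LV and RV contractility, the two
peripheral resistances, the two venous unstressed volumes, and the heart
period) apply a logarithmic static gain to the *delayed* sympathetic firing
and relax through first-order dynamics; an eighth, vagal, effector lengthens
the period linearly in delayed vagal firing.  Pure delays are fixed-lag ring
buffers on the integration grid, initialized at basal activity so the reflex
itself produces no artificial startup transient.  The heart period is the
sum of its intrinsic value and the two period-effector states, saturated to
[0.4 s, 1.0 s]; the upper saturation is the model's heart-rate floor of
60/min, which binds for high-function parameter sets where vagal tone
dominates.  The period is frozen within each beat and refreshed at beat
onsets to avoid phase tearing.

### LV systolic-function parameters

Four quantities describe LV systolic function and are the inverse problem's
targets:

- `E_max,lv` (mmHg/ml) — reference end-systolic elastance,
- `E_max_lv,0` (mmHg/ml) — elastance in absence of autoregulation,
- `G_Emax,lv` (mmHg/ml per spikes/s) — baroreflex contractility gain,
- `k_E,lv` (1/ml) — EDPVR steepness.

The instantaneous LV end-systolic elastance combines them as

    E(t) = E_max,lv · (E_max_lv,0 + G_Emax,lv · ln(max(f_es(t−D) − f_es,min, 0) + 1)) / E_norm

with `E_norm = 2.95 mmHg/ml`, the nominal basal elastance: at nominal
parameters and basal sympathetic tone, `E(t) = E_max,lv`.  This choice keeps
all four parameters active, makes LVEF strictly increasing in `E_max,lv`
even with reflex gains zeroed, and reduces to the classical additive
effector law at the nominal reference.  The right ventricle uses the plain
additive law.

### Numerics

Fixed-step RK4 at `dt = 2 ms`.  The ideal-diode valves make the vector
field non-smooth, so a fixed step keeps the valve-switching error bounded
and the run bit-deterministic; halving the step changes steady-cycle MSAP
by well under 0.1 mmHg, and the trajectory agrees with an adaptive RK45
reference to valve-switching accuracy.  Delayed reflex inputs are held
constant over a step (their time constants are ≥ 1.5 s, three orders above
`dt`).  A non-finite state aborts with the offending compartments and time.
The EDPVR exponent is guarded (`kE·V ≤ 50`) in the user-facing pressure
function.  The simulation protocol is 20 s with the first 10 s discarded;
`steady_state_reached` requires every cycle-to-cycle change of per-beat
mean systemic pressure in the analysis window to stay below 0.5%.  Deep
failure corners genuinely violate this within 20 s (a settling oscillation
plus the 20 s venous-tone time constant); the flag reports it honestly and
downstream analyses do not gate on it.

## Parameter provenance and calibration

The vascular, ventricular and reflex constants are transcribed from the
classical carotid-baroregulation model of the pulsating heart that this
framework builds on; they are configuration values
(`cardioinverse/data/default_config.yaml`), not code constants.  Two groups
were calibrated by forward simulation:

- **Heart-period effectors.**  The intrinsic period offset (0.55 s) and the
  sympathetic/vagal period gains (−0.26, 0.18 s per unit drive) were set so
  the sampled heart-rate distribution spans ~60–75/min with the 60/min
  floor binding at the high-function corner.
- **Sampling ranges.**  Severity is expressed primarily through
  `E_max,lv ∈ [1.0, 3.1]`, with `E_max_lv,0 ∈ [1.8, 2.392]`,
  `G_Emax,lv ∈ [0.2, 0.475]`, `k_E,lv ∈ [0.0105, 0.014]`.  The corners place
  the sampled LVEF span across ~[27%, 60%] — overt systolic failure through
  normal function.  Keeping the denervated elastance in a narrower band also
  keeps the inverse problem well-posed: because `E_max,lv` and `E_max_lv,0`
  enter the effective elastance through a product, equally wide ranges make
  the pair unidentifiable from pressures alone and bias the re-simulated
  end-systolic volume.

## Featurization

Each simulation contributes one window of SAP and one of PAP, represented
by truncated real Fourier coefficients `[a_0..a_M, b_1..b_M]` in the
convention `u(t) = a_0/2 + Σ_j a_j cos(jωt) + b_j sin(jωt)`, computed by
FFT.  Defaults: `M = 5` (11 coefficients per signal, 22 features per
sample), `n_t = 220` points over a `2.2 s` window (`Δt = 10 ms`), so the
retained 11 coefficients are the lowest 5% of the 220 real degrees of
freedom and the retained band extends to `5/2.2 ≈ 2.3 Hz` — the cardiac
fundamental and its first harmonic.

The window **starts at a beat onset** (the simulator's beat markers, or the
diastolic foot detected on measured traces).  This matters: the window must
begin at a reproducible cardiac phase, because the phase accumulated over
~20 beats varies quasi-chaotically with the parameters and otherwise
scrambles the coefficients.  A long (10 s) trailing window without
alignment was measured to cap recovery at ~3% mean relative error; the
aligned 2.2 s window reaches ~1.2%.

Features are standardized per-coefficient on the training split only.

## Inverse network

A multi-layer perceptron `22 → 16×4 → 4`, ReLU hidden activations, sigmoid
output, trained with Adam (learning rate 0.001) on the mean squared error
of min–max-scaled targets.  The sigmoid image is mapped onto the
(0.05, 0.95) sub-interval of each parameter range — keeping targets off the
saturated sigmoid tails — and the inverse map clips to the admissible
range, so predictions are always physically admissible.  Batch size 32, at
most 1000 epochs, early stopping with patience 50 on validation loss, best
validation weights returned; fan-in-scaled (He/Glorot) initialization under
a recorded seed.  The implementation is plain numpy (forward, backprop,
Adam) and is bit-deterministic for a fixed seed.

Splits: 5% of samples form the test set; the remainder is divided 80/20
into train/validation (10 000 samples → 500/7600/1900).

## Evaluation conventions

The 12 clinical variables: mean pressures are time averages over the
analysis window; systolic/diastolic values are per-beat extrema averaged
across beats (beats delimited by the simulator's beat markers);
`HR = 60 / mean(T)`; LVEDV/LVESV are per-beat extrema of LV volume;
`LVEF = 100 (LVEDV − LVESV)/LVEDV`; `CI = HR · SV / 1000 / BSA` with
`BSA = 2.0 m²`; PCWP is the time-averaged left-atrial pressure (the
standard 0D surrogate).  "Error" is the per-sample absolute difference
between the exact-parameter and predicted-parameter re-simulations;
"relative error" normalizes by the exact value; the 95% CI on the mean
error uses the normal approximation `mean ± 1.96·SD/√n`.

The sensitivity analysis perturbs one parameter at a time as
`P = P_mean (1 + ε N(0,1))` with `ε = 0.01` (default 100 draws), the others
held at their midpoints, and tabulates min/max/mean/SD of the 12 variables.
On the default configuration the spread under `G_Emax,lv` perturbation is
the smallest of the four parameters — the model is least sensitive to the
reflex gain, which is also why that parameter is recovered worst.

## What the synthetic data does and does not emulate

All data is self-generated: the generator's defaults *are* the study
conditions (uniform independent sampling of the four parameters, all other
constants fixed, 20 s deterministic simulations).  The signals are
noise-free, perfectly zeroed, uniformly sampled pressures from the same
model family that the network inverts; real arterial lines add damping,
resonance, drift, respiratory and measurement noise, and true physiology is
not spanned by four degrees of freedom.  Passing tests therefore
demonstrate internal consistency of the inverse framework — not clinical
validity, which would require patient data.

## Problem sizes

The packaged experiment sizes keep a full run on one CPU core comfortable:
the end-to-end acceptance experiment uses 2000 samples (100 test) and the
sensitivity check 30 runs per parameter; a 2000-sample generation plus
training plus double re-simulation of the test split completes in well
under two minutes thanks to the jit-compiled integrator (~50 ms per 20 s
simulation after compilation).

## Known limitations

- Right-ventricular failure, respiratory coupling (heart–lung interaction),
  coronary flow and gas transport are out of scope.
- Constants are a faithful transcription of the cited baroregulation model
  plus the documented calibrations; exact numeric agreement with any other
  implementation of that model is not claimed — the test suite asserts
  structural properties (conservation, monotonicity, convergence, recovery)
  rather than absolute values.
- The 0.5% steady-state tolerance is not met by the deepest failure corners
  within the 20 s protocol (see Numerics).
- `E_max_lv,0` and `G_Emax,lv` are only weakly identifiable from arterial
  pressures; their point estimates regress toward the conditional mean.
  This is a property of the physics (the reflex operating point exposes
  only combinations of them), not a defect of the optimizer.
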