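# Methods

This note documents the models implemented in `nanodox`, the choices made
where the design was genuinely open, and what the test suite does and does
not demonstrate.

## The system being modeled

The package simulates a closed sensing/actuation loop between an external
controller and an intra-body nanonetwork, communicating through a bio-cyber
interface:

* **Forward direction (actuation).** A 3-bit electromagnetic command selects
  a physical stimulus applied to a store of drug-loaded PEGylated liposomes
  (`011` → thermal, `111` → optical; all other codes are deliberate no-ops).
  The stimulated population releases doxorubicin (DOX) with first-order
  kinetics; the cumulative dose released during the stimulation window is
  injected into the bloodstream and propagates through a five-compartment
  pharmacokinetic model into tumor cells.
* **Reverse direction (sensing).** A bio-nanosensor releases information
  molecules that exchange between tumor intracellular space and plasma,
  bind receptors, and drive luciferase expression; the luciferase/ATP
  bioluminescence is read by a photodetector and thresholded into bits.
* **Estimation layer.** The interface identifies its own model parameters
  from observed (noisy) trajectories, either by nonlinear least squares or
  by a small neural-network surrogate trained on simulated fits.

## Forward pharmacokinetics

States (concentrations, µM-scale model units): systemic plasma `w1`, body
tissue `w3`, tumor plasma `w2`, tumor extracellular-extravascular space
(EES) `w4`, tumor intracellular space `w5`. With `w4e = w4·UDOXe` and the
shared uptake flux

    J_up = k3wi · ( k1wi·w4e + k2wi·w4e/(kiwi + w4e) − k5wi·w5 ),

the default (`mass_consistent`) right-hand side is

    dw1 = −(k12 + k10)·w1 + k21·w3
    dw3 = k12·w1 − k21·w3
    dw2 = (ps/Vp_t)·(w4·UDOXe − w2·UDOX) + Fpv_t·(w1 − w2)
    dw4 = (ps/Ve_t)·(w2·UDOX − w4·UDOXe) − J_up/Ve_t
    dw5 = J_up

Two deliberate repairs distinguish this from the `as_printed` variant, which
is retained verbatim for documentation and symbolic-fidelity tests:

1. **Transvascular sign.** As published, the permeability–surface-area (ps)
   exchange term enters the EES equation with both contributions negative,
   so `w4` starting at zero could never rise — contradicting the model's own
   qualitative behavior (EES and intracellular levels rise and then fall).
   The influx sign is flipped so the ps term is an antisymmetric exchange,
   restoring mass balance.
2. **A single uptake flux.** The published EES and intracellular equations
   group the saturable-uptake terms differently (the passive term appears
   inside the Michaelis–Menten denominator on one side only). A consistent
   mass balance requires one shared flux; the intracellular grouping
   (linear passive entry + saturable carrier + linear efflux) is adopted for
   both, applied to unbound EES drug, and divided by `Ve_t` on the EES side.

Kept as printed: the tumor does not appear in `dw1` (the tumor is a
negligible sink for the systemic pool); the ps terms divide by the
fractional volumes while the perfusion terms carry none; the unbound
fractions multiply only the transvascular terms.

Initial condition: `w1(0) = dose/VD` with all other compartments zero. When
the forward chain is driven end-to-end the dose is the released amount
`g_f`; otherwise it is the tabulated `D = 0.7` (`w1(0) = 0.007`). The
registry's `omega0` is treated as the commanded injected dose, so the
estimation and sweep layers use `w1(0) = omega0/VD`.

Integration uses LSODA with `rtol 1e-8`, `atol 1e-10` on a fixed 2001-point
output grid over [0, 2000] min. The systemic `(w1, w3)` subsystem has an
analytic biexponential solution (`two_compartment_closed_form`) used as an
independent oracle; the solver tracks it to better than 1e-6 relative.

## Parameters and units

All rates are normalized to **minutes** at load time (every transport
constant is quoted per minute; the gene-expression rates are quoted per
hour and divided by 60). Serialized profiles tag every value with a unit;
bare numbers are rejected, because silently mixed time bases are the main
failure mode of this parameter table.

Derived quantities: `Vp_t = Vv_t(1 − Hct_t)`, `BV = 0.063·rho_t`,
`Fpv_t = W0/BV`, `w1_init = D/VD`. Three constants have no tabulated
values and were fixed once as package defaults:

* `W0 = 0.02 ml·g⁻¹·min⁻¹` — representative solid-tumor perfusion; gives
  `Fpv_t ≈ 0.30 min⁻¹`, comparable to the transvascular conductance so the
  perfusion sweep probes a genuinely sensitive regime.
* `xi = 100`, `omega_R = 0.007` — so the fully-released amount
  `xi·omega_R` equals the tabulated dose `D = 0.7`; `R_IN = 60` min.

The thermal and photo release constants are the experimentally determined
stimulation rates `delta_t = 0.0078 min⁻¹` (42 °C) and
`delta_l = 1.04e-4 min⁻¹` (UV).

## Reverse signaling

Sensor kinetics: `dv1 = k21r·v2 − (k12r + k10 + k1)·v1`,
`dv2 = k12r·v1 − k21r·v2`, with `v2(0) = n0 = 8 µM`, `v1(0) = 0`. The
receptor-bound signal is `g_r = k1·v1` and the transcription factor
`m = µ·g_r` with `µ = 1`.

The luciferase expression stage is the standard two-stage activation model
with Hill-type transcription:

    dM = kr·H(m) − γr·M,   H(m) = m^h/(K^h + m^h)
    dL = kp·M − γp·L

This stage is the largest inferred component of the chain: the printed
sources give the rate constants (`kr = 10 h⁻¹`, `kp = 150 h⁻¹`,
`γr = 10.05 h⁻¹`, `γp = 4.15 h⁻¹`) but not the ODE forms, so the model is
validated only against the qualitative sensitivity trends, not
quantitatively. The Hill constants default to `h = 1` and `K = 0.01` — the
order of magnitude of the transcription-factor signal produced by the
default reverse constants (peak `m ≈ 8e-3`) — and are fully configurable.

Readout: `I = αL·L·X/(X + αM)` with ATP held constant (`X = 40`,
`αM = 15 µM`, `αL = 0.044`); the decoded bit is `1` iff normalized
`I(t) ≥ I0 = 0.7` (the boundary maps to 1).

**Normalization of the threshold scale.** Two references are supported. By
default a trajectory is normalized to its own maximum — the way readout
curves are plotted — but a real detector cannot know a trajectory's future
peak, and a self-normalized threshold is trivially reachable for any sensor
load. The sweep engine therefore calibrates the normalized scale once, at
the base configuration's peak intensity, and decodes every swept value
against that fixed absolute threshold (`norm_ref` in `simulate_reverse`).
Under this calibration the threshold first-crossing time is nonincreasing
in `n0` (a larger load reaches the absolute level sooner), the default
`n0 = 8 µM` crosses at ≈ 25 min, and loads below ~0.5× the default never
cross — consistent with the design premise that a sufficient sensor load is
needed to raise the interface.

## Estimation

**NLS.** `NLSTrajectoryEstimator` minimizes the sum of squared deviations
between the simulated observable (tumor plasma `w2` forward, raw intensity
`I` reverse) and the observed series over the free parameters within
bounds (trust-region reflective least squares). Defaults: free parameters
`(k12, k21, k10, omega0)` forward and `(k12r, k21r, k1, n0)` reverse — the
sensitive knobs probed by the sensitivity sweeps; `M = 50` observation
times on [0, 2000] min; bounds a factor 10 around the registry values. The
finite-difference jacobian uses a relative step of `1e-6`, well above the
ODE tolerance floor, which is what lets noiseless recovery reach ~1e-7
relative error.

**Surrogate.** A single-hidden-layer perceptron: 10 log-sigmoid hidden
units, identity output, features (the noisy trajectory samples) and labels
(parameters) min-max scaled to [0, 1], trained by L-BFGS with an L2 weight
penalty `λ = 1e-3` (sum-of-squared-errors plus `λ·Σw²`, the
Bayesian-regularization objective family; full evidence maximization of
`λ` is out of scope). Training labels are the *NLS estimates*, so the
surrogate learns to reproduce the fitting map at a fraction of its cost;
`scikit-learn` provides the optimizer, while the stored-weight forward
pass used at inference is implemented in-package and cross-checked against
an independent matrix computation. Training sets are generated by sampling
true parameters uniformly in 0.5×–2× of the defaults, simulating, adding
zero-mean Gaussian noise of variance 0.05, and fitting each scenario; every
stage takes an explicit seed and there is no global random state.

**A note on identifiability at the stated noise level.** With the tabulated
dose, the forward observable `w2` peaks near 4e-3 µM while the stated
measurement noise has σ ≈ 0.22 µM. At that signal-to-noise ratio the
individual rate constants are not recoverable to within 10% — a Fisher
information calculation over the 50-point grid bounds even the
best-identified parameter above 30% relative error, and `k21 = 7.052e-5`
contributes less than 0.5% of the observable under any reading of the
initial condition. The recovery experiment is still run at exactly these
conditions and its measured medians are reported; the corresponding
acceptance test documents the contract rather than relaxing it. The
noiseless experiment, by contrast, recovers all four parameters to better
than 1e-4 relative, and the surrogate-vs-NLS comparison is meaningful at
any noise level because both estimators face the same data.

## What the synthetic scenarios do and do not show

All fixtures are generated in-package by the simulators themselves, under
the study conditions above (tabulated parameter defaults, uniform 0.5×–2×
scenario sampling, additive Gaussian noise of variance 0.05). Passing tests
therefore demonstrate internal consistency — solver-vs-oracle agreement,
conservation, calculus identities, qualitative sensitivity directions, and
estimator behavior on data the model itself generated. They do not
demonstrate fidelity to real pharmacokinetic measurements: real DOX data
exhibit inter-subject variability, non-Gaussian and state-dependent
measurement error, spatial heterogeneity in the tumor (explicitly out of
scope: no PDE diffusion, no pharmacodynamic cell-kill stage), and a
bioluminescence pathway whose expression-stage constants are borrowed
rather than jointly measured.

## Numerical choices and degenerate inputs

* LSODA with `rtol 1e-8 / atol 1e-10` for headline simulations; batch
  fitting uses `rtol 1e-6 / atol 1e-8` (errors far below noise).
* The closed-form biexponential falls back to a matrix exponential in the
  measure-zero defective (repeated-eigenvalue) corner.
* `cumulative_release` uses `expm1` to stay accurate for short windows.
* Unmapped 3-bit commands are a physical no-op, not an error; malformed
  command strings are errors.
* Sweep trend checks compare the full metric sequence with a 1e-9 slack
  and require a strict endpoint difference; never-crossed thresholds are
  `+inf` so crossing-time monotonicity is well defined on the extended
  reals.
* Zero sensor load (`n0 = 0`) yields identically zero intensity and an
  all-zero bit stream; degenerate min-max bounds and constant-feature
  training sets are configuration errors.
* The k12 sweep asserts only the rise-then-fall shape of the tumor
  compartments: raising `k12` shunts drug from plasma into body tissue, so
  its effect on tumor exposure is negative — the narrative description of
  that panel contradicts the equations, and the equations win.

## Known limitations

* The wireless segment of the loop is an identity channel by assumption;
  hardware, injection mechanics, and logic-gate electronics beyond the
  3-bit decoder are out of scope.
* One bio-nanosensor, one tumor site; no multi-sensor aggregation.
* The gene-expression stage's functional form is inferred (see above); its
  constants enter only the reverse direction.
* The surrogate is a fixed-architecture regression on one observation
  grid; it does not quantify uncertainty beyond held-out RMSE.
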