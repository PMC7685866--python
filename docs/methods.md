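# Methods

## Model

Five neural-mass populations — cortical pyramidal cells (PY), fast and
slow inhibitory interneurons (I1, I2) forming a disinhibition circuit,
thalamic relay nucleus (TC), and thalamic reticular nucleus (RE) — evolve
by first-order relaxation toward their external input levels `h`, coupled
through two transfer functions: the steep sigmoid
`f(x) = 1/(1 + ε^(−x))` (default base ε = 2.5·10⁵, so ln ε ≈ 12.4 and the
transfer is close to a smooth switch) and the affine map
`g(y) = a·y + b` (a = 2.8, b = 0.5) for thalamic outputs. Thalamus excites
cortex both directly (TC→PY, strength `C7`) and through feedforward
inhibition onto the interneurons (`C11`, `C12`). `C7` is the model's proxy
for impaired astrocytic glutamate uptake: weaker uptake means more
glutamate reaching cortical receptors, i.e. larger `C7`. Stimulation
inputs `u1` (to RE) and `u2` (to TC) enter additively inside the
time-scale bracket of their population's equation, so an input of size A
perturbs the derivative by σ·A.

Two structural points are deliberate and load-bearing:

* each σ multiplies the population's *entire* bracket, stimulus included;
* the relay output enters the cortex through `f(TC)` but the thalamic
  cross-couplings use `g(TC)` and `g(RE)`. This asymmetry is kept exactly
  as in the parent model family.

Both choices are validated by the bifurcation skeleton they produce on the
C7 axis (below).

Time is in seconds: the σ values are per-second rates, and dominant
frequencies of the simulated cortical mean land directly in the physiological
bands (2–4 Hz spike-wave, >10 Hz tonic), which fixes the unit
interpretation.

## Integration

Classic fixed-step RK4 at dt = 1 ms over 30 s from the all-zero initial
state. These are not merely numerical defaults: the regime boundaries of
the bistable windows are *defined* relative to this initial condition, so
sweeps never warm-start from neighbouring parameter values. The stimulus
is evaluated analytically at t, t + dt/2 and t + dt (not sample-and-hold),
so pulse trains present their true on/off pattern to the integrator at the
grid resolution. The inner loop is numba-compiled (~7 ms per 30 s run),
which is what makes dense plane sweeps affordable. A non-finite state
aborts the run with an error naming the failure time; saturated states of
this model are finite, so divergence always indicates a defect, and
clipping would hide it.

Step-size checks: the decoupled (all couplings zero) system has the closed
form s·exp(−σt) and the integrator matches it to <1e−8 at 1 ms with the
expected O(dt⁴) error scaling; in a regular regime (C7 = 1) halving the
step changes the 30 s endpoint by <1e−6 relative.

## Signal analysis and state classification

All analysis runs on the cortical mean (PY + I1 + I2)/3. Unstimulated runs
discard the first 5 s; stimulated runs analyze from 5 s past stimulus
onset. The dominant frequency is the maximum of the mean-removed power
spectrum (DC excluded), zero-padded to ≤0.05 Hz bin spacing, ties broken
toward the lower frequency. A signal whose peak-to-trough amplitude is
below 0.01 counts as steady and reports frequency 0.

The six-state classifier:

1. amplitude < 0.01 → saturated; high vs low by mean level against a
   threshold calibrated once as the midpoint of the equilibrium cortical
   means of the canonical high-saturated (C7 = 6) and low-saturated
   (C7 = 1) regimes at C11 = 0.1 (the saturation levels themselves are not
   tabulated anywhere, so the package computes them from its own
   equilibria);
2. dominant frequency > 10 Hz → tonic (IV);
3. 5–10 Hz → high-frequency clonic (VI);
4. below 5 Hz → spike-wave discharge (III) if the waveform carries ≥ 2
   prominence-filtered local maxima per fundamental period (prominence
   ≥ 10 % of the amplitude), else low-frequency clonic (V). The morphological
   rule encodes the defining feature of a spike-wave cycle — a
   spike peak plus a wave peak — and is the one place where the
   classification is a reconstruction rather than a band rule; the
   prominence fraction and band edges are arguments, not constants.

Two known artifacts of these rules, kept because the rules themselves are
the documented contract: near the SWD/clonic border the second harmonic of
a spike-wave cycle can out-power the fundamental, flipping the dominant
frequency to ~6.5 Hz and the label to VI for isolated parameter cells; and
just past a bifurcation point where the equilibrium is only weakly
attracting, the 5 s-discard window still contains slowly decaying ringing,
so cells very close to a boundary can classify as oscillatory.

## Bifurcation machinery

Equilibria are found by multi-start Newton iteration (3⁵-lattice over
[−6, 4]⁵ plus 60 seeded random starts), accepted only when the vector-field
residual is below 1e−9, and merged at 1e−6. Acceptance is by residual, not
by the root-finder's own status flag, which can report failure on a fully
converged root. Stability comes from the analytic Jacobian (checked against
central finite differences at 1e−4 relative).

Hopf points: warm-started equilibrium tracking along the axis (101 scan
points by default, full re-seeding every 20 steps to catch branches that
appear mid-range), watching the real part of the leading complex
eigenvalue pair; sign changes are bisected to 1e−4 in the parameter.
Sub/supercritical classification is by a simulation probe 0.02 past the
crossing on the unstable side, from the equilibrium perturbed by 0.05: a
settled amplitude under 0.1 indicates a small cycle born at the Hopf
(supercritical), a larger one a jump to a pre-existing cycle
(subcritical). The probe perturbation must be large enough to escape the
near-zero linear growth rate within the 30 s probe window — a 1e−3
perturbation demonstrably is not — yet small enough not to jump the basin
of a small supercritical cycle.

Folds of limit cycles are not continued. Instead, oscillation boundaries
are located by simulating from the zero initial state on a parameter grid
(30 s, first 10 s discarded, oscillation flag = peak-to-trough > 0.01) and
bisecting each flag switch to 0.005. In this model's bistable windows the
zero state lies on the limit-cycle side of the separatrix, so these
switches approximate the fold-of-cycle boundaries of the oscillatory
windows. Full limit-cycle continuation (and period-doubling detection)
is out of scope.

Computed skeleton on the C7 axis at C11 = 0.1 (standard parameters
otherwise): supercritical Hopf at 0.2387, subcritical Hopf at 2.1508,
subcritical Hopf at 3.4672; oscillation onset at 1.678 and offset at
5.045. On the constant-RE-input axis at C7 = 2 the leading pair crosses at
A ≈ −0.5196 (subcritical) and again at −0.0846.

## Stimulation protocols

* **Sustained step** (`StepPulse`): 0 before onset (default t = 10 s), A
  afterwards. The sustained reading — rather than a transient blip — is
  what makes A a meaningful continuation parameter of the stimulated
  system and is consistent with post-stimulus states that are not
  attractors of the unstimulated model; a finite `duration` option covers
  the transient variant.
* **DBS** (`DBSTrain`): A·H(sin(2πt/p))·(1 − H(sin(2π(t+δ)/p))), high for
  a width-δ window once per period p (default p = 0.1 s). Heaviside
  convention H(0) = 1; at 1 ms sampling the convention touches only a
  measure-zero set of grid points.
* **3:2 CRS** (`CoordinatedReset`): 100 Hz pulse cycles of width 1 ms,
  organized in repeating blocks of five cycles — three delivering a pulse,
  two silent — applied simultaneously to RE (amplitude `A_re`) and TC
  (`A_tc`) from t = 10 s. The block structure (`n_on`, `n_off`) and a
  per-target cycle offset are exposed because the waveform is a
  reconstruction: the block pattern, per-target phasing, and whether the
  targets alternate are genuinely open, and alternative readings can be
  expressed through the arguments.

Current consumption of a delivered stimulus is ‖(u1, u2)‖₂ / N over the N
grid samples of both channels stacked.

## Stimulation-efficacy metric

η = (N1 − N2)/N1 counts the (C7, C11) grid cells labelled SWD before (N1)
and after (N2) a protocol. The packaged efficacy grid is C7 ∈ [1.6, 2.4]
(33 points) × C11 ∈ [0, 0.4] (17 points): it covers the SWD-bearing region
of the unstimulated plane with 153 SWD cells, resolving η changes below
1 %. Measured trends under the default CRS reconstruction: positive-RE /
negative-TC intensity pairs *increase* the SWD area (η = −0.05, −0.09,
−0.57 at |A| = 0.2, 0.4, 0.7) — consistent with the stimulated-system
continuation, where a small positive RE input widens the oscillatory
regime — while the reversed polarity clears part of it without a monotone
intensity trend (η = +0.12, +0.21, +0.15). The effective mean drive of the
reconstructed CRS waveform is only ≈ 0.06·A, an order of magnitude below
the sustained-input level that switches regimes in this model, so large
suppression fractions are not reachable under this reconstruction; the
acceptance suite asserts the monotone-improvement hypothesis as stated and
the two η-monotonicity checks fail under the defaults, which is the
package's measured result, not a tolerance choice. Current consumption
grows with amplitude by construction.

## What the bundled experiments do and do not show

All validation inputs are generated by the simulator itself at the
standard parameter set; there is no recorded EEG anywhere in the loop.
Passing tests therefore demonstrate internal consistency of the model,
integrator, classifier, and continuation machinery — e.g. that the Hopf
skeleton, frequency bands, and regime labels agree across independent
routes (eigenvalue analysis vs simulation, analytic vs finite-difference
Jacobian, closed-form vs integrated trajectories) — not that the model
describes any particular patient's EEG. The classifier's band edges and
morphology rule are tuned to this model's waveforms and are not a general
EEG scorer.

## Known limitations

* No stochastic forcing; all runs are deterministic.
* No limit-cycle continuation: fold-of-cycle locations are
  initial-condition-dependent approximations, and period-doubling points
  are not detected.
* The DBS and CRS waveforms at their default settings deliver weak
  time-averaged drive; conclusions about strong-stimulation regimes
  require raising amplitude, width, or duty cycle explicitly.
* Astrocyte dysfunction appears only through the coupling `C7`; there are
  no astrocyte state variables.
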