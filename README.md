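# thalcort

A thalamocortical neural-mass model of epileptic rhythms: simulation,
electrical-stimulation protocols, firing-state classification, and
bifurcation analysis.

## The scientific problem

Absence epilepsy is characterized by 2–4 Hz spike-wave discharges (SWD) in
the EEG; tonic seizures show high-frequency low-amplitude activity, clonic
seizures slow high-amplitude waves. A long-standing line of modelling work
describes these rhythms with small systems of coupled neural-mass ODEs for
the cortico-thalamic loop. `thalcort` implements a five-population variant
with a cortical disinhibition circuit (two inhibitory interneuron
populations with different time scales) and feedforward inhibition from
thalamus to cortex, in which the thalamus→cortex excitatory coupling
strength `C7` serves as a proxy for impaired astrocytic glutamate uptake.
The package is for modellers who want to reproduce and probe this circuit's
regime structure and its response to stimulation, at desk scale.

## The model

Populations: cortical pyramidal cells (PY), two inhibitory interneuron
populations (I1, I2), thalamic relay nucleus (TC), thalamic reticular
nucleus (RE). With the sigmoid transfer f(x) = 1/(1 + ε^(−x)) for cortical
and relay outputs and the affine transfer g(y) = a·y + b for thalamic
outputs:

    PY' = σ1 (h_PY − PY + C1 f(PY) − C3 f(I1) + C9 f(TC) − C_iny f(I2))
    I1' = σ2 (h_I1 − I1 + C2 f(PY) − C_in1 f(I2) + C11 f(TC))
    I2' = σ3 (h_I2 − I2 + C10 f(PY) − C_in2 f(I1) + C12 f(TC))
    TC' = σ4 (h_TC − TC − C6 g(RE) + C7 f(PY) + u2(t))
    RE' = σ5 (h_RE − RE − C4 g(RE) + C5 g(TC) + C8 f(PY) + u1(t))

u1 and u2 are stimulation inputs to RE and TC. Time is in seconds; the
EEG surrogate is the cortical mean (PY + I1 + I2)/3. Integration is
fixed-step RK4 (default 30 s at 1 ms) from the zero initial state.

The package provides:

* `thalcort.model` — parameters, transfer functions, vector field,
  analytic Jacobian;
* `thalcort.stimulation` — sustained step ("single-pulse"), DBS pulse
  trains, 3:2 coordinated reset (CRS), and the current-consumption index;
* `thalcort.simulate` — the compiled RK4 integrator;
* `thalcort.analysis` — dominant frequency, stable extrema, the six-state
  classifier (high/low saturated, SWD, tonic, low/high-frequency clonic),
  1-D bifurcation scans, 2-D state maps, and the SWD-reduction metric η;
* `thalcort.continuation` — equilibrium tracking, Hopf detection with
  sub/supercritical classification, and simulation-based oscillation
  boundaries;
* `thalcort.cli` — a `thalcort` command with `simulate`, `sweep`, `plane`,
  `continue`, `stimulate`, and `scenario` subcommands.

## Worked example

Simulate the spike-wave regime and classify it:

```bash
$ thalcort simulate --C7 2 --C11 0.1 --out out/swd
III  f=3.23 Hz  amplitude=0.2150
```

The label `III` is the spike-wave discharge state; 3.23 Hz is the dominant
frequency of the cortical mean over the post-transient window (inside the
2–4 Hz absence band), and 0.2150 is its peak-to-trough amplitude. The same
from Python, together with the bifurcation structure that explains it:

```python
from thalcort import (ModelParameters, SimulationConfig, integrate,
                      cortical_mean, classify_state, detect_hopf)

cfg = SimulationConfig(params=ModelParameters(C7=2.0, C11=0.1))
report = classify_state(cortical_mean(integrate(cfg)), fs=1000.0, discard=5.0)
print(report.label.roman, round(report.dominant_frequency, 2))   # III 3.23

for p in detect_hopf("C7", (0.0, 1.0), ModelParameters(C11=0.1)):
    print(p.kind.value, round(p.location, 3))   # hopf_super 0.239
```

The Hopf point at C7 ≈ 0.239 is where the tonic limit cycle of the
low-coupling regime gives way to the quiescent low-saturated state; two
further Hopf points near 2.151 and 3.467 and oscillation boundaries near
1.68 and 5.04 delimit the bistable SWD windows (see `docs/methods.md`).

Scenario presets rerun entire experiments, e.g. a C7 bifurcation scan or
the (C7, C11) state plane:

```bash
thalcort scenario fig2b --out out
thalcort scenario fig4 --grid 17 --out out
```

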