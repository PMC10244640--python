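# chanfire

**Neuron-type dependent firing consequences of ion-channel alterations.**

Ion-channel mutations (channelopathies) are routinely classified as loss or
gain of function (LOF/GOF) at the level of the ionic current. Whether a
current-level LOF also means *less firing* depends on the neuron type — on
the other channels the neuron expresses. `chanfire` is a simulation
pipeline for studying exactly that dependence:

* a **model zoo** of twelve single-compartment conductance-based neuron
  models (cortical regular-spiking/fast-spiking cells, cerebellar stellate
  cells and subthalamic-nucleus cells, each with Kv1.1-extended and
  Kv1.1-swap variants), integrated with fixed-step forward Euler
  (Δt = 0.01 ms) via a compiled numba kernel;
* a **firing characterization** that separates sub-threshold excitability
  from supra-threshold gain: the rheobase (smallest current eliciting an
  action potential, refined to 0.05 pA) and the AUC of the steady-state
  frequency–current (fI) curve over a fixed window above the onset of
  repetitive firing,

      AUC = ∫ f(I) dI  over  [I_onset, I_onset + I_max/5]   (trapezoidal);

* a **one-factor-at-a-time sensitivity analysis**: half-activation shifts
  ΔV½ ∈ [−10, +10] mV, slope-factor and maximal-conductance scalings over
  log2-spaced factors in [0.5, 2], summarized per model and alteration by
  the Kendall rank correlation τ between alteration magnitude and
  ΔRheobase or normalized ΔAUC = (AUC_i − AUC_wt)/AUC_wt;
* a **heterozygous Kv1.1 mutation-panel analysis**: mutation effects
  (relative amplitude, relative activation slope, activation V½ shift)
  applied to half of the Kv1.1 (and A-type) channels, firing changes
  classified into GOF/LOF/ambiguous quadrants of the
  (ΔRheobase, normalized ΔAUC) plane, and cross-model consistency measured
  by pairwise Kendall correlations.

It is intended for computational neuroscientists and channelopathy
researchers who want to screen how a given channel alteration plays out
across different ionic-current environments.

## Worked example

```python
from chanfire import NeuronSimulator, build_model, characterize, reduced_protocol

sim = NeuronSimulator(build_model("H"))      # RS pyramidal + Kv1.1
m = characterize(sim, reduced_protocol(), need=("rheobase", "auc"))
print(f"rheobase {m.rheobase_pa:.1f} pA, onset {m.ss_onset_pa:.1f} pA, "
      f"AUC {m.auc:.0f} Hz*pA")
```

prints

```
rheobase 205.0 pA, onset 283.2 pA, AUC 7334 Hz*pA
```

— model H needs 205 pA to spike at all, fires repetitively from 283 pA
upward, and accumulates 7334 Hz·pA of firing over the 200 pA window above
that onset (the AUC proxies the initial steepness of its fI curve). The
`examples/` directory holds one short narrative script per capability
(model characterization, sensitivity sweep, mutation panel, and the
closed-form oracle validating the measurement pipeline), and the `chanfire`
command-line tool exposes the same stages as CSV-writing subcommands
(`characterize`, `sensitivity`, `mutations`, `fixtures`).

A typical sensitivity result (`examples/sensitivity_sweep.py`):

```
model_id current          property  tau_rheobase  n_used  n_excluded
       A      Na conductance_scale          -1.0       7           2
       A    Leak conductance_scale           1.0       9           0
       H      Na conductance_scale          -1.0       9           0
       H    Leak conductance_scale           1.0       9           0
```

— rheobase falls monotonically with sodium conductance (τ = −1) and rises
monotonically with leak conductance (τ = +1) in every model; alterations
that silence a model are excluded and counted, never hidden.

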