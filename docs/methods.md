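# Methods

## The question the package addresses

Clinically observed ion-channel mutations are usually classified as loss or
gain of function (LOF/GOF) at the level of the ionic current. Whether that
classification carries over to *firing* depends on the neuron type — on the
other currents the neuron expresses. `chanfire` implements an in-silico
version of that question: a zoo of single-compartment conductance-based
models spanning several neuron types, a firing characterization that
separates sub-threshold excitability (rheobase) from supra-threshold gain
(fI-curve AUC), a one-factor-at-a-time sensitivity analysis summarized by
Kendall rank correlations, and a heterozygous Kv1.1 mutation-panel analysis
with LOF/GOF quadrant classification.

## Model zoo

Twelve single-compartment models (letters A–L) in three families:

* **Cortical family** — regular-spiking inhibitory (B), fast-spiking (C) and
  regular-spiking pyramidal (D) neurons in the minimal Hodgkin–Huxley
  formulation with I_Na, I_Kd, a slow M-type K⁺ current and leak, plus
  Kv1.1-extended variants (E, G, H, in which 10 % of the delayed-rectifier
  conductance is replaced by Kv1.1).
* **Cerebellar stellate family** — I_Na, I_Kd, a large A-type K⁺ current,
  a small T-type Ca²⁺ current and leak (A), with Kv1.1 added (F) or
  replacing the A-type current (J).
* **STN family** — subthalamic-nucleus-style models with I_Na, I_Kd, A-type,
  L-type and T-type Ca²⁺ currents, a Ca²⁺-activated K⁺ current fed by a
  first-order intracellular calcium pool, and leak (L), with Kv1.1 added (I)
  or replacing the A-type current (K).

Maximal conductances, M-current maximal time constants and capacitances are
the published cell-property table values, audited programmatically in the
test suite. **Units:** conductances are surface densities (mS/cm²) and C_m
is whole-cell capacitance in pF at a specific capacitance of 1 µF/cm², so
the membrane area is `C_m · 1e-6 cm²` and an injected current I in pA is the
density `I / C_m` µA/cm². This reading is fixed by the source models the
table derives from (e.g. C_m = 118.44 pF is exactly 1 µF/cm² times the
classical cortical-model soma area, and the STN conductances match the
canonical STN model in mS/cm²); with it, `dV/dt = I_density − Σ g·x·(V−E)`
needs no conversion factors.

## Gating

Each gate `x` relaxes as `dx/dt = (x∞(V) − x)/τ(V)` and multiplies its
current as `x^p`.

* Kv1.1, M, and the stellate/STN gates use the modified Boltzmann

      x∞(V) = ((1 − a) / (1 + exp[(V − V½)/k]) + a)^j ,

  with signed slope factor k (negative for activation), exponent j ≥ 1 (the
  fit absorbs the classical gate power, so p = 1) and persistent fraction a
  (Kv1.1 inactivation has a = 0.245 — a quarter of the current never
  inactivates). Kv1.1 steady-state parameters are the published wild-type
  fits.
* The cortical-family Na/Kd gates use the classical α/β rate equations with
  the family's threshold parameter VT and their classical powers (m³h, n⁴).
  The published modified-Boltzmann fits of these curves are kept as the
  *anchors* for alterations and reporting. Simulating this family from the
  Boltzmann fits instead is not dynamically viable: the fitted Na-activation
  tail (k ≈ −8.2, j ≈ 1.42) is orders of magnitude above the m³ tail at
  sub-threshold voltages and leaves the models with no resting state below
  −30 mV (they depolarization-block at rest). The persistent fraction of
  the Na-inactivation *fit* (a = 0.05) is likewise treated as an artifact of
  the Boltzmann parameterization and not applied to the rate curves — with
  it, the fast-spiking model blocks at all inputs.

**Alteration semantics** (uniform across gate kinds): a half-activation
shift Δ translates the steady-state curve *and* its time-constant curve
along the voltage axis; a slope scaling s stretches the steady-state curve
about its (shifted) midpoint — for a Boltzmann gate exactly multiplication
of k, sign preserved — leaving τ untouched. Both compose (two +5 mV shifts
equal one +10 mV shift) and are carried as explicit `ss_shift`/`ss_stretch`
fields so a spec documents its own perturbation history.

**Reconstructed kinetics.** The tabulated parameter set for this model zoo
pins steady states and conductances but not time constants, reversal
potentials, or the stellate/STN gating curves; those live in the original
formulations of the source neuron models. This
package reconstructs them in the style of those sources (rate-equation taus
for the cortical family; bell/sigmoid taus and Boltzmann steady states for
the stellate/STN families; E_Na +50…+60 mV, E_K −80…−90 mV, leak reversals
per family; Kv1.1 activation τ ≈ 0.5–4.5 ms peaking near −35 mV and slow,
partially persistent inactivation, τ ≈ 0.3–1.8 s). Free parameters were set
once so that every model rests stably, fires tonically within its stimulus
range, model B depolarization-blocks near the top of its range, and the
STN models are not spontaneous pacemakers. Two Otsuka-style details are
deliberately simplified: the L-type Ca²⁺ current omits calcium-dependent
inactivation and deactivates quickly below spike voltages (without this the
inter-spike interval is dominated by a CaL/Kd standoff tens of µA/cm² large
and the fI curve is nearly flat), and the calcium pool is first-order with
Nernstian E_Ca.

## Integration

Fixed-step forward Euler at Δt = 0.01 ms (deliberately matching the study
design rather than an adaptive solver; a Δt-refinement test quantifies the
discretization error instead — halving Δt moves inter-spike voltages by
< 0.5 mV). Gates stay in [0, 1] by construction (Δt ≪ τ everywhere; the
fastest τ is ≥ 0.05 ms). |V| > 200 mV aborts with an integration-failure
error naming the model. Model specs compile to packed parameter arrays
consumed by a single numba kernel; compilation merges currents with
identical reversal and gating (summing conductances) and de-duplicates
identical gates, which makes an unmutated heterozygous split bit-identical
to the unsplit model. Voltage-dependent steady states and time constants
are tabulated per compiled gate on a 0.05 mV grid over [−150, 100] mV
(alteration shifts/stretches baked in at compile time) and linearly
interpolated inside the kernel; the grid is ≥ 40× finer than the steepest
sigmoid scale in the zoo, and the interpolation error is far below the
forward-Euler discretization error the Δt-refinement test bounds.

Zero-input settling integrates from `V = E_leak` (gates at steady state)
in 500 ms blocks until a block's voltage range falls below 0.01 mV
(maximum 3 s, 2 s at the reduced scale); spontaneously oscillating models
are flagged as limit cycles rather than failed. One settled state per model
is reused for all stimulus amplitudes.

## Firing characterization

* **Spike detection** — voltage peaks with ≥ 50 mV topographic prominence
  and ≥ 1 ms separation (`scipy.signal.find_peaks`; of any closer pair the
  higher peak is kept, which at 0.01 ms resolution is indistinguishable from
  keeping the more prominent).
* **Steady-state rate** — mean of reciprocal inter-spike intervals in a
  500 ms window anchored at the first spike of the last second of the step
  (last half at the reduced scale); fewer than two spikes in the window is
  silence. The mean-of-reciprocals is exact for periodic trains and
  insensitive to the window phase.
* **Coarse fI curve** — equidistant current steps spanning (0, I_max]:
  200 × 2 s at the full scale (5 pA steps for 0–1 nA; 1.75 pA for the
  0–0.35 nA models), 50 × 1 s at the reduced scale.
* **Rheobase** — 100 equidistant substeps across the coarse interval
  preceding the first spiking step; the lowest substep with ≥ 1 action
  potential (full-scale resolution 0.05 / 0.0175 pA). The search ascends
  and integration stops at the first detected spike.
* **AUC** — the onset of *steady* firing is refined the same way; a
  100-point fine fI curve then spans one fifth of the stimulus range from
  that onset, and the AUC is its composite trapezoidal integral (Hz·pA).
* **Ramp hysteresis** — stimulus at the first spike of a symmetric
  triangular ramp (ascending threshold) and at its last spike (descending
  offset); reported but never used as rheobase.
* **Bursting** — steady-window ISI trains with ≥ 4 spikes and
  max(ISI)/min(ISI) > 4 are flagged; characterizations with > 20 % bursty
  fine-fI points are excluded from summaries with their reason recorded
  (thresholds configurable; nothing is silently dropped).
* **Quadrants** — a firing change (ΔRheobase, normalized ΔAUC) is GOF when
  rheobase falls and AUC rises, LOF for the opposite, ambiguous in the two
  mixed quadrants; |Δ| ≤ 1e-9 counts as unchanged on that axis.

"Steady state firing" requires at least two spikes in the window (an ISI
must exist) — a single spike defines the rheobase but not a rate.

## Sensitivity analysis

Half-activation shifts sweep −10…+10 mV in 1 mV steps (21 values; 9 at the
desk scale); slope factors and maximal conductances sweep 21 (or 9) factors
log2-equispaced in [0.5, 2], the midpoint exactly 1. Swept targets are the
current properties shared across the zoo (Na activation/inactivation, Kd
activation, Kv1.1 and A-type activation/inactivation, and all maximal
conductances; leak has only a conductance). Contrasts are
`normalized ΔAUC = (AUC_i − AUC_wt)/AUC_wt` and `ΔRheobase = rheo_i −
rheo_wt`; the identity grid point short-circuits to the wild-type metrics,
which deterministic recomputation reproduces exactly (tested). Kendall τ
(tau-b, tie-corrected, via `scipy.stats.kendalltau`; an exhaustive
pair-count oracle cross-checks it in the tests) is computed against the
alteration magnitude on its natural axis (mV, or log2 factor — immaterial,
since τ is invariant under monotone transforms), with excluded points
dropped pairwise and counted. Combinations a model lacks are marked
inapplicable, never zero.

## Mutation panels

A mutation is (relative amplitude, relative activation slope factor,
absolute activation V½ shift). Heterozygosity splits the Kv1.1 conductance
into equal halves and applies the effects to one half (amplitude as
conductance scaling — proportional at fixed driving force); when the model
also carries an A-type current the same effects are applied to half of it.
Inactivation parameters stay wild type (the descriptors cover activation
only). Models without Kv1.1 are inapplicable by default (configurable).
Cross-model consistency of a panel is summarized by pairwise Kendall
correlations between the per-mutation effect vectors of two models
(symmetric matrices, unit diagonal, control row excluded).

## Synthetic fixtures

The generator module supplies every test input: analytic pseudo-neurons
with closed-form fI curves (type-I square-root, optionally a type-II onset
jump) that emit periodic synthetic spike trains instead of integrating
ODEs — so metric-layer tests are exact up to one fine current substep and
the 1/(500 ms) window quantization; voltage traces with planted
spike-shaped transients of known prominence (seeded Gaussian noise
optional); and seeded mutation panels emulating the *structure* of
published episodic-ataxia Kv1.1 measurements — LOF-dominated amplitudes
uniform in [0.1, 1], slope factors log2-symmetric in [0.5, 2], activation
shifts uniform in [−10, +30] mV (mostly depolarizing), with the identity
control always prepended. The fixtures are not fit to any real
electrophysiology; passing tests certify the pipeline's arithmetic and the
models' qualitative behavior, not quantitative agreement with biological
recordings.

## Problem sizes and protocol scales

The full protocol (200 × 2 s steps, 21-point grids, 2 s + 2 s ramps)
reproduces the study design exactly and is the default for the CLI's
`--scale full`. Tests and the acceptance script run the *reduced* protocol —
1 s steps with the steady window in the last 500 ms, 50 coarse currents,
9-point grids, 1 s + 1 s ramps, Δt unchanged at 0.01 ms and both 100-substep
refinements retained — which keeps a full directional-claim sweep at a few
minutes per model set. Both the acceptance tests and the
acceptance script sweep the full per-claim model sets at this scale.

## Known limitations and deviations

* The reconstructed kinetics reproduce the qualitative phenomenology
  (tonic firing, type-I/II variety, model B's depolarization block, the
  directional τ claims) but not the original models' quantitative rheobases
  or rates; no claim is made at that level.
* **Model E** (RS inhibitory + Kv1.1) responds to Kv1.1 activation
  alterations with the direct current-level sign (AUC falls as the slope
  factor grows, rises with depolarizing V½ shifts) instead of the
  fI-reshaping sign shown by the other six Kv1.1 models. The family
  threshold parameter VT controls both this and model B's depolarization
  block, in opposite directions; B's block (a structural claim) was kept.
  The corresponding per-model acceptance assertions fail for E and are left
  failing. Model F's V½-shift correlation is −0.79 — the right direction but
  marginally outside the ±0.15 acceptance band (a single local
  non-monotonicity on the 9-point grid).
* The ramp-hysteresis ranking places the M-current adaptation of models C/D
  at the top rather than the Kv1.1-swap models I and K (J does rank in the
  top three); the corresponding acceptance assertion is left failing.
* Morphology, synaptic input, channel noise, temperature scaling, subunit
  stoichiometry and time-constant *variation* (as an alteration axis) are
  out of scope.
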