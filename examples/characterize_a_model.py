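"""Characterize the firing of one neuron model.

Builds the RS pyramidal +Kv1.1 model (H), settles it at zero input, and
measures its rheobase, steady-firing onset, fI-curve AUC and ramp
hysteresis at the desk-scale protocol.
"""

from chanfire import NeuronSimulator, build_model, characterize, reduced_protocol

spec = build_model("H")
proto = reduced_protocol()
sim = NeuronSimulator(spec)
rest = sim.settle()

m = characterize(sim, proto, need=("rheobase", "auc", "hysteresis"))

print(f"model {spec.model_id} ({spec.label}), resting at {rest.v_rest:.1f} mV")
print(f"  rheobase:            {m.rheobase_pa:8.2f} pA")
print(f"  steady-firing onset: {m.ss_onset_pa:8.2f} pA")
print(f"  fI-curve AUC:        {m.auc:8.1f} Hz*pA over "
      f"[onset, onset + {proto.auc_fraction * spec.i_max_pa:.0f} pA]")
if m.hysteresis_pa:
    on, off = m.hysteresis_pa
    print(f"  ramp on/off:         {on:8.1f} / {off:.1f} pA")

# The rheobase is the smallest current eliciting any action potential (to
# 0.2 pA resolution here); the AUC integrates the steady-state firing rate
# over a fixed window above the onset of repetitive firing and serves as a
# rheobase-independent measure of the initial fI-curve steepness.
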