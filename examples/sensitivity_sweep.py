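"""One-factor-at-a-time sensitivity of firing to channel alterations.

Scales the sodium and leak maximal conductances of two models over nine
log2-spaced factors in [0.5, 2] and summarizes how rheobase follows each
alteration with a Kendall rank correlation.
"""

from chanfire import AlterationGrid, factor_grid, reduced_protocol, run_oat

grids = [
    AlterationGrid("Na", "conductance_scale", factor_grid(9)),
    AlterationGrid("Leak", "conductance_scale", factor_grid(9)),
]
result = run_oat(["A", "H"], grids, reduced_protocol(), metrics=("rheobase",))

print(result.correlations[
    ["model_id", "current", "property", "tau_rheobase", "n_used", "n_excluded"]
].to_string(index=False))

# tau_rheobase near -1 for the sodium conductance means rheobase falls
# monotonically as g_Na grows (more sodium -> easier to reach threshold);
# near +1 for the leak conductance means rheobase rises monotonically
# (a leakier membrane needs more current to depolarize).  Excluded grid
# points (non-firing or bursting alterations) are counted, never hidden.
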