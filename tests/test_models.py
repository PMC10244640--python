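"""Model registry: conductance-table audit, construction, perturbations."""

import numpy as np
import pandas as pd
import pytest

from chanfire import (Alteration, apply_alteration, build_model,
                      conductance_table, heterozygous_split, model_from_yaml,
                      model_to_yaml, steady_state)

# The published cell-properties table (maximal conductances in mS/cm^2,
# tau_max,M in ms, C_m in pF); NaN marks currents a model does not carry.
_NA = float("nan")
TABLE1 = pd.DataFrame(
    {
        #      Na     Kd     Kv1.1     A        M       L    T        Ca_K  Leak     tau  C_m
        "A": [3.4, 9.0556, _NA, 15.0159, _NA, _NA, 0.45045, _NA, 0.07407, _NA, 177.83],
        "B": [10.0, 2.1, _NA, _NA, 0.0098, _NA, _NA, _NA, 0.0205, 934.0, 119.99],
        "C": [58.0, 3.9, _NA, _NA, 0.075, _NA, _NA, _NA, 0.038, 502.0, 101.71],
        "D": [56.0, 6.0, _NA, _NA, 0.075, _NA, _NA, _NA, 0.0205, 608.0, 118.44],
        "E": [10.0, 1.89, 0.21, _NA, 0.0098, _NA, _NA, _NA, 0.0205, 934.0, 119.99],
        "F": [3.4, 8.15, 0.90556, 15.0159, _NA, _NA, 0.45045, _NA, 0.07407, _NA, 177.83],
        "G": [58.0, 3.51, 0.39, _NA, 0.075, _NA, _NA, _NA, 0.038, 502.0, 101.71],
        "H": [56.0, 5.4, 0.6, _NA, 0.075, _NA, _NA, _NA, 0.0205, 608.0, 118.44],
        "I": [49.0, 56.43, 0.57, 5.0, _NA, 5.0, 5.0, 1.0, 0.035, _NA, 118.44],
        "J": [3.4, 9.0556, 1.50159, _NA, _NA, _NA, 0.45045, _NA, 0.07407, _NA, 177.83],
        "K": [49.0, 57.0, 0.5, _NA, _NA, 5.0, 5.0, 1.0, 0.035, _NA, 118.44],
        "L": [49.0, 57.0, _NA, 5.0, _NA, 5.0, 5.0, 1.0, 0.035, _NA, 118.44],
    },
    index=["Na", "Kd", "Kv1.1", "A", "M", "L", "T", "Ca_K", "Leak",
           "tau_max_M", "C_m"],
)


class TestRegistry:
    def test_conductance_table_matches_published_values(self):
        got = conductance_table()
        pd.testing.assert_frame_equal(got, TABLE1, check_like=True)

    def test_every_table_cell_lands_in_exactly_one_spec_field(self):
        for mid in TABLE1.columns:
            spec = build_model(mid)
            names = [c.name for c in spec.currents if c.g_max > 0]
            assert len(names) == len(set(names))
            for row in TABLE1.index[:-2]:
                cell = TABLE1.loc[row, mid]
                if np.isnan(cell):
                    assert not any(c.name == row and c.g_max > 0
                                   for c in spec.currents)
                else:
                    assert spec.current(row).g_max == cell

    def test_model_h_parameters(self):
        h = build_model("H")
        assert h.current("Na").g_max == 56.0
        assert h.current("Kd").g_max == 5.4
        assert h.current("Kv1.1").g_max == 0.6
        assert h.current("M").g_max == 0.075
        assert h.current("Leak").g_max == 0.0205
        assert h.current("M").activation.tau.params == (608.0,)
        assert h.c_m == 118.44

    def test_delta_variants_lack_a_current(self):
        for mid, g_kv in (("J", 1.50159), ("K", 0.5)):
            spec = build_model(mid)
            assert spec.current("Kv1.1").g_max == g_kv
            assert not spec.has_current("A")

    def test_construction_is_pure(self):
        assert build_model("A") == build_model("A")

    def test_unknown_id_names_valid_ones(self):
        with pytest.raises(KeyError, match="valid ids"):
            build_model("Z")

    def test_stimulus_ranges(self):
        for mid in "ABCDEFGHIJKL":
            expect = 350.0 if mid in "BE" else 1000.0
            assert build_model(mid).i_max_pa == expect


class TestAlterations:
    def test_identity_alterations_are_noops(self):
        g = build_model("G")
        for alt in (Alteration("Kd", "v_half_shift", 0.0, "activation"),
                    Alteration("Kd", "slope_scale", 1.0, "activation"),
                    Alteration("Na", "conductance_scale", 1.0)):
            assert apply_alteration(g, alt) == g

    def test_v_half_shift_translates_curve(self):
        g = build_model("G")
        alt = apply_alteration(
            g, Alteration("Kd", "v_half_shift", 10.0, "activation"))
        orig = g.current("Kd").activation
        shifted = alt.current("Kd").activation
        v = np.linspace(-80, 20, 21)
        np.testing.assert_allclose(steady_state(shifted, v + 10.0),
                                   steady_state(orig, v), rtol=1e-12)

    def test_conductance_scaling_leak(self):
        a = build_model("A")
        alt = apply_alteration(a, Alteration("Leak", "conductance_scale", 2.0))
        assert alt.current("Leak").g_max == pytest.approx(0.14814, abs=1e-6)
        # everything else untouched
        assert alt.current("Na") == a.current("Na")

    def test_shift_composition(self):
        m = build_model("H")
        one = Alteration("Kv1.1", "v_half_shift", 5.0, "activation")
        both = Alteration("Kv1.1", "v_half_shift", 10.0, "activation")
        assert apply_alteration(apply_alteration(m, one), one) == \
            apply_alteration(m, both)

    def test_missing_current_raises_with_context(self):
        with pytest.raises(KeyError, match="D.*Kv1.1|Kv1.1.*D"):
            apply_alteration(build_model("D"),
                             Alteration("Kv1.1", "conductance_scale", 2.0))

    def test_invalid_alteration_specs(self):
        with pytest.raises(ValueError):
            Alteration("Na", "conductance_scale", 2.0, "activation")
        with pytest.raises(ValueError):
            Alteration("Na", "v_half_shift", 5.0)


class TestHeterozygousSplit:
    def test_split_halves_conductance(self):
        h = heterozygous_split(build_model("H"), "Kv1.1")
        halves = [c for c in h.currents if c.base_name == "Kv1.1"]
        assert [c.name for c in halves] == ["Kv1.1/wt", "Kv1.1/mut"]
        assert all(c.g_max == 0.3 for c in halves)
        assert halves[0].activation == halves[1].activation

    def test_split_absent_current_raises(self):
        with pytest.raises(KeyError):
            heterozygous_split(build_model("J"), "A")


class TestSerialization:
    def test_yaml_round_trip(self):
        for mid in ("A", "H", "L"):
            spec = build_model(mid)
            assert model_from_yaml(model_to_yaml(spec)) == spec

    def test_loader_rejects_tampered_registry_model(self):
        text = model_to_yaml(build_model("H")).replace("5.4", "5.5")
        with pytest.raises(ValueError, match="registry"):
            model_from_yaml(text)
        # but accepts it as a non-validated custom spec
        assert model_from_yaml(text, validate=False).current("Kd").g_max == 5.5
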