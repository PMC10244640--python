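"""Heterozygous mutation mechanics and cross-model correlation matrices."""

import numpy as np
import pandas as pd
import pytest

from chanfire import (MutationEffect, apply_mutation, build_model,
                      compile_model, pairwise_model_correlations, read_panel,
                      write_panel)


class TestApplyMutation:
    def test_identity_mutation_compiles_to_wild_type(self):
        for mid in ("H", "F", "J"):
            wt = compile_model(build_model(mid))
            mut = compile_model(apply_mutation(build_model(mid),
                                               MutationEffect("WT")))
            np.testing.assert_array_equal(wt.currents, mut.currents)
            np.testing.assert_array_equal(wt.gates, mut.gates)

    def test_zero_amplitude_is_pure_half_loss(self):
        m = apply_mutation(build_model("H"), MutationEffect("null", amp_rel=0.0))
        kv = [c for c in m.currents if c.base_name == "Kv1.1"]
        assert sum(c.g_max for c in kv) == pytest.approx(0.3)

    def test_mutant_half_carries_all_three_effects(self):
        eff = MutationEffect("X", amp_rel=0.4, k_rel=1.5, dv_half=12.0)
        m = apply_mutation(build_model("H"), eff)
        mut = m.current("Kv1.1/mut")
        wt = m.current("Kv1.1/wt")
        assert mut.g_max == pytest.approx(0.3 * 0.4)
        assert mut.activation.ss_stretch == pytest.approx(1.5)
        assert mut.activation.ss_shift == pytest.approx(12.0)
        assert mut.activation.tau.v_shift == pytest.approx(12.0)
        # wild-type half untouched, inactivation untouched
        assert wt == build_model("H").current("Kv1.1").__class__(
            name="Kv1.1/wt", g_max=0.3,
            e_rev=wt.e_rev, activation=wt.activation,
            inactivation=wt.inactivation)
        assert mut.inactivation == wt.inactivation

    def test_a_current_comutated_when_present(self):
        eff = MutationEffect("X", amp_rel=0.5)
        f = apply_mutation(build_model("F"), eff)  # has Kv1.1 and A
        assert f.has_current("A/mut") and f.has_current("Kv1.1/mut")
        j = apply_mutation(build_model("J"), eff)  # Kv1.1 only
        assert j.has_current("Kv1.1/mut") and not j.has_current("A/mut")

    def test_models_without_kv11_inapplicable(self):
        for mid in ("A", "B", "C", "D", "L"):
            with pytest.raises(KeyError, match="Kv1.1"):
                apply_mutation(build_model(mid), MutationEffect("X", 0.5))

    def test_invalid_effects_rejected(self):
        with pytest.raises(ValueError):
            MutationEffect("X", amp_rel=-0.1)
        with pytest.raises(ValueError):
            MutationEffect("X", k_rel=0.0)


def _toy_results(vectors: dict) -> pd.DataFrame:
    rows = []
    for mid, vec in vectors.items():
        rows.append(dict(model_id=mid, mutation="WT", amp_rel=1.0, k_rel=1.0,
                         dv_half=0.0, d_rheobase_pa=0.0, d_auc_norm=0.0,
                         excluded=False))
        for i, (dr, da) in enumerate(vec):
            rows.append(dict(model_id=mid, mutation=f"M{i}", amp_rel=0.5,
                             k_rel=1.0, dv_half=0.0, d_rheobase_pa=dr,
                             d_auc_norm=da, excluded=False))
    return pd.DataFrame(rows)


class TestPairwiseCorrelations:
    def test_duplicate_model_perfectly_correlated(self):
        vec = [(-5.0, 0.1), (-2.0, 0.3), (4.0, -0.2)]
        res = _toy_results({"X": vec, "Y": vec})
        tr, ta = pairwise_model_correlations(res)
        assert tr.loc["X", "Y"] == 1.0
        assert ta.loc["X", "Y"] == 1.0

    def test_negated_model_anticorrelated(self):
        vec = [(-5.0, 0.1), (-2.0, 0.3), (4.0, -0.2)]
        neg = [(-v[0], -v[1]) for v in vec]
        tr, ta = pairwise_model_correlations(_toy_results({"X": vec, "Y": neg}))
        assert tr.loc["X", "Y"] == -1.0

    def test_matrix_symmetric_unit_diagonal(self):
        res = _toy_results({
            "X": [(-5.0, 0.1), (-2.0, 0.3), (4.0, -0.2), (1.0, 0.0)],
            "Y": [(-1.0, 0.2), (3.0, -0.1), (2.0, 0.4), (-4.0, 0.3)],
            "Z": [(0.5, -0.3), (-2.5, 0.2), (1.5, 0.1), (3.5, -0.4)],
        })
        tr, _ = pairwise_model_correlations(res)
        np.testing.assert_array_equal(tr.values, tr.values.T)
        np.testing.assert_array_equal(np.diag(tr.values), 1.0)

    def test_matches_exhaustive_pair_count(self):
        import itertools

        vx = [(-5.0, 0.0), (-2.0, 0.0), (4.0, 0.0), (1.0, 0.0)]
        vy = [(-1.0, 0.0), (3.0, 0.0), (2.0, 0.0), (-4.0, 0.0)]
        tr, _ = pairwise_model_correlations(_toy_results({"X": vx, "Y": vy}))
        x = [v[0] for v in vx]
        y = [v[0] for v in vy]
        conc = disc = 0
        for i, j in itertools.combinations(range(4), 2):
            s = (x[j] - x[i]) * (y[j] - y[i])
            conc += s > 0
            disc += s < 0
        assert tr.loc["X", "Y"] == pytest.approx((conc - disc) / 6.0)

    def test_control_row_excluded_by_default(self):
        vec = [(-5.0, 0.1), (-2.0, 0.3)]
        res = _toy_results({"X": vec, "Y": vec})
        tr, _ = pairwise_model_correlations(res, include_control=False)
        assert tr.loc["X", "Y"] == 1.0  # two mutations, control dropped


class TestPanelIO:
    def test_round_trip(self, tmp_path):
        panel = [MutationEffect("WT"),
                 MutationEffect("V1", 0.3, 1.4, 12.5),
                 MutationEffect("V2", 0.9, 0.7, -3.0)]
        path = tmp_path / "panel.tsv"
        write_panel(path, panel)
        assert read_panel(path) == panel

    def test_missing_columns_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("name\tamp_rel\nX\t0.5\n")
        with pytest.raises(ValueError):
            read_panel(path)
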