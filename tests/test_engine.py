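"""Integrator: passive-membrane oracle, determinism, convergence, bounds."""

import numpy as np
import pytest

from chanfire import (CurrentSpec, IntegrationError, IntegratorConfig,
                      ModelSpec, NeuronSimulator, build_model, compile_model)


def passive_spec(g_leak=0.05, e_leak=-70.0, c_m=100.0):
    return ModelSpec(model_id="passive", label="leak only", c_m=c_m,
                     currents=(CurrentSpec("Leak", g_leak, e_leak),),
                     i_max_pa=1000.0)


class TestPassiveMembrane:
    def test_settles_to_leak_reversal(self):
        sim = NeuronSimulator(passive_spec())
        res = sim.settle()
        assert res.settled and not res.limit_cycle
        assert res.v_rest == pytest.approx(-70.0, abs=1e-6)

    def test_step_matches_rc_closed_form(self):
        g, e, cm = 0.05, -70.0, 100.0
        sim = NeuronSimulator(passive_spec(g, e, cm))
        tr = sim.run_step(200.0, 500.0)
        i_dens = 200.0 / cm  # uA/cm^2 at 1 uF/cm^2
        tau = 1.0 / g  # ms (C_bar = 1)
        expect = e + (i_dens / g) * (1.0 - np.exp(-tr.time / tau))
        assert np.max(np.abs(tr.voltage - expect)) < 0.1

    def test_zero_input_trace_is_flat(self):
        sim = NeuronSimulator(passive_spec())
        tr = sim.run_step(0.0, 200.0)
        np.testing.assert_allclose(tr.voltage, -70.0, atol=1e-6)

    def test_trace_columnar_export(self):
        sim = NeuronSimulator(passive_spec())
        tr = sim.run_step(100.0, 50.0)
        df = tr.to_frame(stride=10)
        assert list(df.columns) == ["time_ms", "stimulus_pa", "voltage_mv"]
        assert len(df) == len(tr.time[::10])


class TestDeterminism:
    def test_settle_twice_identical(self):
        a = NeuronSimulator(build_model("H")).settle()
        b = NeuronSimulator(build_model("H")).settle()
        np.testing.assert_array_equal(a.state, b.state)

    def test_step_traces_bit_identical(self):
        t1 = NeuronSimulator(build_model("A")).run_step(500.0, 300.0)
        t2 = NeuronSimulator(build_model("A")).run_step(500.0, 300.0)
        np.testing.assert_array_equal(t1.voltage, t2.voltage)


class TestNumerics:
    def test_dt_refinement_convergence(self):
        """Halving dt moves the trace by < 0.5 mV away from spike peaks."""
        from scipy.signal import find_peaks

        tr = {}
        for dt in (0.01, 0.005):
            sim = NeuronSimulator(build_model("H"), IntegratorConfig(dt=dt))
            tr[dt] = sim.run_step(500.0, 400.0)
        coarse = tr[0.01].voltage
        fine = tr[0.005].voltage[::2]
        peaks, _ = find_peaks(coarse, prominence=50, distance=100)
        mask = np.ones(len(coarse), dtype=bool)
        for p in peaks:
            mask[max(0, p - 150):p + 150] = False  # blank 1.5 ms around spikes
        # spike-time drift accumulates; compare the first interspike stretch
        upto = peaks[1] if len(peaks) > 1 else len(coarse)
        assert np.max(np.abs(coarse[:upto][mask[:upto]] -
                             fine[:upto][mask[:upto]])) < 0.5

    def test_gate_variables_stay_in_unit_interval(self):
        for mid in "ABCDEFGHIJKL":
            sim = NeuronSimulator(build_model(mid))
            tr = sim.run_step(0.7 * sim.spec.i_max_pa, 300.0)
            gates = tr.state[1:-1]
            assert np.all((gates >= 0.0) & (gates <= 1.0)), mid

    def test_divergence_raises_integration_error(self):
        runaway = ModelSpec(model_id="runaway", label="", c_m=100.0,
                            currents=(CurrentSpec("Leak", 0.05, 500.0),),
                            i_max_pa=1000.0)
        sim = NeuronSimulator(runaway)
        with pytest.raises(IntegrationError):
            sim.settle()

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            IntegratorConfig(dt=0.0)
        with pytest.raises(ValueError):
            IntegratorConfig(record_stride=0)


class TestRamp:
    def test_stimulus_symmetric_about_midpoint(self):
        sim = NeuronSimulator(passive_spec())
        tr = sim.run_ramp(half_ms=200.0, peak_pa=400.0)
        s = tr.stimulus
        one_sample = 400.0 * tr.dt / 200.0  # grid discretization of the peak
        np.testing.assert_allclose(s, s[::-1], atol=one_sample + 1e-9)
        assert s.max() == pytest.approx(400.0, rel=1e-3)

    def test_passive_ramp_lags_stimulus(self):
        g, cm = 0.05, 100.0
        sim = NeuronSimulator(passive_spec(g, -70.0, cm))
        tr = sim.run_ramp(half_ms=500.0, peak_pa=500.0)
        # quasi-static prediction lags by the membrane time constant
        tau = 1.0 / g
        drive = tr.stimulus / cm / g
        v_pred = -70.0 + np.interp(tr.time - tau, tr.time, drive,
                                   left=0.0)
        mid = slice(len(tr.time) // 4, len(tr.time) // 2)
        assert np.max(np.abs(tr.voltage[mid] - v_pred[mid])) < 0.5


class TestCompilation:
    def test_zero_conductance_currents_dropped(self):
        comp = compile_model(build_model("D"))  # carries an inert g=0 current
        assert np.all(comp.currents[:, 0] > 0)

    def test_unmutated_split_compiles_identically(self):
        from chanfire import heterozygous_split

        base = compile_model(build_model("H"))
        split = compile_model(heterozygous_split(build_model("H"), "Kv1.1"))
        np.testing.assert_array_equal(base.currents, split.currents)
        np.testing.assert_array_equal(base.gates, split.gates)

    def test_split_total_current_additive(self):
        """Split and unsplit specs produce bit-identical voltage traces."""
        from chanfire import heterozygous_split

        spec = build_model("F")
        split = heterozygous_split(heterozygous_split(spec, "Kv1.1"), "A")
        t1 = NeuronSimulator(spec).run_step(700.0, 300.0)
        t2 = NeuronSimulator(split).run_step(700.0, 300.0)
        np.testing.assert_array_equal(t1.voltage, t2.voltage)
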