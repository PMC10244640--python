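"""Spike detection and firing characterization against planted ground truth."""

import numpy as np
import pytest

from chanfire import (AnalyticNeuron, SpikeTrain, characterize,
                      classify_burst, classify_firing_change, coarse_fi,
                      detect_spikes, make_spike_trace, steady_state_rate)
from chanfire.metrics import FICurve, NonFiringError, ramp_hysteresis


class TestDetectSpikes:
    def test_flat_trace_gives_empty_train(self):
        tr = make_spike_trace([], 500.0)
        assert len(detect_spikes(tr)) == 0

    def test_recovers_planted_spikes(self):
        times = np.linspace(37.0, 950.0, 17)
        tr = make_spike_trace(times, 1000.0, prominence_mv=80.0)
        st = detect_spikes(tr)
        assert len(st) == 17
        np.testing.assert_allclose(st.spike_times, times, atol=tr.dt)

    def test_subthreshold_bumps_excluded(self):
        spikes = np.array([100.0, 300.0, 500.0])
        bumps = np.array([200.0, 400.0])
        tr_spikes = make_spike_trace(spikes, 600.0, prominence_mv=80.0)
        tr_bumps = make_spike_trace(bumps, 600.0, prominence_mv=30.0)
        v = np.maximum(tr_spikes.voltage, tr_bumps.voltage)
        tr_spikes.voltage = v
        st = detect_spikes(tr_spikes)
        np.testing.assert_allclose(st.spike_times, spikes, atol=tr_spikes.dt)

    def test_noise_does_not_create_spurious_spikes(self):
        times = np.arange(50.0, 950.0, 100.0)
        tr = make_spike_trace(times, 1000.0, noise_sd=2.0, seed=7)
        assert len(detect_spikes(tr)) == len(times)

    def test_spike_train_validation(self):
        with pytest.raises(ValueError):
            SpikeTrain(spike_times=np.array([5.0, 3.0]))


class TestSteadyStateRate:
    def _train(self, times):
        return SpikeTrain(spike_times=np.asarray(times, dtype=float))

    def test_periodic_train(self):
        st = self._train(np.arange(0.0, 2000.0, 20.0))  # 50 Hz
        assert steady_state_rate(st, 2000.0) == pytest.approx(50.0)

    def test_no_spikes_in_last_second(self):
        st = self._train([100.0, 200.0, 300.0])
        assert steady_state_rate(st, 2000.0) == 0.0

    def test_mean_of_reciprocal_isis(self):
        # ISIs 20, 20, 25, 25 ms -> mean of (50, 50, 40, 40) Hz
        st = self._train([1000.0, 1020.0, 1040.0, 1065.0, 1090.0])
        assert steady_state_rate(st, 2000.0) == pytest.approx(45.0)

    def test_single_spike_counts_as_silence(self):
        st = self._train([1500.0])
        assert steady_state_rate(st, 2000.0) == 0.0

    def test_invariant_to_phase_of_first_spike(self):
        period = 1000.0 / 40.0
        for phase in (0.0, 7.3, 13.9):
            t = np.arange(phase, 2000.0, period)
            st = self._train(t)
            assert steady_state_rate(st, 2000.0) == pytest.approx(40.0)


class TestBurstClassification:
    def test_tonic_train_not_bursty(self):
        st = SpikeTrain(np.arange(1000.0, 2000.0, 20.0))
        assert not classify_burst(st, 2000.0)

    def test_planted_burst_train_flagged(self):
        times, t = [], 1000.0
        for _ in range(4):
            for _ in range(3):
                times.append(t)
                t += 5.0
            t += 200.0
        st = SpikeTrain(np.array(times))
        assert classify_burst(st, 2000.0, window_ms=500.0)

    def test_two_spikes_insufficient_evidence(self):
        st = SpikeTrain(np.array([1100.0, 1300.0]))
        assert not classify_burst(st, 2000.0)


class TestQuadrants:
    @pytest.mark.parametrize("d_rheo,d_auc,label", [
        (-10.0, 0.2, "GOF"),
        (10.0, -0.2, "LOF"),
        (-10.0, -0.2, "ambiguous_LL"),
        (10.0, 0.2, "ambiguous_UR"),
        (0.0, 0.0, "unchanged"),
        (1e-12, 1e-12, "unchanged"),
        (0.0, 0.3, "AUC_increase"),
        (-5.0, 0.0, "rheobase_decrease"),
    ])
    def test_labels(self, d_rheo, d_auc, label):
        assert classify_firing_change(d_rheo, d_auc) == label


class TestFICurveStructures:
    def test_rates_must_be_nonnegative(self):
        with pytest.raises(ValueError):
            FICurve(currents=[1.0, 2.0], rates=[-0.1, 1.0])

    def test_currents_strictly_increasing(self):
        with pytest.raises(ValueError):
            FICurve(currents=[2.0, 1.0], rates=[0.0, 1.0])


@pytest.fixture(scope="module")
def type1():
    return AnalyticNeuron(threshold_pa=100.0, gain_hz_per_sqrt_pa=10.0)


@pytest.fixture(scope="module")
def type1_metrics(type1, proto):
    return characterize(type1, proto, need=("rheobase", "auc"))


class TestAnalyticOraclePipeline:
    """The full pipeline against closed-form pseudo-neurons."""

    def test_rheobase_within_one_fine_substep(self, type1_metrics, proto):
        substep = proto.fine_substep_pa(1000.0)
        assert abs(type1_metrics.rheobase_pa - 100.0) <= substep + 1e-9

    def test_auc_matches_closed_form_integral(self, type1_metrics):
        closed = (2.0 / 3.0) * 10.0 * 200.0**1.5  # integral of 10*sqrt(I-100)
        assert type1_metrics.auc == pytest.approx(closed, rel=0.01)

    def test_fi_curve_nondecreasing(self, type1, proto):
        scan = coarse_fi(type1, proto, stop="none")
        rates = scan.fi.rates
        assert np.all(np.diff(rates) >= -1e-9)

    def test_auc_equals_trapezoid_oracle(self, type1, proto):
        m = characterize(type1, proto, need=("auc",))
        c, r = m.fine.currents, m.fine.rates
        manual = sum((r[i] + r[i + 1]) / 2.0 * (c[i + 1] - c[i])
                     for i in range(len(c) - 1))
        assert m.auc == pytest.approx(manual, rel=1e-12)

    def test_type2_onset_discontinuity(self, proto):
        n2 = AnalyticNeuron(threshold_pa=200.0, gain_hz_per_sqrt_pa=2.0,
                            onset_rate_hz=20.0)
        m = characterize(n2, proto, need=("auc",))
        positive = m.fine.rates[m.fine.rates > 0]
        assert positive.min() >= 20.0

    def test_nonfiring_model_raises(self, proto):
        silent = AnalyticNeuron(threshold_pa=5000.0)
        with pytest.raises(NonFiringError):
            characterize(silent, proto, need=("rheobase",))

    def test_ramp_thresholds_nearly_coincide_for_memoryless_neuron(self, proto):
        n2 = AnalyticNeuron(threshold_pa=300.0, gain_hz_per_sqrt_pa=5.0,
                            onset_rate_hz=100.0)
        on, off = ramp_hysteresis(n2, proto)
        ramp_slope = 1000.0 / proto.ramp_half_ms  # pA per ms
        period_ms = 1000.0 / 100.0
        assert abs(on - off) <= 2 * ramp_slope * period_ms + 1.0

    def test_characterization_deterministic(self, type1, proto):
        a = characterize(type1, proto, need=("rheobase", "auc"))
        b = characterize(type1, proto, need=("rheobase", "auc"))
        assert a.rheobase_pa == b.rheobase_pa and a.auc == b.auc
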