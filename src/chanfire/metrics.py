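"""Spike detection and firing characterization.

The firing of a model neuron is summarized by two complementary measures:

* **rheobase** — the smallest injected current eliciting at least one action
  potential, refined to ``coarse step / n_fine`` resolution (0.05 pA for the
  0-1 nA full protocol, 0.0175 pA for 0-0.35 nA);
* **AUC** — the area under the steady-state frequency-current (fI) curve over
  a window of one fifth of the stimulus range starting at the onset of steady
  firing, computed with the composite trapezoidal rule (Hz*pA).  The AUC is a
  rheobase-independent proxy for the initial steepness of the fI curve.

Spikes are voltage peaks with at least 50 mV topographic prominence separated
by at least 1 ms.  The steady-state rate of a step response is the mean of
the reciprocal interspike intervals inside a 500 ms window anchored at the
first spike after ``search_start_ms``; fewer than two spikes in the window
count as silence.  Periodic-bursting responses are flagged (bimodal
steady-window ISIs) and excluded from downstream summaries rather than
silently dropped.

All functions accept any *simulator* object exposing ``run_step(amp_pa,
duration_ms) -> Trace`` and ``any_spike(amp_pa, duration_ms) -> bool`` (the
compiled neuron models and the analytic oracle neurons both do).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.integrate import trapezoid
from scipy.signal import find_peaks

from .engine import Trace
from .protocols import FiringProtocol

__all__ = [
    "SpikeTrain",
    "FICurve",
    "FiringMetrics",
    "NonFiringError",
    "detect_spikes",
    "steady_state_rate",
    "classify_burst",
    "classify_firing_change",
    "coarse_fi",
    "refine_rheobase",
    "refine_ss_onset_and_auc",
    "ramp_hysteresis",
    "characterize",
]


class NonFiringError(RuntimeError):
    """No (steady) firing anywhere in the stimulus range."""


@dataclass(frozen=True)
class SpikeTrain:
    spike_times: np.ndarray  # ms, strictly increasing
    amplitude_pa: float = float("nan")

    def __post_init__(self):
        t = np.asarray(self.spike_times, dtype=float)
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("spike times must be strictly increasing")
        object.__setattr__(self, "spike_times", t)

    def __len__(self):
        return len(self.spike_times)


@dataclass
class FICurve:
    currents: np.ndarray  # pA, strictly increasing
    rates: np.ndarray     # Hz, >= 0 (NaN where not evaluated)
    resolution: str = "coarse"  # coarse | fine

    def __post_init__(self):
        self.currents = np.asarray(self.currents, dtype=float)
        self.rates = np.asarray(self.rates, dtype=float)
        if np.any(np.diff(self.currents) <= 0):
            raise ValueError("fI currents must be strictly increasing")
        if np.any(self.rates[np.isfinite(self.rates)] < 0):
            raise ValueError("firing rates must be non-negative")


@dataclass
class CoarseScan:
    """Ascending coarse fI scan with bookkeeping for the refinement stages."""

    fi: FICurve
    n_spikes: np.ndarray
    first_spike_idx: Optional[int]
    first_steady_idx: Optional[int]
    evaluated: np.ndarray  # bool mask (ascending scans may stop early)


@dataclass
class FiringMetrics:
    """Firing characterization of one model (or one altered model)."""

    rheobase_pa: float = float("nan")
    auc: float = float("nan")          # Hz*pA
    ss_onset_pa: float = float("nan")  # onset of steady firing
    hysteresis_pa: Optional[tuple] = None  # (ramp-on, ramp-off) or None
    burst_fraction: float = 0.0
    burst_flag: bool = False
    block_flag: bool = False
    coarse: Optional[CoarseScan] = None
    fine: Optional[FICurve] = None


# ---------------------------------------------------------------------------
# Spike-level operations
# ---------------------------------------------------------------------------

def detect_spikes(trace: Trace, prominence_mv: float = 50.0,
                  min_isi_ms: float = 1.0) -> SpikeTrain:
    """Detect action potentials as prominent voltage peaks.

    Peaks need at least ``prominence_mv`` topographic prominence and
    ``min_isi_ms`` separation (of any closer pair the higher peak is kept).
    An empty train is a valid result.
    """
    v = np.asarray(trace.voltage, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("non-finite voltage trace passed to detect_spikes")
    sample_dt = trace.dt if len(trace.time) < 2 else trace.time[1] - trace.time[0]
    distance = max(1, int(round(min_isi_ms / sample_dt)))
    idx, _ = find_peaks(v, prominence=prominence_mv, distance=distance)
    amp = float(trace.stimulus[0]) if len(trace.stimulus) else float("nan")
    return SpikeTrain(spike_times=trace.time[idx], amplitude_pa=amp)


def _steady_window_isis(st: SpikeTrain, step_ms: float, window_ms: float,
                        search_start_ms: float) -> np.ndarray:
    t = st.spike_times
    t = t[t >= search_start_ms]
    if len(t) < 2:
        return np.empty(0)
    t0 = t[0]
    in_win = t[(t >= t0) & (t <= min(t0 + window_ms, step_ms))]
    if len(in_win) < 2:
        return np.empty(0)
    return np.diff(in_win)


def steady_state_rate(st: SpikeTrain, step_ms: float, window_ms: float = 500.0,
                      search_start_ms: Optional[float] = None) -> float:
    """Mean instantaneous firing rate (Hz) in the steady window.

    The window starts at the first spike at or after ``search_start_ms``
    (default: the final second of the step) and spans ``window_ms``; the rate
    is the mean of reciprocal interspike intervals whose defining spikes both
    fall inside the window.  Fewer than two such spikes yield 0 Hz.
    """
    if search_start_ms is None:
        search_start_ms = max(0.0, step_ms - 2.0 * window_ms)
    isis = _steady_window_isis(st, step_ms, window_ms, search_start_ms)
    if isis.size == 0:
        return 0.0
    return float(np.mean(1000.0 / isis))


def classify_burst(st: SpikeTrain, step_ms: float, window_ms: float = 500.0,
                   search_start_ms: Optional[float] = None,
                   ratio: float = 4.0, min_spikes: int = 4) -> bool:
    """Flag periodic bursting: strongly bimodal steady-window ISIs.

    Requires at least ``min_spikes`` spikes in the window; the train is
    bursty when the largest ISI exceeds ``ratio`` times the smallest.
    """
    if search_start_ms is None:
        search_start_ms = max(0.0, step_ms - 2.0 * window_ms)
    isis = _steady_window_isis(st, step_ms, window_ms, search_start_ms)
    if isis.size < min_spikes - 1:
        return False
    return bool(isis.max() / isis.min() > ratio)


_QUADRANTS = {
    (-1, +1): "GOF",
    (+1, -1): "LOF",
    (-1, -1): "ambiguous_LL",
    (+1, +1): "ambiguous_UR",
    (0, 0): "unchanged",
    (0, +1): "AUC_increase",
    (0, -1): "AUC_decrease",
    (-1, 0): "rheobase_decrease",
    (+1, 0): "rheobase_increase",
}


def classify_firing_change(d_rheobase_pa: float, d_auc_norm: float,
                           tol_rheobase_pa: float = 1e-9,
                           tol_auc: float = 1e-9) -> str:
    """Quadrant of a firing change in the (Δrheobase, normalized ΔAUC) plane.

    Lower rheobase with larger AUC is an unambiguous firing gain of function
    (GOF); higher rheobase with smaller AUC a loss of function (LOF); the two
    remaining quadrants are ambiguous.  Values within tolerance of zero count
    as unchanged on that axis.
    """
    sr = 0 if abs(d_rheobase_pa) <= tol_rheobase_pa else int(math.copysign(1, d_rheobase_pa))
    sa = 0 if abs(d_auc_norm) <= tol_auc else int(math.copysign(1, d_auc_norm))
    return _QUADRANTS[(sr, sa)]


# ---------------------------------------------------------------------------
# Protocol-level operations
# ---------------------------------------------------------------------------

def _step_rate(sim, amp: float, proto: FiringProtocol):
    tr = sim.run_step(amp, proto.step_ms)
    st = detect_spikes(tr, proto.prominence_mv, proto.min_isi_ms)
    rate = steady_state_rate(st, proto.step_ms, proto.window_ms,
                             proto.search_start_ms)
    return st, rate


def coarse_fi(sim, proto: FiringProtocol, i_max: Optional[float] = None,
              stop: str = "none") -> CoarseScan:
    """Ascending coarse fI scan.

    ``stop`` may be ``"none"`` (evaluate every amplitude), ``"steady"``
    (stop once steady firing is found; remaining rates are NaN) or
    ``"spike"`` (stop at the first amplitude with any spike).  Raises
    :class:`NonFiringError` when the requested stopping feature never occurs.
    """
    if i_max is None:
        i_max = proto.i_max_for(sim.spec)
    amps = proto.coarse_amplitudes(i_max)
    rates = np.full(len(amps), np.nan)
    n_spk = np.zeros(len(amps), dtype=int)
    evaluated = np.zeros(len(amps), dtype=bool)
    first_spike = None
    first_steady = None
    for i, amp in enumerate(amps):
        if stop == "spike":
            # presence query only (early-exit integration)
            evaluated[i] = True
            if sim.any_spike(amp, proto.step_ms):
                n_spk[i] = 1
                first_spike = i
                break
            continue
        st, rate = _step_rate(sim, amp, proto)
        rates[i] = rate
        n_spk[i] = len(st)
        evaluated[i] = True
        if first_spike is None and len(st) > 0:
            first_spike = i
        if first_steady is None and rate > 0.0:
            first_steady = i
            if stop == "steady":
                break
    if stop == "spike" and first_spike is None:
        raise NonFiringError("no action potentials anywhere in the stimulus range")
    if stop == "steady" and first_steady is None:
        raise NonFiringError("no steady firing anywhere in the stimulus range")
    return CoarseScan(
        fi=FICurve(currents=amps, rates=rates, resolution="coarse"),
        n_spikes=n_spk, first_spike_idx=first_spike,
        first_steady_idx=first_steady, evaluated=evaluated,
    )


def refine_rheobase(sim, proto: FiringProtocol, scan: CoarseScan,
                    i_max: Optional[float] = None) -> float:
    """Refine rheobase over the coarse interval preceding the first spike.

    100 equidistant substeps span the interval; the rheobase is the lowest
    substep eliciting at least one action potential (ascending search; falls
    back to the coarse first-spiking amplitude if no substep fires).
    """
    if scan.first_spike_idx is None:
        raise NonFiringError("cannot refine rheobase of a non-firing model")
    if i_max is None:
        i_max = proto.i_max_for(sim.spec)
    hi = scan.fi.currents[scan.first_spike_idx]
    step = proto.coarse_step_pa(i_max)
    lo = hi - step
    for k in range(1, proto.n_fine + 1):
        amp = lo + k * step / proto.n_fine
        if sim.any_spike(amp, proto.step_ms):
            return float(amp)
    return float(hi)


def refine_ss_onset_and_auc(sim, proto: FiringProtocol, scan: CoarseScan,
                            i_max: Optional[float] = None):
    """Refine the steady-firing onset and compute the fI-curve AUC.

    100 substeps across the coarse interval preceding steady firing locate
    the onset; a 100-point fine fI curve then spans one fifth of the overall
    current range from the onset upward and its trapezoidal integral is the
    AUC.  Returns ``(onset_pa, auc, fine_curve, burst_fraction)``.
    """
    if scan.first_steady_idx is None:
        raise NonFiringError("cannot refine steady-firing onset: no steady firing")
    if i_max is None:
        i_max = proto.i_max_for(sim.spec)
    hi = scan.fi.currents[scan.first_steady_idx]
    step = proto.coarse_step_pa(i_max)
    lo = hi - step
    onset = float(hi)
    for k in range(1, proto.n_fine + 1):
        amp = lo + k * step / proto.n_fine
        _, rate = _step_rate(sim, amp, proto)
        if rate > 0.0:
            onset = float(amp)
            break
    fine_amps = np.linspace(onset, onset + proto.auc_fraction * i_max,
                            proto.n_fine)
    fine_rates = np.empty(len(fine_amps))
    bursts = 0
    firing = 0
    for i, amp in enumerate(fine_amps):
        st, rate = _step_rate(sim, amp, proto)
        fine_rates[i] = rate
        if rate > 0.0:
            firing += 1
            if classify_burst(st, proto.step_ms, proto.window_ms,
                              proto.search_start_ms, proto.burst_ratio,
                              proto.burst_min_spikes):
                bursts += 1
    auc = float(trapezoid(fine_rates, fine_amps))
    burst_fraction = bursts / firing if firing else 0.0
    fine = FICurve(currents=fine_amps, rates=fine_rates, resolution="fine")
    return onset, auc, fine, burst_fraction


def ramp_hysteresis(sim, proto: FiringProtocol,
                    i_max: Optional[float] = None) -> Optional[tuple]:
    """Stimulus at firing onset (ascending ramp) and offset (descending ramp).

    Returns ``(on_pa, off_pa)`` or None when the ramp elicits no spikes.
    These ramp thresholds characterize hysteresis only; they do not feed the
    step-protocol rheobase.
    """
    if i_max is None:
        i_max = proto.i_max_for(sim.spec)
    tr = sim.run_ramp(proto.ramp_half_ms, i_max)
    st = detect_spikes(tr, proto.prominence_mv, proto.min_isi_ms)
    if len(st) == 0:
        return None
    sample_dt = tr.time[1] - tr.time[0]
    stim_at = lambda t: float(tr.stimulus[int(round(t / sample_dt))])
    return stim_at(st.spike_times[0]), stim_at(st.spike_times[-1])


def characterize(sim, proto: FiringProtocol,
                 need: Sequence[str] = ("rheobase", "auc"),
                 i_max: Optional[float] = None) -> FiringMetrics:
    """Full firing characterization of one simulator.

    ``need`` selects the computed pieces among ``rheobase``, ``auc``,
    ``hysteresis`` and ``fi`` (full coarse curve with depolarization-block
    flag); unrequested pieces are skipped for speed.  Raises
    :class:`NonFiringError` if a requested piece is undefined because the
    model never (steadily) fires.
    """
    if i_max is None:
        i_max = proto.i_max_for(sim.spec)
    m = FiringMetrics()
    scan = None
    if "fi" in need:
        scan = coarse_fi(sim, proto, i_max, stop="none")
        rates = scan.fi.rates
        if scan.first_steady_idx is not None:
            m.block_flag = bool(rates[-1] < 0.5 * np.nanmax(rates))
    elif "auc" in need:
        scan = coarse_fi(sim, proto, i_max, stop="steady")
    elif "rheobase" in need:
        scan = coarse_fi(sim, proto, i_max, stop="spike")
    if scan is not None:
        m.coarse = scan
    if "rheobase" in need:
        if scan.first_spike_idx is None:
            raise NonFiringError("no action potentials in the stimulus range")
        m.rheobase_pa = refine_rheobase(sim, proto, scan, i_max)
    if "auc" in need:
        if scan.first_steady_idx is None:
            raise NonFiringError("no steady firing in the stimulus range")
        onset, auc, fine, burst_frac = refine_ss_onset_and_auc(
            sim, proto, scan, i_max)
        m.ss_onset_pa = onset
        m.auc = auc
        m.fine = fine
        m.burst_fraction = burst_frac
        m.burst_flag = burst_frac > proto.burst_fraction_limit
    if "hysteresis" in need:
        m.hysteresis_pa = ramp_hysteresis(sim, proto, i_max)
    return m
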