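"""Synthetic test inputs with known ground truth.

Three generators make every pipeline stage testable without external data:

* :class:`AnalyticNeuron` — a pseudo-neuron with a closed-form fI curve
  (type-I: ``rate = gain * sqrt(I - threshold)`` above threshold; type-II:
  a discontinuous onset at ``onset_rate_hz``).  It satisfies the simulator
  contract of the metrics layer by emitting synthetic periodic spike trains
  at the closed-form rate (no ODE integration), so metric-layer tests are
  fast and exact up to one fine current substep and the 1/(window) rate
  quantization.
* :func:`make_spike_trace` — voltage traces with spike-shaped transients of
  known prominence at planted times (plus optional seeded Gaussian noise),
  the ground truth for spike detection.
* :func:`make_panel` — seeded, loss-of-function-dominated mutation panels
  emulating the structure of published heterologous-expression measurements
  of episodic-ataxia Kv1.1 variants: relative amplitude below wild type,
  log-symmetric slope factors, and mostly depolarizing activation shifts.

These generators never import from the modules they are used to test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .engine import Trace
from .mutations import MutationEffect

__all__ = [
    "AnalyticNeuron",
    "PanelSpec",
    "make_spike_trace",
    "make_panel",
]


def _spike_shape(width_samples: int) -> np.ndarray:
    """A triangular unit spike of the given width (odd sample count)."""
    half = width_samples // 2
    up = np.linspace(0.0, 1.0, half + 1)
    return np.concatenate([up, up[-2::-1]])


def _plant_spikes(bumps: np.ndarray, times_ms, dt: float, amplitude: float,
                  width_ms: float = 2.0) -> None:
    """Superimpose triangular transients (relative to 0) onto ``bumps``."""
    width = int(round(width_ms / dt)) | 1
    shape = amplitude * _spike_shape(width)
    half = len(shape) // 2
    for t in np.asarray(times_ms, dtype=float):
        i = int(round(t / dt))
        lo, hi = i - half, i + half + 1
        s_lo = max(0, -lo)
        s_hi = len(shape) - max(0, hi - len(bumps))
        lo, hi = max(lo, 0), min(hi, len(bumps))
        if lo < hi:
            np.maximum(bumps[lo:hi], shape[s_lo:s_hi], out=bumps[lo:hi])


def make_spike_trace(spike_times_ms: Sequence[float], duration_ms: float,
                     prominence_mv: float = 80.0, baseline_mv: float = -65.0,
                     noise_sd: float = 0.0, dt: float = 0.01,
                     seed: int = 0, amplitude_pa: float = 0.0) -> Trace:
    """A voltage trace with spike-shaped peaks of known prominence.

    Peaks of ``prominence_mv`` above ``baseline_mv`` are planted at the
    requested times (2 ms triangular transients); optional Gaussian noise is
    drawn from a seeded generator, so identical seeds give identical traces.
    """
    n = int(round(duration_ms / dt))
    bumps = np.zeros(n)
    _plant_spikes(bumps, spike_times_ms, dt, prominence_mv)
    v = baseline_mv + bumps
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        v = v + rng.normal(0.0, noise_sd, size=n)
    t = np.arange(n) * dt
    return Trace(time=t, voltage=v, stimulus=np.full(n, amplitude_pa),
                 state=np.array([v[-1]]), dt=dt)


@dataclass(frozen=True)
class _FakeSpec:
    """Minimal spec-like object so analytic neurons fit the simulator API."""

    model_id: str
    i_max_pa: float
    c_m: float = float("nan")


class AnalyticNeuron:
    """Pseudo-neuron with a closed-form fI curve (oracle for the metrics layer).

    Parameters
    ----------
    threshold_pa:
        Rheobase of the closed form; no spikes below it.
    gain_hz_per_sqrt_pa:
        Type-I gain: ``rate(I) = gain * sqrt(I - threshold)``.
    onset_rate_hz:
        If positive, a type-II-like discontinuity: the rate jumps from 0 to
        this value at threshold (added to the square-root branch).
    """

    def __init__(self, threshold_pa: float, gain_hz_per_sqrt_pa: float = 10.0,
                 onset_rate_hz: float = 0.0, i_max_pa: float = 1000.0,
                 baseline_mv: float = -65.0, spike_mv: float = 80.0,
                 dt: float = 0.05):
        if threshold_pa < 0 or gain_hz_per_sqrt_pa < 0 or onset_rate_hz < 0:
            raise ValueError("analytic neuron parameters must be non-negative")
        self.threshold_pa = float(threshold_pa)
        self.gain = float(gain_hz_per_sqrt_pa)
        self.onset_rate_hz = float(onset_rate_hz)
        self.baseline_mv = baseline_mv
        self.spike_mv = spike_mv
        self.dt = dt
        self.spec = _FakeSpec(model_id="analytic", i_max_pa=float(i_max_pa))

    # -- closed form --------------------------------------------------------

    def rate(self, amp_pa: float) -> float:
        """The closed-form steady firing rate (Hz)."""
        if amp_pa <= self.threshold_pa:
            return 0.0
        return self.onset_rate_hz + self.gain * np.sqrt(amp_pa - self.threshold_pa)

    # -- simulator contract -------------------------------------------------

    def run_step(self, amp_pa: float, duration_ms: float) -> Trace:
        """Emit a periodic synthetic spike train at the closed-form rate."""
        rate = self.rate(amp_pa)
        n = int(round(duration_ms / self.dt))
        bumps = np.zeros(n)
        if rate > 0:
            period = 1000.0 / rate
            times = np.arange(period / 2.0, duration_ms, period)
            _plant_spikes(bumps, times, self.dt, self.spike_mv)
        v = self.baseline_mv + bumps
        t = np.arange(n) * self.dt
        return Trace(time=t, voltage=v, stimulus=np.full(n, amp_pa),
                     state=np.array([v[-1]]), dt=self.dt)

    def any_spike(self, amp_pa: float, duration_ms: float) -> bool:
        return self.rate(amp_pa) > 0 and duration_ms >= 500.0 / max(self.rate(amp_pa), 1e-9)

    def run_ramp(self, half_ms: float, peak_pa: float) -> Trace:
        """Memoryless ramp response: spikes wherever the ramp exceeds threshold."""
        n = int(round(2 * half_ms / self.dt))
        t = np.arange(n) * self.dt
        ph = np.minimum(t / half_ms, 2.0 - t / half_ms)
        stim = peak_pa * np.clip(ph, 0.0, 1.0)
        bumps = np.zeros(n)
        # march through the ramp emitting spikes at the instantaneous rate
        times = []
        t_next = 0.0
        for i in range(n):
            r = self.rate(stim[i])
            if r <= 0:
                t_next = t[i]
                continue
            if t[i] >= t_next:
                times.append(t[i])
                t_next = t[i] + 1000.0 / r
        _plant_spikes(bumps, times, self.dt, self.spike_mv)
        v = self.baseline_mv + bumps
        return Trace(time=t, voltage=v, stimulus=stim, state=np.array([v[-1]]),
                     dt=self.dt)


@dataclass(frozen=True)
class PanelSpec:
    """Specification of a synthetic mutation panel.

    The default ranges are loss-of-function dominated: amplitudes uniformly
    below wild type, slope factors log2-symmetric around 1, and activation
    shifts biased to depolarized (positive) values.
    """

    n_mutations: int = 10
    amp_rel_range: tuple = (0.1, 1.0)
    k_rel_range: tuple = (0.5, 2.0)
    dv_half_range: tuple = (-10.0, 30.0)
    seed: int = 0

    def __post_init__(self):
        for r in (self.amp_rel_range, self.k_rel_range, self.dv_half_range):
            if not (np.isfinite(r[0]) and np.isfinite(r[1]) and r[0] <= r[1]):
                raise ValueError(f"invalid panel range {r}")
        if self.k_rel_range[0] <= 0:
            raise ValueError("slope factors must be positive")


def make_panel(spec: PanelSpec = PanelSpec()) -> list:
    """Draw a seeded synthetic mutation panel (identity control prepended)."""
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.amp_rel_range
    amp = rng.uniform(lo, hi, spec.n_mutations)
    klo, khi = np.log2(spec.k_rel_range)
    k = np.exp2(rng.uniform(klo, khi, spec.n_mutations))
    dv = rng.uniform(*spec.dv_half_range, spec.n_mutations)
    panel = [MutationEffect("WT")]
    panel += [MutationEffect(f"M{i + 1:02d}", float(amp[i]), float(k[i]),
                             float(dv[i]))
              for i in range(spec.n_mutations)]
    return panel
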