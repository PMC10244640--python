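"""Stimulus/analysis protocol definitions.

The *full* protocol mirrors the study design: 200 equidistant 2 s current
steps spanning (0, I_max], spikes detected at 50 mV prominence with a 1 ms
minimum interspike interval, steady-state rate measured in a 500 ms window
anchored at the first spike in the last second, 100-substep refinements of
rheobase and steady-firing onset, a fine fI curve of 100 steps covering one
fifth of the stimulus range, and a 2 s up / 2 s down triangular ramp.

The *reduced* protocol keeps dt = 0.01 ms and all refinement structure but
uses 1 s steps (steady window in the last 500 ms), 50 coarse currents and a
1 s + 1 s ramp, trading resolution for run time on a desk-scale budget.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

__all__ = ["FiringProtocol", "full_protocol", "reduced_protocol"]


@dataclass(frozen=True)
class FiringProtocol:
    """All knobs of the firing-characterization pipeline."""

    n_coarse: int = 200           # coarse fI steps spanning (0, I_max]
    step_ms: float = 2000.0       # duration of each current step
    window_ms: float = 500.0      # steady-rate averaging window
    search_start_ms: float = 1000.0  # first spike searched from here on
    n_fine: int = 100             # substeps for rheobase/onset refinement & fine fI
    auc_fraction: float = 0.2     # fine fI span as a fraction of I_max
    ramp_half_ms: float = 2000.0  # ascending (= descending) ramp duration
    dt: float = 0.01              # integrator time step (ms)
    settle_max_ms: float = 3000.0
    prominence_mv: float = 50.0
    min_isi_ms: float = 1.0
    burst_ratio: float = 4.0      # max/min steady-window ISI ratio flagging a burst
    burst_min_spikes: int = 4
    burst_fraction_limit: float = 0.2  # share of bursty fine-fI points tolerated
    i_max_pa: Optional[float] = None   # None: use the model's stimulus range

    def __post_init__(self):
        if self.window_ms + self.search_start_ms > self.step_ms:
            raise ValueError("steady window must fit inside the step")
        if self.n_coarse < 2 or self.n_fine < 1:
            raise ValueError("need at least 2 coarse and 1 fine step")

    # -- derived quantities -------------------------------------------------

    def i_max_for(self, spec) -> float:
        return self.i_max_pa if self.i_max_pa is not None else spec.i_max_pa

    def coarse_amplitudes(self, i_max: float) -> np.ndarray:
        """Equidistant amplitudes spanning (0, i_max]."""
        return i_max * np.arange(1, self.n_coarse + 1) / self.n_coarse

    def coarse_step_pa(self, i_max: float) -> float:
        return i_max / self.n_coarse

    def fine_substep_pa(self, i_max: float) -> float:
        """Increment of the 100-substep refinement searches."""
        return self.coarse_step_pa(i_max) / self.n_fine

    def with_scale(self, **kw) -> "FiringProtocol":
        return replace(self, **kw)


def full_protocol(**kw) -> FiringProtocol:
    return FiringProtocol(**kw)


def reduced_protocol(**kw) -> FiringProtocol:
    base = dict(n_coarse=50, step_ms=1000.0, search_start_ms=500.0,
                ramp_half_ms=1000.0, settle_max_ms=2000.0)
    base.update(kw)
    return FiringProtocol(**base)
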