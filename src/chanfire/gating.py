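"""Voltage-gated channel gating: steady states, time constants, alterations.

Every gate ``x`` relaxes first-order toward a voltage-dependent steady state,

    dx/dt = (x_inf(V) - x) / tau_x(V),

and enters its membrane current as ``x ** power`` (``power`` is 1 for gates
whose fitted steady state already absorbs the classical Hodgkin-Huxley gate
exponent, and the classical power for rate-equation gates).

Two steady-state families are supported:

* ``boltzmann`` — the modified Boltzmann

      x_inf(V) = ((1 - a) / (1 + exp[(V - V1/2) / k]) + a) ** j

  with half-maximal voltage ``V1/2`` (mV), signed slope factor ``k`` (mV;
  negative for activation in the convention used here), exponent ``j >= 1``
  and persistent fraction ``0 <= a <= 1`` (the non-(in)activating floor on
  the saturating side of the curve).

* rate-equation kinds (``hh_na_m``, ``hh_na_h``, ``hh_kd_n``) — the classical
  cortical-neuron alpha/beta formulations with spike-threshold adjustment
  ``vt``; here ``x_inf = alpha/(alpha+beta)`` and ``v_half`` records the
  fitted Boltzmann midpoint of the curve, used as the anchor for slope
  alterations.

Alterations are uniform across kinds: a half-activation shift ``ss_shift``
translates the steady-state curve (and, via :class:`TauSpec.v_shift`, the tau
curve) along the voltage axis; a slope factor ``ss_stretch`` stretches the
steady-state curve about its shifted midpoint, which for a Boltzmann gate is
exactly multiplication of ``k``.  Both compose multiplicatively/additively.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "TauSpec",
    "GatingSpec",
    "CalciumGatingSpec",
    "steady_state",
    "time_constant",
    "TAU_KINDS",
    "SS_KINDS",
]

# Numeric codes shared with the compiled integrator kernel.
SS_KINDS = {
    "boltzmann": 0,
    "hh_na_m": 1,  # classical sodium activation rates (uses vt)
    "hh_na_h": 2,  # sodium inactivation rates
    "hh_kd_n": 3,  # delayed-rectifier activation rates
}

TAU_KINDS = {
    "constant": 0,   # params: (tau,)
    "bell": 1,       # params: (t_min, t_amp, v_peak, sigma_left, sigma_right)
    "sigmoid": 2,    # params: (t_min, t_amp, v_mid, slope)
    "hh_na_m": 3,    # params: (vt,)  tau = 1/(alpha+beta)
    "hh_na_h": 4,    # params: (vt,)
    "hh_kd_n": 5,    # params: (vt,)
    "m_current": 6,  # params: (tau_max,)  slow non-inactivating K+ (M)
}


@dataclass(frozen=True)
class TauSpec:
    """Voltage-dependent time-constant description for one gate.

    ``v_shift`` translates the curve along the voltage axis (mV); it tracks
    shifts applied to the gate's half-activation voltage.
    """

    kind: str
    params: tuple
    v_shift: float = 0.0

    def __post_init__(self):
        if self.kind not in TAU_KINDS:
            raise ValueError(
                f"unknown tau kind {self.kind!r}; valid: {sorted(TAU_KINDS)}"
            )

    def shifted(self, dv: float) -> "TauSpec":
        return replace(self, v_shift=self.v_shift + float(dv))


@dataclass(frozen=True)
class GatingSpec:
    """One gate: steady-state description, current exponent, tau description.

    ``ss_shift`` (mV) and ``ss_stretch`` (dimensionless) carry accumulated
    half-activation shifts and slope scalings; the pristine gate has 0 and 1.
    """

    v_half: float
    k: float
    j: float = 1.0
    a: float = 0.0
    kind: str = "boltzmann"
    vt: float = 0.0
    power: int = 1
    ss_shift: float = 0.0
    ss_stretch: float = 1.0
    tau: TauSpec = field(default_factory=lambda: TauSpec("constant", (1.0,)))

    def __post_init__(self):
        if self.kind not in SS_KINDS:
            raise ValueError(
                f"unknown steady-state kind {self.kind!r}; valid: {sorted(SS_KINDS)}"
            )
        if not (0.0 <= self.a <= 1.0):
            raise ValueError(f"persistent fraction a={self.a} outside [0, 1]")
        if self.j < 1.0:
            raise ValueError(f"exponent j={self.j} must be >= 1")
        if self.k == 0.0:
            raise ValueError("slope factor k must be nonzero")
        if self.ss_stretch <= 0.0:
            raise ValueError("slope scaling must be positive")

    @property
    def effective_v_half(self) -> float:
        return self.v_half + self.ss_shift

    @property
    def effective_k(self) -> float:
        return self.k * self.ss_stretch

    def shifted(self, dv: float) -> "GatingSpec":
        """Translate steady state and tau along the voltage axis by ``dv``."""
        return replace(self, ss_shift=self.ss_shift + float(dv),
                       tau=self.tau.shifted(dv))

    def slope_scaled(self, factor: float) -> "GatingSpec":
        """Scale the slope factor (stretch the curve about its midpoint)."""
        return replace(self, ss_stretch=self.ss_stretch * float(factor))


@dataclass(frozen=True)
class CalciumGatingSpec:
    """Calcium-dependent gate (Hill function of intracellular [Ca2+] in uM)."""

    kd_um: float
    hill: float = 2.0
    tau_ms: float = 2.0
    power: int = 1

    def steady_state(self, ca_um):
        c = np.power(np.maximum(ca_um, 0.0), self.hill)
        return c / (c + self.kd_um**self.hill)


# ---------------------------------------------------------------------------
# Rate equations (classical cortical-family formulation)
# ---------------------------------------------------------------------------

def _vtrap(x, y):
    """x / (1 - exp(-x/y)) with the removable singularity at x = 0 filled in."""
    x = np.asarray(x, dtype=float)
    small = np.abs(x / y) < 1e-7
    safe = np.where(small, 1.0, x)
    return np.where(small, y * (1.0 + x / (2.0 * y)), safe / (1.0 - np.exp(-safe / y)))


def _rates(kind: str, vt: float, v):
    x = np.asarray(v, dtype=float) - vt
    if kind == "hh_na_m":
        alpha = 0.32 * _vtrap(x - 13.0, 4.0)
        beta = 0.28 * _vtrap(40.0 - x, 5.0)
    elif kind == "hh_na_h":
        alpha = 0.128 * np.exp(-(x - 17.0) / 18.0)
        beta = 4.0 / (1.0 + np.exp(-(x - 40.0) / 5.0))
    elif kind == "hh_kd_n":
        alpha = 0.032 * _vtrap(x - 15.0, 5.0)
        beta = 0.5 * np.exp(-(x - 10.0) / 40.0)
    else:
        raise ValueError(f"no rate equations for kind {kind!r}")
    return alpha, beta


def steady_state(gate: GatingSpec, v):
    """Steady-state open fraction of ``gate`` at membrane voltage ``v`` (mV).

    Honors accumulated shift and slope alterations; always in [0, 1] and
    monotone in ``v`` with the direction set by the sign of ``k``.
    """
    v = np.asarray(v, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("non-finite membrane voltage passed to steady_state")
    # shift, then stretch about the shifted midpoint
    u = gate.v_half + (v - gate.v_half - gate.ss_shift) / gate.ss_stretch
    if gate.kind == "boltzmann":
        inner = (1.0 - gate.a) / (1.0 + np.exp((u - gate.v_half) / gate.k)) + gate.a
        out = np.power(inner, gate.j)
    else:
        # the fitted persistent fraction is an artifact of the Boltzmann
        # parameterization; the classical rate curves carry no floor
        alpha, beta = _rates(gate.kind, gate.vt, u)
        out = alpha / (alpha + beta)
    out = np.asarray(out, dtype=float)
    return out if out.ndim else float(out)


def _tau_eval(kind: str, params, v):
    p = params
    v = np.asarray(v, dtype=float)
    if kind == "constant":
        return np.full_like(v, p[0])
    if kind == "bell":
        t_min, t_amp, v_peak, s_l, s_r = p
        return t_min + t_amp / (np.exp((v - v_peak) / s_r) + np.exp(-(v - v_peak) / s_l))
    if kind == "sigmoid":
        t_min, t_amp, v_mid, slope = p
        return t_min + t_amp / (1.0 + np.exp((v - v_mid) / slope))
    if kind in ("hh_na_m", "hh_na_h", "hh_kd_n"):
        alpha, beta = _rates(kind, p[0], v)
        return 1.0 / (alpha + beta)
    if kind == "m_current":
        tau_max = p[0]
        return tau_max / (3.3 * np.exp((v + 35.0) / 20.0) + np.exp(-(v + 35.0) / 20.0))
    raise ValueError(f"unknown tau kind {kind!r}")


def time_constant(gate: GatingSpec, v):
    """Time constant (ms) of ``gate`` at voltage ``v`` (mV), honoring ``v_shift``."""
    v = np.asarray(v, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("non-finite membrane voltage passed to time_constant")
    out = np.asarray(_tau_eval(gate.tau.kind, gate.tau.params, v - gate.tau.v_shift),
                     dtype=float)
    return out if out.ndim else float(out)
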