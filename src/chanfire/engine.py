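"""Fixed-step forward-Euler integration of the model ODEs.

The membrane equation is integrated per unit area (specific capacitance
1 uF/cm^2), so with conductance densities g in mS/cm^2 and the injected
current expressed as a density I[pA]/C_m[pF] in uA/cm^2,

    dV/dt = I_stim - sum_c g_c * x_act * x_inact * (V - E_c)      [mV/ms]

Gates relax as dx/dt = (x_inf(V) - x)/tau_x(V) and stay in [0, 1] by
construction (dt << tau everywhere).  The integrator is deliberately a fixed
time-step forward-Euler scheme (default dt = 0.01 ms); a dt-refinement test
documents the discretization error instead of an adaptive solver hiding it.

Model specs are compiled to packed parameter arrays consumed by a single
numba-jitted kernel.  Compilation merges currents whose reversal and gating
are identical (summing conductances) and de-duplicates identical gates, so an
unmutated heterozygous split integrates bit-identically to the unsplit model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from numba import njit

from .gating import SS_KINDS, TAU_KINDS, CalciumGatingSpec, GatingSpec
from .models import CA_REVERSAL, ModelSpec

__all__ = [
    "IntegratorConfig",
    "Trace",
    "IntegrationError",
    "CompiledModel",
    "compile_model",
    "NeuronSimulator",
    "SettleResult",
]

V_DIVERGE = 200.0  # |V| beyond this aborts with an integration failure


class IntegrationError(RuntimeError):
    pass


@dataclass(frozen=True)
class IntegratorConfig:
    """Fixed-step forward-Euler configuration."""

    dt: float = 0.01  # ms
    record_stride: int = 1  # keep every record_stride-th sample

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.record_stride < 1:
            raise ValueError("record_stride must be >= 1")


@dataclass
class Trace:
    """A recorded membrane trajectory."""

    time: np.ndarray  # ms
    voltage: np.ndarray  # mV
    stimulus: np.ndarray  # pA
    state: np.ndarray  # final state vector [V, gates..., Ca]
    dt: float

    def __post_init__(self):
        if not (len(self.time) == len(self.voltage) == len(self.stimulus)):
            raise ValueError("time/voltage/stimulus lengths differ")

    @property
    def ok(self) -> bool:
        return bool(np.all(np.isfinite(self.voltage)))

    def to_frame(self, stride: int = 1):
        """Columnar view (time_ms, stimulus_pa, voltage_mv) for text export."""
        import pandas as pd

        return pd.DataFrame({
            "time_ms": self.time[::stride],
            "stimulus_pa": self.stimulus[::stride],
            "voltage_mv": self.voltage[::stride],
        })


# ---------------------------------------------------------------------------
# Kernel
# ---------------------------------------------------------------------------
# gate rows (17 cols):
#   [0 mode (0 voltage / 1 calcium), 1 ss_kind, 2 v_half|kd, 3 k|hill, 4 j,
#    5 a, 6 vt, 7 ss_shift, 8 ss_stretch, 9 power,
#    10 tau_kind, 11..15 tau params, 16 tau_v_shift]
# current rows: [g, e_rev, act_idx, inact_idx, ca_rev, ca_flux] (6)
# ca row: [has_pool, k_influx, inv_tau, ca_rest, ca_out, rt2f] (6)
#
# Voltage-dependent steady states and time constants are tabulated once per
# compiled (possibly altered) gate on a fine voltage grid and linearly
# interpolated inside the kernel; the tables are built from the exact
# gating-module curves, so alteration semantics are baked in at compile time.

_GATE_COLS = 17
_CUR_COLS = 6

TAB_V0 = -150.0   # mV, lower edge of the lookup grid
TAB_DV = 0.05     # mV, grid spacing (sigmoid scales are >= 2 mV everywhere)
TAB_N = int(round((100.0 - TAB_V0) / TAB_DV)) + 1


@njit(cache=True, fastmath=True, inline="always")
def _ipow(x, p):
    if p == 1:
        return x
    if p == 2:
        return x * x
    if p == 3:
        return x * x * x
    if p == 4:
        x2 = x * x
        return x2 * x2
    return x**p


@njit(cache=True, fastmath=True)
def _vtrap(x, y):
    if abs(x / y) < 1e-7:
        return y * (1.0 + x / (2.0 * y))
    return x / (1.0 - np.exp(-x / y))


@njit(cache=True, fastmath=True)
def _rates_nb(kind, vt, v):
    x = v - vt
    if kind == 1:  # hh_na_m
        alpha = 0.32 * _vtrap(x - 13.0, 4.0)
        beta = 0.28 * _vtrap(40.0 - x, 5.0)
    elif kind == 2:  # hh_na_h
        alpha = 0.128 * np.exp(-(x - 17.0) / 18.0)
        beta = 4.0 / (1.0 + np.exp(-(x - 40.0) / 5.0))
    else:  # hh_kd_n
        alpha = 0.032 * _vtrap(x - 15.0, 5.0)
        beta = 0.5 * np.exp(-(x - 10.0) / 40.0)
    return alpha, beta


@njit(cache=True, fastmath=True)
def _tau_of(kind, p0, p1, p2, p3, p4, v):
    if kind == 0:
        return p0
    if kind == 1:  # bell: t_min,t_amp,v_peak,s_l,s_r
        return p0 + p1 / (np.exp((v - p2) / p4) + np.exp(-(v - p2) / p3))
    if kind == 2:  # sigmoid: t_min,t_amp,v_mid,slope
        return p0 + p1 / (1.0 + np.exp((v - p2) / p3))
    if kind == 3 or kind == 4 or kind == 5:  # rate-equation taus
        alpha, beta = _rates_nb(kind - 2, p0, v)
        return 1.0 / (alpha + beta)
    # kind == 6: m_current, p0 = tau_max
    return p0 / (3.3 * np.exp((v + 35.0) / 20.0) + np.exp(-(v + 35.0) / 20.0))


@njit(cache=True, fastmath=True)
def _kernel(gates, currs, ca, xinf_tab, tau_tab, tab_v0, tab_dv, tab_n,
            y, dt, n_steps, stim_kind, s_amp, s_half, t0, stride, v_out):
    """Advance ``y`` in place for n_steps; record V every ``stride`` steps.

    Returns (n_recorded, status); status 0 = ok, 1 = diverged.
    """
    n_g = gates.shape[0]
    n_c = currs.shape[0]
    has_pool = ca[0] > 0.5
    iw = 0
    for step in range(n_steps):
        v = y[0]
        if stim_kind == 0:
            istim = s_amp
        else:
            t = t0 + step * dt
            ph = t / s_half
            if ph > 2.0:
                ph = 2.0
            istim = s_amp * (ph if ph <= 1.0 else 2.0 - ph)
        cai = y[1 + n_g] if has_pool else 0.0

        itot = istim
        ica = 0.0
        for c in range(n_c):
            e = currs[c, 1]
            if currs[c, 4] > 0.5:  # calcium Nernst reversal
                cc = cai
                if cc < 1e-6:
                    cc = 1e-6
                e = ca[5] * np.log(ca[4] / cc)
            x = 1.0
            ai = int(currs[c, 2])
            if ai >= 0:
                x *= _ipow(y[1 + ai], int(gates[ai, 9]))
            ii = int(currs[c, 3])
            if ii >= 0:
                x *= _ipow(y[1 + ii], int(gates[ii, 9]))
            icur = currs[c, 0] * x * (v - e)
            itot -= icur
            if currs[c, 5] > 0.5:
                ica += icur

        # table index for the membrane voltage (clamped to the grid)
        pos = (v - tab_v0) / tab_dv
        if pos < 0.0:
            pos = 0.0
        elif pos > tab_n - 1.001:
            pos = tab_n - 1.001
        i0 = int(pos)
        w = pos - i0

        for gi in range(n_g):
            if gates[gi, 0] > 0.5:  # calcium-dependent gate
                kd = gates[gi, 2]
                hill = gates[gi, 3]
                cpow = cai**hill
                xinf = cpow / (cpow + kd**hill)
                tau = gates[gi, 11]
            else:
                xinf = xinf_tab[gi, i0] + w * (xinf_tab[gi, i0 + 1]
                                               - xinf_tab[gi, i0])
                tau = tau_tab[gi, i0] + w * (tau_tab[gi, i0 + 1]
                                             - tau_tab[gi, i0])
            y[1 + gi] += dt * (xinf - y[1 + gi]) / tau

        if has_pool:
            y[1 + n_g] += dt * (-ca[1] * ica - (cai - ca[3]) * ca[2])
            if y[1 + n_g] < 1e-6:
                y[1 + n_g] = 1e-6

        if step % stride == 0:
            v_out[iw] = v
            iw += 1
        v = v + dt * itot
        if not (-V_DIVERGE < v < V_DIVERGE):
            return iw, 1
        y[0] = v
    return iw, 0


# ---------------------------------------------------------------------------
# Compilation
# ---------------------------------------------------------------------------

@dataclass
class CompiledModel:
    """Packed parameter arrays and gate lookup tables for the kernel."""

    spec: ModelSpec
    gates: np.ndarray
    currents: np.ndarray
    ca: np.ndarray
    gate_names: tuple
    xinf_tab: np.ndarray = None
    tau_tab: np.ndarray = None

    @property
    def n_states(self) -> int:
        return 1 + self.gates.shape[0] + 1  # V, gates, Ca (always allocated)

    def initial_state(self, v0: Optional[float] = None) -> np.ndarray:
        from .gating import steady_state

        if v0 is None:
            v0 = self._resting_guess()
        y = np.empty(self.n_states)
        y[0] = v0
        for i, (_, gate) in enumerate(self.gate_names):
            if isinstance(gate, CalciumGatingSpec):
                ca0 = self.ca[3] if self.ca[0] > 0.5 else 0.0
                y[1 + i] = float(gate.steady_state(ca0))
            else:
                y[1 + i] = steady_state(gate, v0)
        y[-1] = self.ca[3] if self.ca[0] > 0.5 else 0.0
        return y

    def _resting_guess(self) -> float:
        for c in self.spec.currents:
            if c.base_name == "Leak" and isinstance(c.e_rev, float):
                return c.e_rev
        return -65.0


def _pack_gate(gate, row):
    if isinstance(gate, CalciumGatingSpec):
        row[0] = 1.0
        row[2] = gate.kd_um
        row[3] = gate.hill
        row[9] = float(gate.power)
        row[10] = 0.0  # constant tau
        row[11] = gate.tau_ms
        return
    row[0] = 0.0
    row[1] = float(SS_KINDS[gate.kind])
    row[2] = gate.v_half
    row[3] = gate.k
    row[4] = gate.j
    row[5] = gate.a
    row[6] = gate.vt
    row[7] = gate.ss_shift
    row[8] = gate.ss_stretch
    row[9] = float(gate.power)
    row[10] = float(TAU_KINDS[gate.tau.kind])
    params = gate.tau.params
    for i in range(5):
        row[11 + i] = params[i] if i < len(params) else 0.0
    row[16] = gate.tau.v_shift


def compile_model(spec: ModelSpec) -> CompiledModel:
    """Pack a model spec into kernel arrays.

    Zero-conductance currents are dropped; currents with identical reversal,
    gating and flags are merged by summing conductances; identical gates share
    one state variable.
    """
    merged = {}
    order = []
    for c in spec.currents:
        if c.g_max == 0.0:
            continue
        key = (c.e_rev, c.activation, c.inactivation, c.ca_flux)
        if key in merged:
            merged[key] += c.g_max
        else:
            merged[key] = c.g_max
            order.append((key, c))

    gate_index = {}
    gate_names = []

    def gid(owner, which, gate):
        if gate is None:
            return -1
        if gate not in gate_index:
            gate_index[gate] = len(gate_names)
            gate_names.append((f"{owner}.{which}", gate))
        return gate_index[gate]

    curr = np.zeros((len(order), _CUR_COLS))
    for i, (key, c) in enumerate(order):
        e_rev, act, inact, ca_flux = key
        curr[i, 0] = merged[key]
        curr[i, 1] = 0.0 if e_rev == CA_REVERSAL else float(e_rev)
        curr[i, 2] = gid(c.base_name, "act", act)
        curr[i, 3] = gid(c.base_name, "inact", inact)
        curr[i, 4] = 1.0 if e_rev == CA_REVERSAL else 0.0
        curr[i, 5] = 1.0 if ca_flux else 0.0

    gates = np.zeros((len(gate_names), _GATE_COLS))
    for i, (_, gate) in enumerate(gate_names):
        _pack_gate(gate, gates[i])

    pool = spec.calcium_pool
    ca = np.zeros(6)
    if pool is not None:
        ca[:] = (1.0, pool.k_influx, 1.0 / pool.tau_ms, pool.ca_rest,
                 pool.ca_out, pool.rt2f)

    # tabulate every voltage-dependent gate on the kernel's lookup grid;
    # the gating module is the single source of truth for the curves
    from .gating import steady_state as _ss, time_constant as _tc

    vgrid = TAB_V0 + TAB_DV * np.arange(TAB_N)
    xinf_tab = np.ones((len(gate_names), TAB_N))
    tau_tab = np.ones((len(gate_names), TAB_N))
    for i, (_, gate) in enumerate(gate_names):
        if isinstance(gate, CalciumGatingSpec):
            continue  # evaluated analytically from [Ca] in the kernel
        xinf_tab[i] = _ss(gate, vgrid)
        tau_tab[i] = _tc(gate, vgrid)

    return CompiledModel(spec=spec, gates=gates, currents=curr, ca=ca,
                         gate_names=tuple(gate_names), xinf_tab=xinf_tab,
                         tau_tab=tau_tab)


# ---------------------------------------------------------------------------
# Simulation driver
# ---------------------------------------------------------------------------

@dataclass
class SettleResult:
    state: np.ndarray
    settled: bool
    limit_cycle: bool
    v_rest: float


class NeuronSimulator:
    """Stateful driver: settle a model once, then run step/ramp protocols.

    All protocol runs start from the same settled zero-input state (one
    settling per model instance; re-settling per amplitude is equivalent for a
    settled fixed point and configurable by calling :meth:`settle` again).
    """

    def __init__(self, spec: ModelSpec, config: IntegratorConfig = IntegratorConfig()):
        self.spec = spec
        self.config = config
        self.compiled = compile_model(spec)
        self._settle: Optional[SettleResult] = None

    def _run(self, y, dt, n_steps, stim_kind, s_amp, s_half, t0, stride,
             v_out):
        c = self.compiled
        return _kernel(c.gates, c.currents, c.ca, c.xinf_tab, c.tau_tab,
                       TAB_V0, TAB_DV, TAB_N, y, dt, n_steps, stim_kind,
                       s_amp, s_half, t0, stride, v_out)

    # -- settling -----------------------------------------------------------

    def settle(self, max_ms: float = 3000.0, check_ms: float = 500.0,
               tol_mv: float = 0.01) -> SettleResult:
        """Relax to the zero-input steady state (or flag a limit cycle)."""
        dt = self.config.dt
        y = self.compiled.initial_state()
        n_chunk = int(round(check_ms / dt))
        v_out = np.empty(n_chunk)
        n_chunks = max(2, int(np.ceil(max_ms / check_ms)))
        spiked = False
        for _ in range(n_chunks):
            nrec, status = self._run(y, dt, n_chunk, 0, 0.0, 1.0, 0.0, 1,
                                     v_out)
            if status != 0:
                raise IntegrationError(
                    f"model {self.spec.model_id} diverged during settling"
                )
            vchunk = v_out[:nrec]
            if vchunk.max() - vchunk.min() > 20.0:
                spiked = True  # spontaneous large-amplitude oscillation
            elif vchunk.max() - vchunk.min() < tol_mv:
                self._settle = SettleResult(y.copy(), True, False, float(y[0]))
                return self._settle
        self._settle = SettleResult(y.copy(), not spiked, spiked, float(y[0]))
        return self._settle

    @property
    def settle_result(self) -> SettleResult:
        if self._settle is None:
            self.settle()
        return self._settle

    # -- protocols ----------------------------------------------------------

    def _density(self, amp_pa: float) -> float:
        return amp_pa / self.spec.c_m  # uA/cm^2

    def run_step(self, amp_pa: float, duration_ms: float) -> Trace:
        """Constant-current step from the settled state."""
        dt = self.config.dt
        stride = self.config.record_stride
        y = self.settle_result.state.copy()
        n_steps = int(round(duration_ms / dt))
        n_rec = (n_steps + stride - 1) // stride
        v_out = np.empty(n_rec)
        nrec, status = self._run(y, dt, n_steps, 0, self._density(amp_pa),
                                 1.0, 0.0, stride, v_out)
        if status != 0:
            raise IntegrationError(
                f"model {self.spec.model_id}: voltage diverged at step "
                f"amplitude {amp_pa} pA"
            )
        t = np.arange(nrec) * dt * stride
        stim = np.full(nrec, amp_pa)
        return Trace(time=t, voltage=v_out[:nrec], stimulus=stim, state=y, dt=dt)

    def run_ramp(self, half_ms: float = 2000.0,
                 peak_pa: Optional[float] = None) -> Trace:
        """Symmetric triangular ramp 0 -> peak -> 0 from the settled state."""
        dt = self.config.dt
        stride = self.config.record_stride
        if peak_pa is None:
            peak_pa = self.spec.i_max_pa
        y = self.settle_result.state.copy()
        n_steps = int(round(2.0 * half_ms / dt))
        n_rec = (n_steps + stride - 1) // stride
        v_out = np.empty(n_rec)
        nrec, status = self._run(y, dt, n_steps, 1, self._density(peak_pa),
                                 half_ms, 0.0, stride, v_out)
        if status != 0:
            raise IntegrationError(
                f"model {self.spec.model_id}: voltage diverged on the ramp"
            )
        t = np.arange(nrec) * dt * stride
        ph = np.minimum(t / half_ms, 2.0 - t / half_ms)
        stim = peak_pa * np.clip(ph, 0.0, 1.0)
        return Trace(time=t, voltage=v_out[:nrec], stimulus=stim, state=y, dt=dt)

    def any_spike(self, amp_pa: float, duration_ms: float,
                  chunk_ms: float = 250.0, prominence: float = 50.0) -> bool:
        """Early-exit spike query: integrate in chunks, stop at first spike."""
        from scipy.signal import find_peaks

        dt = self.config.dt
        y = self.settle_result.state.copy()
        n_total = int(round(duration_ms / dt))
        n_chunk = int(round(chunk_ms / dt))
        dist = max(1, int(round(1.0 / dt)))
        v_all = np.empty(0)
        done = 0
        buf = np.empty(min(n_chunk, n_total))
        while done < n_total:
            n = min(n_chunk, n_total - done)
            nrec, status = self._run(y, dt, n, 0, self._density(amp_pa),
                                     1.0, 0.0, 1, buf[:n])
            if status != 0:
                raise IntegrationError(
                    f"model {self.spec.model_id}: voltage diverged at "
                    f"{amp_pa} pA"
                )
            v_all = np.concatenate([v_all, buf[:nrec]])
            done += n
            peaks, _ = find_peaks(v_all, prominence=prominence, distance=dist)
            if len(peaks):
                return True
        return False
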