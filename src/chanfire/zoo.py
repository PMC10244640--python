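"""The twelve-model zoo: parameter tables for models A-L.

Three families of single-compartment, conductance-based models:

* **Cortical/thalamic family** (models B, C, D and their Kv1.1-extended
  variants E, G, H): regular-spiking inhibitory (B/E), fast-spiking (C/G) and
  regular-spiking pyramidal (D/H) cells in the Pospischil-style minimal
  Hodgkin-Huxley formulation (I_Na, I_Kd, I_M, leak, plus an inert
  high-threshold Ca current carried at zero conductance).  Steady-state gating
  uses the fitted modified-Boltzmann parameters; time constants come from the
  original alpha/beta rate equations with the family's spike-threshold
  adjustment VT.
* **Cerebellar stellate family** (A, F, J): I_Na, I_Kd, A-type K+, low-threshold
  Ca (T) and leak; F adds Kv1.1, J replaces the A-type current by Kv1.1.
* **Subthalamic nucleus (STN) family** (L, I, K): I_Na, I_Kd, A-type, L-type Ca,
  T-type Ca, Ca-activated K+ and leak with an intracellular calcium pool;
  I adds Kv1.1, K replaces the A-type current by Kv1.1.

Units: conductances are surface densities in mS/cm^2; membrane capacitance is
whole-cell pF at a specific capacitance of 1 uF/cm^2, so the cell area is
``C_m * 1e-6 cm^2`` and an injected current I[pA] corresponds to a current
density of ``I / C_m`` uA/cm^2.  Voltages in mV, time in ms.

The stellate- and STN-family time constants and reversal potentials (and the
Kv1.1 time constants) are reconstructions in the style of the source models of
those neuron types, parameterized as modified-Boltzmann steady states with
bell/sigmoid time constants; see docs/methods.md.
"""

from __future__ import annotations

from .gating import CalciumGatingSpec, GatingSpec, TauSpec

__all__ = ["MODEL_IDS", "MODEL_TABLE", "CONDUCTANCE_ROWS"]

MODEL_IDS = "ABCDEFGHIJKL"

# Rows of the published conductance/cell-property table, used for the
# programmatic audit that every tabulated cell lands in exactly one model field.
CONDUCTANCE_ROWS = ("Na", "Kd", "Kv1.1", "A", "M", "L", "T", "Ca_K", "Leak")


def _boltz(v_half, k, j=1.0, a=0.0, tau=("constant", (1.0,))):
    return GatingSpec(v_half=v_half, k=k, j=j, a=a, tau=TauSpec(tau[0], tau[1]))


#: Fitted modified-Boltzmann parameters of the cortical-family and Kv1.1
#: steady-state curves (midpoint mV, slope mV, exponent, persistent fraction).
#: For the rate-equation gates these are the published fits used as anchors
#: for slope alterations and for reporting.
FITTED_BOLTZMANN = {
    "cortical_Na_act": (-34.33054521, -8.21450277, 1.42295686, 0.0),
    "cortical_Na_inact": (-34.51951036, 4.04059373, 1.0, 0.05),
    "cortical_Kd_act": (-63.76096946, -13.83488194, 7.35347425, 0.0),
    "cortical_L_act": (-39.03684525, -5.57756176, 2.25190197, 0.0),
    "cortical_L_inact": (-57.37, 20.98, 1.0, 0.0),
    "cortical_M_act": (-45.0, -9.9998807337, 1.0, 0.0),
    "Kv11_act": (-30.01851852, -7.73333333, 1.0, 0.0),
    "Kv11_inact": (-46.85851852, 7.67266667, 1.0, 0.245),
}


# ---------------------------------------------------------------------------
# Shared gate definitions
# ---------------------------------------------------------------------------

def _cortical_gates(vt: float, tau_max_m: float) -> dict:
    """Cortical-family gates: classical rate-equation Na/Kd dynamics with the
    fitted Boltzmann midpoints as alteration anchors.

    ``vt`` is the family's spike-threshold adjustment entering the rate
    equations (steady states and time constants alike); ``tau_max_m`` the
    M-current maximal time constant (ms).
    """
    f = FITTED_BOLTZMANN
    return {
        "Na_act": GatingSpec(*f["cortical_Na_act"], kind="hh_na_m", vt=vt,
                             power=3, tau=TauSpec("hh_na_m", (vt,))),
        "Na_inact": GatingSpec(*f["cortical_Na_inact"], kind="hh_na_h", vt=vt,
                               power=1, tau=TauSpec("hh_na_h", (vt,))),
        "Kd_act": GatingSpec(*f["cortical_Kd_act"], kind="hh_kd_n", vt=vt,
                             power=4, tau=TauSpec("hh_kd_n", (vt,))),
        # High-threshold Ca (I_L) gating is tabulated for this family but the
        # conductance table assigns it no conductance; stored inert (g = 0).
        "L_act": _boltz(*f["cortical_L_act"],
                        tau=("bell", (1.0, 5.0, -30.0, 15.0, 15.0))),
        "L_inact": _boltz(*f["cortical_L_inact"],
                          tau=("bell", (100.0, 300.0, -50.0, 20.0, 20.0))),
        "M_act": _boltz(*f["cortical_M_act"],
                        tau=("m_current", (tau_max_m,))),
    }


def _kv11_gates() -> dict:
    """Kv1.1: fitted wild-type steady states; slow, partially persistent
    inactivation (persistent fraction a = 0.245)."""
    f = FITTED_BOLTZMANN
    return {
        "Kv11_act": _boltz(*f["Kv11_act"],
                           tau=("bell", (0.5, 8.0, -35.0, 15.0, 15.0))),
        "Kv11_inact": _boltz(*f["Kv11_inact"],
                             tau=("bell", (300.0, 3000.0, -50.0, 20.0, 20.0))),
    }


def _stellate_gates() -> dict:
    return {
        "Na_act": _boltz(-48.0, -3.5, j=3.0,
                         tau=("bell", (0.05, 0.3, -48.0, 10.0, 10.0))),
        "Na_inact": _boltz(-48.0, 6.0, j=1.0,
                           tau=("bell", (0.5, 10.0, -55.0, 12.0, 12.0))),
        "Kd_act": _boltz(-30.0, -13.0, j=4.0,
                         tau=("bell", (0.5, 4.0, -35.0, 20.0, 20.0))),
        "A_act": _boltz(-30.0, -9.0, j=1.0,
                        tau=("bell", (0.3, 2.0, -45.0, 15.0, 15.0))),
        "A_inact": _boltz(-75.0, 7.0, j=1.0,
                          tau=("bell", (10.0, 50.0, -70.0, 15.0, 15.0))),
        "T_act": _boltz(-58.0, -5.0, j=2.0,
                        tau=("bell", (1.0, 8.0, -60.0, 12.0, 12.0))),
        "T_inact": _boltz(-82.0, 5.0, j=1.0,
                          tau=("bell", (15.0, 60.0, -80.0, 12.0, 12.0))),
    }


def _stn_gates() -> dict:
    return {
        "Na_act": _boltz(-42.0, -5.0, j=3.0,
                         tau=("bell", (0.2, 2.0, -53.0, 15.0, 15.0))),
        "Na_inact": _boltz(-45.5, 6.4, j=1.0,
                           tau=("bell", (0.5, 24.5, -50.0, 15.0, 16.0))),
        "Kd_act": _boltz(-38.0, -10.0, j=4.0,
                         tau=("bell", (0.5, 11.0, -40.0, 50.0, 40.0))),
        "A_act": _boltz(-45.0, -14.7, j=2.0,
                        tau=("sigmoid", (1.0, 1.0, -40.0, 0.5))),
        "A_inact": _boltz(-90.0, 7.5, j=1.0,
                          tau=("bell", (1.0, 60.0, -65.0, 15.0, 15.0))),
        "CaL_act": _boltz(-25.0, -6.0, j=2.0,
                          tau=("bell", (1.0, 10.0, -20.0, 15.0, 15.0))),
        "CaL_inact": _boltz(-60.0, 7.5, j=1.0,
                            tau=("bell", (30.0, 300.0, -50.0, 20.0, 20.0))),
        "T_act": _boltz(-44.0, -6.7, j=2.0, tau=("constant", (5.0,))),
        "T_inact": _boltz(-85.0, 5.8, j=1.0,
                          tau=("bell", (20.0, 150.0, -70.0, 15.0, 15.0))),
        "CaK_act": CalciumGatingSpec(kd_um=2.0, hill=2.0, tau_ms=2.0),
    }


# ---------------------------------------------------------------------------
# Per-model tables
# ---------------------------------------------------------------------------
# Each entry: label, family, c_m (pF), i_max (pA), conductances (mS/cm^2),
# reversal potentials (mV) and family kinetics parameters.

_CORTICAL_EREV = {"Na": 50.0, "K": -90.0, "Ca": 120.0}
_STELLATE_EREV = {"Na": 55.0, "K": -88.0, "Ca": 120.0, "Leak": -70.0}
_STN_EREV = {"Na": 60.0, "K": -90.0, "Leak": -65.0}

MODEL_TABLE = {
    "A": dict(label="Cb stellate", family="stellate", c_m=177.83, i_max=1000.0,
              g=dict(Na=3.4, Kd=9.0556, A=15.0159, T=0.45045, Leak=0.07407),
              e_rev=_STELLATE_EREV),
    "B": dict(label="RS inhibitory", family="cortical", c_m=119.99, i_max=350.0,
              g=dict(Na=10.0, Kd=2.1, M=0.0098, L=0.0, Leak=0.0205),
              e_rev={"Na": 50.0, "K": -80.0, "Ca": 120.0, "Leak": -67.0}, vt=-67.9, tau_max_m=934.0),
    "C": dict(label="FS", family="cortical", c_m=101.71, i_max=1000.0,
              g=dict(Na=58.0, Kd=3.9, M=0.075, L=0.0, Leak=0.038),
              e_rev={**_CORTICAL_EREV, "Leak": -70.4}, vt=-57.9, tau_max_m=502.0),
    "D": dict(label="RS pyramidal", family="cortical", c_m=118.44, i_max=1000.0,
              g=dict(Na=56.0, Kd=6.0, M=0.075, L=0.0, Leak=0.0205),
              e_rev={**_CORTICAL_EREV, "Leak": -70.3}, vt=-56.2, tau_max_m=608.0),
    "E": dict(label="RS inhibitory +Kv1.1", family="cortical", c_m=119.99,
              i_max=350.0,
              g={"Na": 10.0, "Kd": 1.89, "Kv1.1": 0.21, "M": 0.0098, "L": 0.0,
                 "Leak": 0.0205},
              e_rev={"Na": 50.0, "K": -80.0, "Ca": 120.0, "Leak": -67.0}, vt=-67.9, tau_max_m=934.0),
    "F": dict(label="Cb stellate +Kv1.1", family="stellate", c_m=177.83,
              i_max=1000.0,
              g={"Na": 3.4, "Kd": 8.15, "Kv1.1": 0.90556, "A": 15.0159,
                 "T": 0.45045, "Leak": 0.07407},
              e_rev=_STELLATE_EREV),
    "G": dict(label="FS +Kv1.1", family="cortical", c_m=101.71, i_max=1000.0,
              g={"Na": 58.0, "Kd": 3.51, "Kv1.1": 0.39, "M": 0.075, "L": 0.0,
                 "Leak": 0.038},
              e_rev={**_CORTICAL_EREV, "Leak": -70.4}, vt=-57.9, tau_max_m=502.0),
    "H": dict(label="RS pyramidal +Kv1.1", family="cortical", c_m=118.44,
              i_max=1000.0,
              g={"Na": 56.0, "Kd": 5.4, "Kv1.1": 0.6, "M": 0.075, "L": 0.0,
                 "Leak": 0.0205},
              e_rev={**_CORTICAL_EREV, "Leak": -70.3}, vt=-56.2, tau_max_m=608.0),
    "I": dict(label="STN +Kv1.1", family="stn", c_m=118.44, i_max=1000.0,
              g={"Na": 49.0, "Kd": 56.43, "Kv1.1": 0.57, "A": 5.0, "L": 5.0,
                 "T": 5.0, "Ca_K": 1.0, "Leak": 0.035},
              e_rev=_STN_EREV),
    "J": dict(label="Cb stellate dKv1.1", family="stellate", c_m=177.83,
              i_max=1000.0,
              g={"Na": 3.4, "Kd": 9.0556, "Kv1.1": 1.50159, "T": 0.45045,
                 "Leak": 0.07407},
              e_rev=_STELLATE_EREV),
    "K": dict(label="STN dKv1.1", family="stn", c_m=118.44, i_max=1000.0,
              g={"Na": 49.0, "Kd": 57.0, "Kv1.1": 0.5, "L": 5.0, "T": 5.0,
                 "Ca_K": 1.0, "Leak": 0.035},
              e_rev=_STN_EREV),
    "L": dict(label="STN", family="stn", c_m=118.44, i_max=1000.0,
              g={"Na": 49.0, "Kd": 57.0, "A": 5.0, "L": 5.0, "T": 5.0,
                 "Ca_K": 1.0, "Leak": 0.035},
              e_rev=_STN_EREV),
}

FAMILY_GATES = {
    "stellate": _stellate_gates,
    "stn": _stn_gates,
}


def cortical_gates(vt: float, tau_max_m: float) -> dict:
    return _cortical_gates(vt, tau_max_m)


def kv11_gates() -> dict:
    return _kv11_gates()
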