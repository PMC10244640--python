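"""Model specifications and parameter-perturbation mechanics.

A :class:`ModelSpec` is a declarative description of one single-compartment
conductance-based neuron: capacitance, a list of ionic currents with maximal
conductances, reversal potentials and gating specs, and (for the STN family)
an intracellular calcium pool.  Specs are immutable; perturbations
(:func:`apply_alteration`, :func:`heterozygous_split`, and the mutation
machinery built on top of them) return new specs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Union

import yaml

from . import zoo
from .gating import CalciumGatingSpec, GatingSpec, TauSpec

__all__ = [
    "CurrentSpec",
    "CalciumPool",
    "ModelSpec",
    "Alteration",
    "build_model",
    "apply_alteration",
    "heterozygous_split",
    "conductance_table",
    "model_to_yaml",
    "model_from_yaml",
    "MODEL_IDS",
]

MODEL_IDS = zoo.MODEL_IDS

#: Reversal marker for currents whose reversal follows the Nernst potential of
#: the intracellular calcium pool.
CA_REVERSAL = "ca"


@dataclass(frozen=True)
class CurrentSpec:
    """One ionic current: maximal conductance, reversal, and up to two gates."""

    name: str
    g_max: float  # mS/cm^2
    e_rev: Union[float, str]  # mV, or CA_REVERSAL for the calcium Nernst rule
    activation: Optional[Union[GatingSpec, CalciumGatingSpec]] = None
    inactivation: Optional[GatingSpec] = None
    ca_flux: bool = False  # current feeds the intracellular calcium pool

    def __post_init__(self):
        if self.g_max < 0:
            raise ValueError(f"negative conductance for {self.name}")

    @property
    def base_name(self) -> str:
        """Current name without a heterozygous-split suffix."""
        return self.name.split("/")[0]


@dataclass(frozen=True)
class CalciumPool:
    """First-order intracellular calcium dynamics (concentrations in uM).

    d[Ca]/dt = -k_influx * I_Ca - ([Ca] - ca_rest) / tau_ms, with the calcium
    reversal potential from the Nernst equation E_Ca = rt2f * ln(ca_out/[Ca]).
    """

    k_influx: float = 0.0002  # uM cm^2 / (uA ms)
    tau_ms: float = 100.0
    ca_rest: float = 0.05
    ca_out: float = 2000.0
    rt2f: float = 13.0  # mV


@dataclass(frozen=True)
class ModelSpec:
    model_id: str
    label: str
    c_m: float  # pF (1 uF/cm^2 x membrane area)
    currents: tuple
    calcium_pool: Optional[CalciumPool] = None
    i_max_pa: float = 1000.0  # upper end of the step/ramp stimulus range (pA)

    def current(self, name: str) -> CurrentSpec:
        for c in self.currents:
            if c.name == name:
                return c
        raise KeyError(
            f"model {self.model_id} has no current {name!r} "
            f"(has: {[c.name for c in self.currents]})"
        )

    def has_current(self, name: str) -> bool:
        return any(c.name == name or c.base_name == name for c in self.currents)

    @property
    def area_cm2(self) -> float:
        return self.c_m * 1e-6

    def with_currents(self, currents) -> "ModelSpec":
        return replace(self, currents=tuple(currents))


@dataclass(frozen=True)
class Alteration:
    """A single parameter perturbation.

    ``property`` is one of ``v_half_shift`` (amount in mV, applied to the gate
    and to its tau curve along the voltage axis), ``slope_scale``
    (dimensionless factor on the signed slope k), or ``conductance_scale``
    (dimensionless factor on g_max; ``target_gate`` must be None).
    """

    target_current: str
    property: str  # v_half_shift | slope_scale | conductance_scale
    amount: float
    target_gate: Optional[str] = None  # "activation" | "inactivation" | None

    def __post_init__(self):
        if self.property not in ("v_half_shift", "slope_scale", "conductance_scale"):
            raise ValueError(f"unknown alteration property {self.property!r}")
        if self.property == "conductance_scale":
            if self.target_gate is not None:
                raise ValueError("conductance_scale carries target_gate=None")
        elif self.target_gate not in ("activation", "inactivation"):
            raise ValueError(f"{self.property} needs target_gate activation|inactivation")

    @property
    def magnitude(self) -> float:
        """Alteration size on its natural axis: mV for shifts, log2 for scales."""
        import math

        if self.property == "v_half_shift":
            return self.amount
        return math.log2(self.amount)


# ---------------------------------------------------------------------------
# Model construction
# ---------------------------------------------------------------------------

def _gate(gates: dict, key: str):
    return gates.get(key)


def build_model(model_id: str) -> ModelSpec:
    """Construct the fully parameterized model for a letter id A-L."""
    model_id = str(model_id).upper()
    if model_id not in zoo.MODEL_TABLE:
        raise KeyError(
            f"unknown model id {model_id!r}; valid ids: {', '.join(zoo.MODEL_IDS)}"
        )
    entry = zoo.MODEL_TABLE[model_id]
    family = entry["family"]
    e = entry["e_rev"]
    g = entry["g"]

    if family == "cortical":
        gates = zoo.cortical_gates(entry["vt"], entry["tau_max_m"])
    else:
        gates = zoo.FAMILY_GATES[family]()
    kv = zoo.kv11_gates()

    currents = []

    def add(name, gname_act=None, gname_inact=None, e_rev=None, ca_flux=False,
            gate_source=None):
        if name not in g:
            return
        src = gate_source if gate_source is not None else gates
        currents.append(CurrentSpec(
            name=name,
            g_max=g[name],
            e_rev=e_rev,
            activation=_gate(src, gname_act) if gname_act else None,
            inactivation=_gate(src, gname_inact) if gname_inact else None,
            ca_flux=ca_flux,
        ))

    add("Na", "Na_act", "Na_inact", e_rev=e["Na"])
    add("Kd", "Kd_act", None, e_rev=e["K"])
    add("Kv1.1", "Kv11_act", "Kv11_inact", e_rev=e["K"], gate_source=kv)
    add("A", "A_act", "A_inact", e_rev=e["K"])
    add("M", "M_act", None, e_rev=e["K"])
    pool = None
    if family == "stn":
        pool = CalciumPool()
        add("L", "CaL_act", "CaL_inact", e_rev=CA_REVERSAL, ca_flux=True)
        add("T", "T_act", "T_inact", e_rev=CA_REVERSAL, ca_flux=True)
        add("Ca_K", "CaK_act", None, e_rev=e["K"])
    else:
        add("L", "L_act", "L_inact", e_rev=e.get("Ca", 120.0))
        add("T", "T_act", "T_inact", e_rev=e.get("Ca", 120.0))
    add("Leak", e_rev=e["Leak"])

    return ModelSpec(
        model_id=model_id,
        label=entry["label"],
        c_m=entry["c_m"],
        currents=tuple(currents),
        calcium_pool=pool,
        i_max_pa=entry["i_max"],
    )


# ---------------------------------------------------------------------------
# Perturbations
# ---------------------------------------------------------------------------

def apply_alteration(m: ModelSpec, alt: Alteration) -> ModelSpec:
    """Return a new spec with one parameter perturbed.

    A half-activation shift also translates the gate's time-constant curve
    along the voltage axis; slope scaling preserves the sign of k; conductance
    scaling touches g_max only.  Raises ``KeyError`` if the model lacks the
    target current so that sweep drivers can skip inapplicable combinations.
    """
    if not m.has_current(alt.target_current):
        raise KeyError(
            f"model {m.model_id} has no current {alt.target_current!r}; "
            "alteration not applicable"
        )
    new_currents = []
    for c in m.currents:
        if c.base_name != alt.target_current:
            new_currents.append(c)
            continue
        if alt.property == "conductance_scale":
            new_currents.append(replace(c, g_max=c.g_max * alt.amount))
            continue
        gate_attr = alt.target_gate
        gate = getattr(c, gate_attr)
        if gate is None or isinstance(gate, CalciumGatingSpec):
            raise KeyError(
                f"current {alt.target_current!r} of model {m.model_id} has no "
                f"voltage-dependent {gate_attr} gate"
            )
        if alt.property == "v_half_shift":
            gate = gate.shifted(alt.amount)
        else:  # slope_scale
            gate = gate.slope_scaled(alt.amount)
        new_currents.append(replace(c, **{gate_attr: gate}))
    return m.with_currents(new_currents)


def heterozygous_split(m: ModelSpec, current_name: str) -> ModelSpec:
    """Replace ``current_name`` by two half-conductance copies.

    The copies (suffixed ``/wt`` and ``/mut``) carry identical gating, so the
    unmutated split model produces exactly the same total membrane current as
    the original at every voltage; mutation effects are then applied to the
    ``/mut`` half only.
    """
    if not m.has_current(current_name):
        raise KeyError(
            f"model {m.model_id} has no current {current_name!r} to split"
        )
    new_currents = []
    for c in m.currents:
        if c.name != current_name:
            new_currents.append(c)
            continue
        half = c.g_max / 2.0
        new_currents.append(replace(c, name=f"{c.name}/wt", g_max=half))
        new_currents.append(replace(c, name=f"{c.name}/mut", g_max=half))
    return m.with_currents(new_currents)


# ---------------------------------------------------------------------------
# Tabulation & serialization
# ---------------------------------------------------------------------------

def conductance_table():
    """Maximal conductances, tau_max,M and capacitance of all models.

    Returns a pandas DataFrame with one column per model (A-L) and one row per
    conductance plus ``tau_max_M`` and ``C_m``; absent currents are NaN.
    Mirrors the published cell-properties table.
    """
    import numpy as np
    import pandas as pd

    rows = list(zoo.CONDUCTANCE_ROWS) + ["tau_max_M", "C_m"]
    data = {}
    for mid in zoo.MODEL_IDS:
        entry = zoo.MODEL_TABLE[mid]
        col = {}
        for r in zoo.CONDUCTANCE_ROWS:
            gval = entry["g"].get(r, np.nan)
            # the zero-conductance inert current is not a tabulated cell
            col[r] = np.nan if (r == "L" and gval == 0.0) else gval
        col["tau_max_M"] = entry.get("tau_max_m", np.nan)
        col["C_m"] = entry["c_m"]
        data[mid] = col
    return pd.DataFrame(data, index=rows, columns=list(zoo.MODEL_IDS))


def _gate_to_dict(gate):
    if gate is None:
        return None
    if isinstance(gate, CalciumGatingSpec):
        return {"calcium": {"kd_um": gate.kd_um, "hill": gate.hill,
                            "tau_ms": gate.tau_ms, "power": gate.power}}
    return {
        "v_half": gate.v_half, "k": gate.k, "j": gate.j, "a": gate.a,
        "kind": gate.kind, "vt": gate.vt, "power": gate.power,
        "ss_shift": gate.ss_shift, "ss_stretch": gate.ss_stretch,
        "tau": {"kind": gate.tau.kind, "params": list(gate.tau.params),
                "v_shift": gate.tau.v_shift},
    }


def _gate_from_dict(d):
    if d is None:
        return None
    if "calcium" in d:
        return CalciumGatingSpec(**d["calcium"])
    tau = TauSpec(d["tau"]["kind"], tuple(d["tau"]["params"]),
                  d["tau"].get("v_shift", 0.0))
    return GatingSpec(
        v_half=d["v_half"], k=d["k"], j=d["j"], a=d["a"],
        kind=d.get("kind", "boltzmann"), vt=d.get("vt", 0.0),
        power=d.get("power", 1), ss_shift=d.get("ss_shift", 0.0),
        ss_stretch=d.get("ss_stretch", 1.0), tau=tau,
    )


def model_to_yaml(m: ModelSpec) -> str:
    """Serialize a model spec to a plain-text YAML document."""
    doc = {
        "model_id": m.model_id,
        "label": m.label,
        "c_m_pF": m.c_m,
        "i_max_pA": m.i_max_pa,
        "currents": [
            {
                "name": c.name,
                "g_max": c.g_max,
                "e_rev": c.e_rev,
                "ca_flux": c.ca_flux,
                "activation": _gate_to_dict(c.activation),
                "inactivation": _gate_to_dict(c.inactivation),
            }
            for c in m.currents
        ],
        "calcium_pool": None if m.calcium_pool is None else {
            "k_influx": m.calcium_pool.k_influx,
            "tau_ms": m.calcium_pool.tau_ms,
            "ca_rest": m.calcium_pool.ca_rest,
            "ca_out": m.calcium_pool.ca_out,
            "rt2f": m.calcium_pool.rt2f,
        },
    }
    return yaml.safe_dump(doc, sort_keys=False)


def model_from_yaml(text: str, validate: bool = True) -> ModelSpec:
    """Load a model spec from YAML.

    With ``validate=True`` and a registry id A-L, the loaded spec must equal
    the registry entry (guards hand-edited configs against table drift).
    """
    doc = yaml.safe_load(text)
    currents = tuple(
        CurrentSpec(
            name=c["name"], g_max=c["g_max"], e_rev=c["e_rev"],
            ca_flux=c.get("ca_flux", False),
            activation=_gate_from_dict(c.get("activation")),
            inactivation=_gate_from_dict(c.get("inactivation")),
        )
        for c in doc["currents"]
    )
    pool = doc.get("calcium_pool")
    spec = ModelSpec(
        model_id=doc["model_id"], label=doc["label"], c_m=doc["c_m_pF"],
        currents=currents,
        calcium_pool=None if pool is None else CalciumPool(**pool),
        i_max_pa=doc["i_max_pA"],
    )
    if validate and spec.model_id in zoo.MODEL_TABLE:
        ref = build_model(spec.model_id)
        if spec != ref:
            raise ValueError(
                f"loaded spec for model {spec.model_id} deviates from the "
                "registry parameter tables"
            )
    return spec
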