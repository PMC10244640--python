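"""Heterozygous Kv1.1 mutation panels across the model zoo.

A mutation is described by three biophysical effect sizes relative to wild
type: relative current amplitude (``amp_rel``, wild type 1), relative
activation slope factor (``k_rel``, wild type 1), and an absolute activation
half-maximal-voltage shift (``dv_half`` in mV, wild type 0).  Heterozygosity
is modeled by splitting the Kv1.1 conductance into two equal halves and
applying the mutation effects to one half only; when the model also carries
an A-type current the same effects are applied to half of it as well (both
are inactivating potassium currents affected alike).  Amplitude is
implemented as conductance scaling of the mutant half: at fixed driving
force, current amplitude and conductance are proportional.

Each (model, mutation) pair is characterized through the full firing
pipeline and contrasted against its wild type (Δrheobase, normalized ΔAUC,
firing-change quadrant).  Pairwise Kendall correlations between the
per-mutation effect vectors of two models quantify how consistently a
mutation panel acts across neuron types.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .engine import IntegrationError, IntegratorConfig, NeuronSimulator
from .metrics import NonFiringError, characterize, classify_firing_change
from .models import ModelSpec, build_model, heterozygous_split
from .protocols import FiringProtocol
from .sensitivity import kendall_tau

__all__ = [
    "MutationEffect",
    "KV11_MODELS",
    "apply_mutation",
    "run_panel",
    "pairwise_model_correlations",
    "read_panel",
    "write_panel",
]

#: Models carrying a Kv1.1 current (the mutation panel's default scope).
KV11_MODELS = ("E", "F", "G", "H", "I", "J", "K")

#: Identity (wild-type) effect, prepended to panels as a control.
WT_EFFECT_NAME = "WT"


@dataclass(frozen=True)
class MutationEffect:
    name: str
    amp_rel: float = 1.0   # relative current amplitude, >= 0
    k_rel: float = 1.0     # relative activation slope factor, > 0
    dv_half: float = 0.0   # activation V1/2 shift (mV)

    def __post_init__(self):
        if self.amp_rel < 0:
            raise ValueError("relative amplitude must be >= 0")
        if self.k_rel <= 0:
            raise ValueError("relative slope factor must be > 0")

    @property
    def is_identity(self) -> bool:
        return self.amp_rel == 1.0 and self.k_rel == 1.0 and self.dv_half == 0.0


def _mutate_half(current, eff: MutationEffect):
    """Apply the mutation descriptors to one (half-conductance) current."""
    act = current.activation
    if act is None:
        raise KeyError(f"current {current.name!r} has no activation gate")
    act = act.shifted(eff.dv_half).slope_scaled(eff.k_rel)
    return replace(current, g_max=current.g_max * eff.amp_rel, activation=act)


def apply_mutation(m: ModelSpec, eff: MutationEffect,
                   include_a: bool = True) -> ModelSpec:
    """Heterozygous application of ``eff`` to Kv1.1 (and I_A when present).

    The Kv1.1 (and optionally A-type) conductance is split into equal wild
    type and mutant halves; the mutant halves get ``g * amp_rel / 2``, the
    activation slope scaled by ``k_rel`` and the activation V1/2 shifted by
    ``dv_half`` (with the time-constant curve translated along the voltage
    axis).  Models without Kv1.1 are inapplicable and raise ``KeyError``.
    """
    if not m.has_current("Kv1.1"):
        raise KeyError(
            f"model {m.model_id} carries no Kv1.1 current; "
            "mutation panel not applicable"
        )
    targets = ["Kv1.1"]
    if include_a and m.has_current("A"):
        targets.append("A")
    out = m
    for name in targets:
        out = heterozygous_split(out, name)
        new_currents = []
        for c in out.currents:
            if c.name == f"{name}/mut":
                c = _mutate_half(c, eff)
            new_currents.append(c)
        out = out.with_currents(new_currents)
    return out


def run_panel(models: Sequence = KV11_MODELS,
              panel: Sequence[MutationEffect] = (),
              proto: Optional[FiringProtocol] = None,
              metrics: Sequence[str] = ("rheobase", "auc"),
              include_a: bool = True,
              config: Optional[IntegratorConfig] = None) -> pd.DataFrame:
    """Characterize every (model, mutation) pair.

    Returns one row per pair with Δrheobase (pA), normalized ΔAUC (and as a
    percentage), the firing-change quadrant, and exclusion bookkeeping.  The
    wild-type control row is included for every model and is exactly
    (0, 0, unchanged).  Per-row failures are recorded, never raised.
    """
    if proto is None:
        from .protocols import full_protocol

        proto = full_protocol()
    if config is None:
        config = IntegratorConfig(dt=proto.dt)
    panel = list(panel)
    if not any(e.is_identity for e in panel):
        panel = [MutationEffect(WT_EFFECT_NAME)] + panel
    rows = []
    for model in models:
        spec = build_model(model) if isinstance(model, str) else model
        wt = _characterize(spec, proto, metrics, config)
        for eff in panel:
            if eff.is_identity:
                pt = dict(wt)  # the identity mutation is bitwise the wild type
            else:
                mutated = apply_mutation(spec, eff, include_a=include_a)
                pt = _characterize(mutated, proto, metrics, config)
            row = dict(model_id=spec.model_id, mutation=eff.name,
                       amp_rel=eff.amp_rel, k_rel=eff.k_rel,
                       dv_half=eff.dv_half,
                       rheobase_pa=pt["rheobase_pa"], auc=pt["auc"],
                       d_rheobase_pa=np.nan, d_auc_norm=np.nan,
                       pct_auc_change=np.nan, quadrant="",
                       excluded=pt["excluded"] or wt["excluded"],
                       reason=pt["reason"] or wt["reason"])
            if not row["excluded"]:
                d_rheo = pt["rheobase_pa"] - wt["rheobase_pa"]
                row["d_rheobase_pa"] = d_rheo
                if "auc" in metrics:
                    if wt["auc"] > 0:
                        d_auc = (pt["auc"] - wt["auc"]) / wt["auc"]
                        row["d_auc_norm"] = d_auc
                        row["pct_auc_change"] = 100.0 * d_auc
                        row["quadrant"] = classify_firing_change(d_rheo, d_auc)
                    else:
                        row["excluded"] = True
                        row["reason"] = "zero_wt_auc"
                else:
                    row["quadrant"] = classify_firing_change(d_rheo, 0.0)
            rows.append(row)
    return pd.DataFrame(rows)


def pairwise_model_correlations(results: pd.DataFrame,
                                include_control: bool = False):
    """Model-by-model Kendall-tau matrices of mutation effects.

    Entry (i, j) is the Kendall correlation between the two models'
    per-mutation effect vectors; returns ``(tau_rheobase, tau_auc)``
    DataFrames (symmetric, unit diagonal, NaN where undefined).  The
    wild-type control row is dropped unless ``include_control``.
    """
    df = results
    if not include_control:
        df = df[~((df.amp_rel == 1.0) & (df.k_rel == 1.0) & (df.dv_half == 0.0))]
    df = df[~df.excluded]
    models = sorted(df.model_id.unique())
    mats = {}
    for col in ("d_rheobase_pa", "d_auc_norm"):
        mat = pd.DataFrame(np.eye(len(models)), index=models, columns=models)
        for i, mi in enumerate(models):
            vi = df[df.model_id == mi].set_index("mutation")[col]
            for j, mj in enumerate(models):
                if j <= i:
                    continue
                vj = df[df.model_id == mj].set_index("mutation")[col]
                common = vi.index.intersection(vj.index)
                tau = kendall_tau(vi.loc[common], vj.loc[common]) \
                    if len(common) >= 2 else float("nan")
                mat.iloc[i, j] = mat.iloc[j, i] = tau
        mats[col] = mat
    return mats["d_rheobase_pa"], mats["d_auc_norm"]


def _characterize(spec: ModelSpec, proto, metrics, config) -> dict:
    sim = NeuronSimulator(spec, config)
    try:
        fm = characterize(sim, proto, need=tuple(metrics))
    except NonFiringError:
        return dict(rheobase_pa=np.nan, auc=np.nan, excluded=True,
                    reason="non_firing")
    except IntegrationError as err:
        return dict(rheobase_pa=np.nan, auc=np.nan, excluded=True,
                    reason=f"integration_failure: {err}")
    excluded = bool(fm.burst_flag)
    return dict(rheobase_pa=fm.rheobase_pa, auc=fm.auc, excluded=excluded,
                reason="bursting" if excluded else "")


# ---------------------------------------------------------------------------
# Panel file IO (columnar text: name, amp_rel, k_rel, dv_half_mV)
# ---------------------------------------------------------------------------

def write_panel(path, panel: Sequence[MutationEffect]) -> None:
    df = pd.DataFrame([dict(name=e.name, amp_rel=e.amp_rel, k_rel=e.k_rel,
                            dv_half_mV=e.dv_half) for e in panel])
    df.to_csv(path, sep="\t", index=False)


def read_panel(path) -> list:
    df = pd.read_csv(path, sep="\t")
    required = {"name", "amp_rel", "k_rel", "dv_half_mV"}
    if not required.issubset(df.columns):
        raise ValueError(f"panel file needs columns {sorted(required)}")
    return [MutationEffect(str(r["name"]), float(r.amp_rel), float(r.k_rel),
                           float(r.dv_half_mV)) for _, r in df.iterrows()]
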