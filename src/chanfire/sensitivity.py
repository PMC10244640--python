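"""One-factor-at-a-time sensitivity analysis across the model zoo.

For each model and each targeted current property, a single parameter is
swept while everything else stays at baseline: half-activation voltages are
shifted from -10 to +10 mV in 1 mV increments (21 values), and slope factors
and maximal conductances are scaled over 21 factors spaced equally on a log2
axis between 0.5 and 2.  Each grid point is characterized (rheobase, fI-curve
AUC) and contrasted against the unaltered model:

    normalized dAUC = (AUC_i - AUC_wt) / AUC_wt,     dRheobase = rheo_i - rheo_wt.

Per (model, current, gate, property) the relationship between alteration
magnitude and contrast is summarized by the Kendall rank correlation tau
(tau-b, tie-corrected): +1/-1 for strictly monotone relationships, near 0 for
flat or non-monotone ones.  Correlations use the alteration magnitude on its
natural axis (mV for shifts, log2 factor for scalings); Kendall tau is
invariant under monotone axis transforms, so the choice is inessential.

Grid points where the altered model never fires steadily, bursts, or has an
undefined contrast are excluded pairwise from the correlation with their
reason recorded — never silently dropped.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .engine import IntegrationError, IntegratorConfig, NeuronSimulator
from .metrics import NonFiringError, characterize
from .models import Alteration, ModelSpec, apply_alteration, build_model
from .protocols import FiringProtocol

__all__ = [
    "AlterationGrid",
    "OATResult",
    "build_grids",
    "shift_grid",
    "factor_grid",
    "normalized_delta_auc",
    "kendall_tau",
    "run_oat",
    "DEFAULT_TARGETS",
]

#: The current properties common to (most of) the zoo, as swept by default:
#: (current, gate, property).  The leak current has no gates, so only its
#: conductance is scaled; combinations absent from a model are skipped and
#: marked inapplicable.
DEFAULT_TARGETS = tuple(
    [("Na", g, p) for g in ("activation", "inactivation")
     for p in ("v_half_shift", "slope_scale")]
    + [("Na", None, "conductance_scale")]
    + [("Kd", "activation", p) for p in ("v_half_shift", "slope_scale")]
    + [("Kd", None, "conductance_scale")]
    + [(c, g, p) for c in ("Kv1.1", "A") for g in ("activation", "inactivation")
       for p in ("v_half_shift", "slope_scale")]
    + [(c, None, "conductance_scale") for c in ("Kv1.1", "A")]
    + [("Leak", None, "conductance_scale")]
)


def shift_grid(n: int = 21, half_span_mv: float = 10.0) -> np.ndarray:
    """Half-activation shift grid: ``n`` equidistant values in [-span, span].

    ``n`` must be odd so the grid contains the unaltered point 0.
    """
    if n % 2 == 0:
        raise ValueError("shift grid needs an odd point count to contain 0")
    return np.linspace(-half_span_mv, half_span_mv, n)


def factor_grid(n: int = 21) -> np.ndarray:
    """Scaling grid: ``n`` log2-equispaced factors in [0.5, 2].

    Odd ``n`` makes the middle value exactly 1 (the unaltered point).
    """
    if n % 2 == 0:
        raise ValueError("factor grid needs an odd point count to contain 1")
    g = np.exp2(np.linspace(-1.0, 1.0, n))
    g[n // 2] = 1.0  # exact identity at the midpoint
    return g


@dataclass(frozen=True)
class AlterationGrid:
    """One swept parameter: target current/gate/property plus its value grid."""

    target_current: str
    property: str  # v_half_shift | slope_scale | conductance_scale
    values: np.ndarray
    target_gate: Optional[str] = None

    def alterations(self):
        return [Alteration(self.target_current, self.property, float(v),
                           self.target_gate) for v in self.values]

    def magnitudes(self) -> np.ndarray:
        if self.property == "v_half_shift":
            return np.asarray(self.values, dtype=float)
        return np.log2(np.asarray(self.values, dtype=float))

    @property
    def identity_value(self) -> float:
        return 0.0 if self.property == "v_half_shift" else 1.0


def build_grids(n_points: int = 21,
                targets: Sequence[tuple] = DEFAULT_TARGETS) -> list:
    """The full cross of sweep targets with their value grids."""
    grids = []
    for current, gate, prop in targets:
        values = shift_grid(n_points) if prop == "v_half_shift" else factor_grid(n_points)
        grids.append(AlterationGrid(current, prop, values, gate))
    return grids


def normalized_delta_auc(auc_i: float, auc_wt: float) -> float:
    """(AUC_i - AUC_wt) / AUC_wt; undefined for a silent wild type."""
    if not (auc_wt > 0):
        raise ZeroDivisionError("wild-type AUC is zero; contrast undefined")
    return (auc_i - auc_wt) / auc_wt


def kendall_tau(x, y) -> float:
    """Kendall rank correlation (tau-b, tie-corrected).

    Strictly monotone tie-free inputs give exactly +/-1.  Returns NaN when
    the correlation is undefined (fewer than two pairs or a constant input).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("kendall_tau needs equal-length inputs")
    if len(x) < 2 or np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan")
    tau = stats.kendalltau(x, y).statistic
    return float(tau)


@dataclass
class OATResult:
    records: pd.DataFrame      # one row per (model, grid point)
    correlations: pd.DataFrame  # one row per (model, current, gate, property)


def _grid_key(grid: AlterationGrid):
    return (grid.target_current, grid.target_gate or "", grid.property)


def run_oat(models: Sequence, grids: Sequence[AlterationGrid],
            proto: FiringProtocol, metrics: Sequence[str] = ("rheobase", "auc"),
            config: Optional[IntegratorConfig] = None,
            progress: bool = False) -> OATResult:
    """Sweep every applicable (model, grid point) and summarize with Kendall tau.

    ``models`` may contain model-id letters or ready specs.  ``metrics``
    selects which firing measures are computed ("rheobase", "auc" or both);
    restricting them roughly halves the simulation cost of a sweep.  Rows are
    emitted in deterministic order; per-point failures are recorded as
    excluded rows and never abort the sweep.
    """
    if config is None:
        config = IntegratorConfig(dt=proto.dt)
    rows = []
    corr_rows = []
    for model in models:
        spec = build_model(model) if isinstance(model, str) else model
        wt = _characterize_point(spec, proto, metrics, config)
        for grid in grids:
            key = _grid_key(grid)
            if not spec.has_current(grid.target_current):
                corr_rows.append(dict(
                    model_id=spec.model_id, current=key[0], gate=key[1],
                    property=key[2], tau_auc=np.nan, tau_rheobase=np.nan,
                    n_used=0, n_excluded=0, applicable=False))
                continue
            mags = grid.magnitudes()
            pts = []
            for value, mag, alt in zip(grid.values, mags, grid.alterations()):
                if value == grid.identity_value:
                    pt = dict(wt)  # identity alteration: bitwise the same model
                    pt.update(excluded=wt["excluded"], reason=wt["reason"])
                else:
                    try:
                        altered = apply_alteration(spec, alt)
                    except KeyError as err:  # e.g. gate missing on this current
                        pt = _failed_point(str(err))
                        pts.append(_record(spec, key, value, mag, pt, wt))
                        continue
                    pt = _characterize_point(altered, proto, metrics, config)
                pts.append(_record(spec, key, value, mag, pt, wt))
            rows.extend(pts)
            included = [p for p in pts if not p["excluded"]]
            tau_auc = kendall_tau([p["magnitude"] for p in included],
                                  [p["d_auc_norm"] for p in included]) \
                if "auc" in metrics and included else float("nan")
            tau_rheo = kendall_tau([p["magnitude"] for p in included],
                                   [p["d_rheobase_pa"] for p in included]) \
                if "rheobase" in metrics and included else float("nan")
            corr_rows.append(dict(
                model_id=spec.model_id, current=key[0], gate=key[1],
                property=key[2], tau_auc=tau_auc, tau_rheobase=tau_rheo,
                n_used=len(included), n_excluded=len(pts) - len(included),
                applicable=True))
            if progress:
                print(f"[oat] {spec.model_id} {key}: tau_auc={tau_auc:+.2f} "
                      f"tau_rheo={tau_rheo:+.2f} used={len(included)}")
    return OATResult(records=pd.DataFrame(rows),
                     correlations=pd.DataFrame(corr_rows))


# -- helpers ---------------------------------------------------------------

def _failed_point(reason: str) -> dict:
    return dict(rheobase_pa=np.nan, auc=np.nan, ss_onset_pa=np.nan,
                burst_flag=False, excluded=True, reason=reason)


def _characterize_point(spec: ModelSpec, proto: FiringProtocol,
                        metrics: Sequence[str],
                        config: IntegratorConfig) -> dict:
    sim = NeuronSimulator(spec, config)
    try:
        fm = characterize(sim, proto, need=tuple(metrics))
    except NonFiringError:
        return _failed_point("non_firing")
    except IntegrationError as err:
        return _failed_point(f"integration_failure: {err}")
    excluded = bool(fm.burst_flag)
    return dict(rheobase_pa=fm.rheobase_pa, auc=fm.auc,
                ss_onset_pa=fm.ss_onset_pa, burst_flag=fm.burst_flag,
                excluded=excluded, reason="bursting" if excluded else "")


def _record(spec: ModelSpec, key, value, mag, pt: dict, wt: dict) -> dict:
    row = dict(model_id=spec.model_id, current=key[0], gate=key[1],
               property=key[2], amount=float(value), magnitude=float(mag),
               rheobase_pa=pt["rheobase_pa"], auc=pt["auc"],
               d_rheobase_pa=np.nan, d_auc_norm=np.nan,
               burst_flag=pt["burst_flag"], excluded=pt["excluded"],
               reason=pt["reason"])
    if not pt["excluded"] and not wt["excluded"]:
        if np.isfinite(pt["rheobase_pa"]) and np.isfinite(wt["rheobase_pa"]):
            row["d_rheobase_pa"] = pt["rheobase_pa"] - wt["rheobase_pa"]
        if np.isfinite(pt["auc"]) and np.isfinite(wt["auc"]):
            if wt["auc"] > 0:
                row["d_auc_norm"] = (pt["auc"] - wt["auc"]) / wt["auc"]
            else:
                row["excluded"] = True
                row["reason"] = "zero_wt_auc"
    elif wt["excluded"] and not pt["excluded"]:
        row["excluded"] = True
        row["reason"] = f"wild_type:{wt['reason']}"
    return row
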