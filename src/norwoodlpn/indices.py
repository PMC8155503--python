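"""Summary hemodynamic indices computed from simulated waveforms.

All quantities are evaluated on the final (periodic) cycle and reported in
clinical units: pressures in mmHg, flows in L/min, vascular resistances in
Wood units (mmHg per L/min), Reynolds numbers and Poiseuille wall shear
stress (dyn/cm^2) per conduit.
"""
from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .engine import WaveformSet
from .geometry import BloodProperties
from .units import MMHG, cgs_to_lmin, mm_to_cm

__all__ = [
    "IndexReport",
    "summarize_pressure",
    "compute_qp_qs",
    "vascular_resistance_wood",
    "reynolds_number",
    "poiseuille_wss",
    "compute_report",
    "SYSTEMIC_OUTLETS",
    "PULMONARY_OUTLETS",
]

PULMONARY_OUTLETS = ("LPA", "RPA")
SYSTEMIC_OUTLETS = ("DAo", "RC", "RS", "LC", "LS")


def summarize_pressure(w: WaveformSet, node: str) -> tuple[float, float, float, float]:
    """(systolic, diastolic, mean, pulse) pressure in mmHg over the final cycle."""
    if not w.periodicity_achieved:
        warnings.warn(
            f"waveforms not periodic; pressure summary at {node} uses last cycle",
            stacklevel=2,
        )
    p = w.last_cycle(w.pressures[node]) / MMHG
    sys_, dia = float(p.max()), float(p.min())
    mean = w.mean_pressure(node) / MMHG
    return sys_, dia, mean, sys_ - dia


def _outlet_mean_flows(w: WaveformSet, outlets) -> dict[str, float]:
    out = {}
    for o in outlets:
        for cid in (f"seg_{o}", f"wk_{o}_Rp", o):
            if cid in w.flows:
                out[o] = cgs_to_lmin(w.mean_flow(cid))
                break
        else:
            raise KeyError(f"no flow trace found for outlet {o!r}")
    return out


def compute_qp_qs(w: WaveformSet) -> float:
    """Pulmonary-to-systemic flow ratio from cycle-mean outlet flows."""
    qp = sum(_outlet_mean_flows(w, PULMONARY_OUTLETS).values())
    qs = sum(_outlet_mean_flows(w, SYSTEMIC_OUTLETS).values())
    return qp / qs


def vascular_resistance_wood(mean_drop_mmhg: float, flow_lmin: float) -> float:
    """Resistance in Wood units = mmHg / (L/min)."""
    if flow_lmin <= 0:
        raise ValueError("flow must be positive")
    return mean_drop_mmhg / flow_lmin


def reynolds_number(q_cm3s: float, diameter_cm: float, blood: BloodProperties) -> float:
    """Re = 4 rho Q / (pi mu d) for Poiseuille pipe flow at flow Q."""
    if diameter_cm <= 0:
        raise ValueError("diameter must be positive")
    return 4.0 * blood.rho * abs(q_cm3s) / (math.pi * blood.mu * diameter_cm)


def poiseuille_wss(q_cm3s: float, radius_cm: float, mu: float) -> float:
    """Poiseuille wall shear stress tau = 4 mu Q / (pi r^3), dyn/cm^2."""
    if radius_cm <= 0:
        raise ValueError("radius must be positive")
    return 4.0 * mu * q_cm3s / (math.pi * radius_cm**3)


@dataclass
class IndexReport:
    """Every printed hemodynamic index, with the definitions used."""

    stage: str | None = None
    pressures: dict[str, dict[str, float]] = field(default_factory=dict)  # node -> sys/dia/mean/pulse
    mean_flows_lmin: dict[str, float] = field(default_factory=dict)
    cardiac_output_lmin: float = float("nan")
    qp_qs: float = float("nan")
    mean_pa_pressure_mmhg: float = float("nan")
    wood_units: dict[str, dict[str, float]] = field(default_factory=dict)
    reynolds: dict[str, dict[str, float]] = field(default_factory=dict)
    wss_dyn_cm2: dict[str, dict[str, float]] = field(default_factory=dict)
    peak_systole_s: float = float("nan")
    notes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "stage": self.stage,
            "pressures_mmHg": self.pressures,
            "mean_flows_Lmin": self.mean_flows_lmin,
            "cardiac_output_Lmin": self.cardiac_output_lmin,
            "qp_qs": self.qp_qs,
            "mean_pa_pressure_mmHg": self.mean_pa_pressure_mmhg,
            "resistances_wood_units": self.wood_units,
            "reynolds_numbers": self.reynolds,
            "wss_dyn_cm2": self.wss_dyn_cm2,
            "peak_systole_s": self.peak_systole_s,
            "notes": self.notes,
        }

    def to_json(self, path=None, indent: int = 2) -> str:
        text = json.dumps(self.to_dict(), indent=indent)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text


def compute_report(
    w: WaveformSet,
    netlist_meta: Mapping | None = None,
    blood: BloodProperties | None = None,
    stage: str | None = None,
    inlet: str = "inlet",
    pa_node: str = "pa",
    p_la_mmhg: float = 6.0,
) -> IndexReport:
    """Full index report from a simulated Norwood-template waveform set.

    ``netlist_meta`` supplies conduit diameters (segments + shunt) for
    Reynolds/WSS; Wood-unit resistances use systemic (MAP - P_RA)/Qs and
    pulmonary (mean PA - P_LA)/Qp conventions, reported alongside their
    definitions.
    """
    meta = dict(netlist_meta or {})
    if blood is None:
        b = meta.get("blood", {})
        blood = BloodProperties(rho=b.get("rho", 1.06), mu=b.get("mu", 0.04))
    rep = IndexReport(stage=stage)

    nodes = [inlet] + [n for n in (pa_node,) if n in w.pressures]
    nodes += [o for o in PULMONARY_OUTLETS + SYSTEMIC_OUTLETS if o in w.pressures]
    for node in nodes:
        s, d, m, pp = summarize_pressure(w, node)
        rep.pressures[node] = {"systolic": s, "diastolic": d, "mean": m, "pulse": pp}

    rep.mean_flows_lmin = _outlet_mean_flows(w, PULMONARY_OUTLETS + SYSTEMIC_OUTLETS)
    inflow_id = "heart_naov" if "heart_naov" in w.flows else "inflow"
    rep.cardiac_output_lmin = cgs_to_lmin(w.mean_flow(inflow_id))
    rep.qp_qs = compute_qp_qs(w)
    if pa_node in w.pressures:
        rep.mean_pa_pressure_mmhg = rep.pressures[pa_node]["mean"]

    qp = sum(rep.mean_flows_lmin[o] for o in PULMONARY_OUTLETS)
    qs = sum(rep.mean_flows_lmin[o] for o in SYSTEMIC_OUTLETS)
    map_mmhg = rep.pressures[inlet]["mean"]
    p_ra = meta.get("p_ra_mmhg")
    if p_ra is None:
        p_ra = 0.0
        rep.notes.append("systemic Wood units referenced to 0 (no P_RA in meta)")
    rep.wood_units = {
        "systemic": {
            "value": vascular_resistance_wood(map_mmhg - p_ra, qs),
            "definition": f"(MAP - P_RA={p_ra:g}) / Qs",
        },
    }
    if pa_node in w.pressures:
        rep.wood_units["pulmonary"] = {
            "value": vascular_resistance_wood(
                rep.mean_pa_pressure_mmhg - p_la_mmhg, qp),
            "definition": f"(mean PA - P_LA={p_la_mmhg:g}) / Qp",
        }

    # peak systole = time of maximum inflow within the final cycle
    s = w.cycle_slice(-1)
    q_in = w.flows[inflow_id][s]
    i_peak = int(np.argmax(q_in))
    rep.peak_systole_s = float(w.time[s][i_peak] - w.time[s][0])

    # conduit Reynolds numbers and WSS (shunt + PAs)
    conduits: dict[str, tuple[str, float]] = {}
    shunt_meta = meta.get("shunt")
    if shunt_meta and "shunt" in w.flows:
        conduits["shunt"] = ("shunt", shunt_meta["effective_diameter_mm"])
    for name in PULMONARY_OUTLETS:
        seg = meta.get("segments", {}).get(name)
        if seg and f"seg_{name}" in w.flows:
            conduits[name] = (f"seg_{name}", seg["diameter_mm"])
    for name, (cid, dia_mm) in conduits.items():
        q = w.flows[cid][s]
        d_cm = mm_to_cm(dia_mm)
        q_avg = abs(w.mean_flow(cid))
        q_peak = float(q.max())   # peak systolic flow of the conduit itself
        rep.reynolds[name] = {
            "Re_avg": reynolds_number(q_avg, d_cm, blood),
            "Re_max": reynolds_number(q_peak, d_cm, blood),
        }
        rep.wss_dyn_cm2[name] = {
            "avg": poiseuille_wss(q_avg, d_cm / 2.0, blood.mu),
            "peak": poiseuille_wss(q_peak, d_cm / 2.0, blood.mu),
        }
    return rep
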