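"""Windkessel and heart parameter blocks, and netlist attachment helpers.

Component parameters are CGS; constructors accept the clinical units the
literature reports (mmHg, mmHg/mL) through the ``from_clinical`` helpers.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

from .netlist import GROUND, Netlist, SchemaError
from .units import MMHG

__all__ = [
    "WindkesselParams",
    "HeartParams",
    "attach_windkessel",
    "attach_heart",
    "attach_inflow",
    "detach_inflow",
    "detach_heart",
    "get_windkessel",
    "set_windkessel",
    "windkessel_unit_check",
]


@dataclass(frozen=True)
class WindkesselParams:
    """Three-element Windkessel: proximal R, distal R, compliance, venous P_ref."""

    R_p: float
    R_d: float
    C: float
    P_ref: float = 0.0

    def __post_init__(self) -> None:
        if min(self.R_p, self.R_d, self.C) <= 0:
            raise ValueError("Windkessel R_p, R_d and C must be positive")

    @property
    def R_total(self) -> float:
        return self.R_p + self.R_d

    def scaled(self, r_factor: float = 1.0, c_factor: float = 1.0) -> "WindkesselParams":
        return replace(self, R_p=self.R_p * r_factor, R_d=self.R_d * r_factor,
                       C=self.C * c_factor)


@dataclass(frozen=True)
class HeartParams:
    """0D heart: fixed-pressure right atrium, two diode valves, elastance chamber.

    ``E_max``/``E_min`` are chamber elastances in dyn/cm^2 per cm^3
    (mmHg/mL x 1333.22); the activation is a normalized double-Hill with
    shape constants (m1, m2) and time constants tau1/tau2 as fractions of
    the period T.
    """

    P_RA: float                       # dyn/cm^2
    E_max: float                      # dyn/cm^2/cm^3
    E_min: float
    V0: float                         # cm^3
    T: float                          # s
    avv_R: float = 33.0               # dyn*s/cm^5
    avv_L: float = 0.667              # dyn*s^2/cm^5
    naov_R: float = 10.0
    naov_L: float = 0.10
    m1: float = 1.32
    m2: float = 27.4
    tau1_frac: float = 0.269
    tau2_frac: float = 0.452

    def __post_init__(self) -> None:
        if not (self.E_max > self.E_min > 0):
            raise ValueError("need E_max > E_min > 0")
        if self.T <= 0:
            raise ValueError("period T must be positive")
        if self.V0 < 0:
            raise ValueError("V0 must be >= 0")

    @classmethod
    def from_clinical(
        cls,
        p_ra_mmhg: float,
        e_max_mmhg_ml: float,
        e_min_mmhg_ml: float,
        v0_ml: float,
        period_s: float,
        **kwargs,
    ) -> "HeartParams":
        return cls(
            P_RA=p_ra_mmhg * MMHG,
            E_max=e_max_mmhg_ml * MMHG,
            E_min=e_min_mmhg_ml * MMHG,
            V0=v0_ml,
            T=period_s,
            **kwargs,
        )


# -- attachment helpers -------------------------------------------------------

def attach_windkessel(nl: Netlist, outlet: str, wk: WindkesselParams) -> None:
    """Attach a 3-element Windkessel at an outlet node (idempotent per outlet)."""
    mid, ref = f"{outlet}__wk", f"{outlet}__ref"
    for cid in (f"wk_{outlet}_Rp", f"wk_{outlet}_C", f"wk_{outlet}_Rd", f"wk_{outlet}_Pref"):
        if cid in nl:
            nl.remove(cid)
    nl.add("resistor", f"wk_{outlet}_Rp", outlet, mid, R=wk.R_p)
    nl.add("capacitor", f"wk_{outlet}_C", mid, GROUND, C=wk.C)
    nl.add("resistor", f"wk_{outlet}_Rd", mid, ref, R=wk.R_d)
    nl.add("pressure_source", f"wk_{outlet}_Pref", ref, GROUND, P=wk.P_ref)


def get_windkessel(nl: Netlist, outlet: str) -> WindkesselParams:
    return WindkesselParams(
        R_p=nl[f"wk_{outlet}_Rp"].params["R"],
        R_d=nl[f"wk_{outlet}_Rd"].params["R"],
        C=nl[f"wk_{outlet}_C"].params["C"],
        P_ref=nl[f"wk_{outlet}_Pref"].params["P"],
    )


def set_windkessel(nl: Netlist, outlet: str, wk: WindkesselParams) -> None:
    nl[f"wk_{outlet}_Rp"].params["R"] = wk.R_p
    nl[f"wk_{outlet}_Rd"].params["R"] = wk.R_d
    nl[f"wk_{outlet}_C"].params["C"] = wk.C
    nl[f"wk_{outlet}_Pref"].params["P"] = wk.P_ref


def attach_heart(nl: Netlist, heart: HeartParams, inlet: str | None = None) -> None:
    """Attach the atrium-valve-ventricle-valve chain upstream of the inlet."""
    inlet = inlet or nl.inlet
    if inlet is None:
        raise SchemaError("netlist has no inlet to attach the heart to")
    detach_heart(nl)
    nl.add("pressure_source", "heart_Pra", "ra", GROUND, P=heart.P_RA)
    nl.add("diode_valve", "heart_avv", "ra", "ventricle",
           R_open=heart.avv_R, L=heart.avv_L)
    nl.add("elastance_chamber", "heart_ventricle", "ventricle", GROUND,
           E_max=heart.E_max, E_min=heart.E_min, V0=heart.V0, T=heart.T,
           m1=heart.m1, m2=heart.m2, tau1_frac=heart.tau1_frac,
           tau2_frac=heart.tau2_frac)
    nl.add("diode_valve", "heart_naov", "ventricle", inlet,
           R_open=heart.naov_R, L=heart.naov_L)


def detach_heart(nl: Netlist) -> None:
    for cid in ("heart_Pra", "heart_avv", "heart_ventricle", "heart_naov"):
        if cid in nl:
            nl.remove(cid)


def attach_inflow(nl: Netlist, inlet: str | None = None, **params) -> None:
    """Attach a prescribed inflow at the inlet.

    ``params`` is a flow_source parameter set: ``value`` (constant cm^3/s),
    ``profile`` (dict, see :mod:`norwoodlpn.synth`), or ``fn`` (callable,
    in-memory only).
    """
    inlet = inlet or nl.inlet
    if inlet is None:
        raise SchemaError("netlist has no inlet to attach inflow to")
    detach_inflow(nl)
    nl.add("flow_source", "inflow", GROUND, inlet, **params)


def detach_inflow(nl: Netlist) -> None:
    if "inflow" in nl:
        nl.remove("inflow")


# -- unit-consistency reporting ----------------------------------------------

#: multiplicative factor taking a printed value to CGS under each reading
_UNIT_READINGS = {
    "Pa_s_mm3": 1.0e4,        # pressure in Pa, length in mm
    "mmHg_s_mL": MMHG,        # pressure in mmHg, volume in mL
    "cgs": 1.0,
}


def windkessel_unit_check(
    printed_total_R: dict[str, float], target_R_cgs: dict[str, float]
) -> dict:
    """Rank unit interpretations of printed Windkessel resistances.

    ``printed_total_R`` maps outlet -> printed total resistance (unknown
    units); ``target_R_cgs`` maps outlet -> the resistance implied by the
    pooled pressure/flow targets, in CGS. Returns per-interpretation mean
    absolute log10 ratio (smaller = more consistent) plus the best reading.
    """
    import math

    scores = {}
    for name, factor in _UNIT_READINGS.items():
        logs = [
            abs(math.log10(printed_total_R[k] * factor / target_R_cgs[k]))
            for k in printed_total_R
            if k in target_R_cgs and printed_total_R[k] > 0 and target_R_cgs[k] > 0
        ]
        scores[name] = sum(logs) / len(logs) if logs else float("inf")
    best = min(scores, key=scores.get)
    return {"scores": scores, "best": best, "factor": _UNIT_READINGS[best]}
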