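"""Vessel geometry -> 0D circuit elements.

Each compliant vessel segment is reduced to a series resistance (Poiseuille)
and inertance with half its tube-law compliance lumped at each end node
(pi-element). The systemic-to-pulmonary shunt is rigid and carries a
nonlinear pressure-drop law: Poiseuille viscous term plus a Borda-Carnot
style dynamic-pressure loss at the anastomoses, evaluated on the pinched
(effective) diameter.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

from .netlist import Netlist
from .units import MMHG, mm_to_cm

__all__ = [
    "VesselSegment",
    "ShuntSpec",
    "BloodProperties",
    "scale_segment",
    "poiseuille_resistance",
    "segment_compliance",
    "segment_inertance",
    "linearized_stiffness_from_area",
    "apply_anastomotic_pinch",
    "shunt_pressure_drop",
    "shunt_coefficients",
    "build_network",
    "default_geometry",
    "NORWOOD_SEGMENTS",
]


@dataclass(frozen=True)
class BloodProperties:
    """Density (g/cm^3) and dynamic viscosity (poise)."""

    rho: float = 1.06
    mu: float = 0.04

    def __post_init__(self) -> None:
        if self.rho <= 0 or self.mu <= 0:
            raise ValueError("blood density and viscosity must be positive")


@dataclass(frozen=True)
class VesselSegment:
    """Geometric + material description of one vessel segment.

    ``thickness_mm`` may be None, in which case the wall is taken as
    ``thickness_frac`` of the local radius. ``stiffness`` is the linearized
    elastic modulus E in dyn/cm^2.
    """

    name: str
    diameter_mm: float
    length_mm: float
    thickness_mm: float | None = 1.5
    thickness_frac: float = 0.15
    stiffness: float = 3.0e6
    rigid: bool = False

    def __post_init__(self) -> None:
        if self.diameter_mm <= 0 or self.length_mm <= 0:
            raise ValueError(f"{self.name}: diameter and length must be positive")
        if self.stiffness <= 0:
            raise ValueError(f"{self.name}: stiffness must be positive")

    @property
    def radius_cm(self) -> float:
        return mm_to_cm(self.diameter_mm) / 2.0

    @property
    def length_cm(self) -> float:
        return mm_to_cm(self.length_mm)

    @property
    def wall_thickness_cm(self) -> float:
        if self.thickness_mm is not None:
            return mm_to_cm(self.thickness_mm)
        return self.thickness_frac * self.radius_cm

    @property
    def area_cm2(self) -> float:
        return math.pi * self.radius_cm**2

    def resistance(self, blood: BloodProperties) -> float:
        return poiseuille_resistance(blood.mu, self.length_cm, self.radius_cm)

    def compliance(self) -> float:
        if self.rigid:
            return 0.0
        return segment_compliance(
            self.radius_cm, self.length_cm, self.stiffness, self.wall_thickness_cm
        )

    def inertance(self, blood: BloodProperties) -> float:
        return segment_inertance(blood.rho, self.length_cm, self.area_cm2)


@dataclass(frozen=True)
class ShuntSpec:
    """Modified Blalock-Thomas-Taussig shunt with anastomotic pinch.

    ``pinch_fraction`` is the fractional diameter reduction at the suture
    lines; ``K`` the total dynamic-pressure loss coefficient (one
    Borda-Carnot-type loss per anastomosis by default).
    """

    nominal_diameter_mm: float = 3.5
    pinch_fraction: float = 0.10
    length_mm: float = 20.0
    K: float = 2.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.pinch_fraction < 1.0):
            raise ValueError("pinch_fraction must lie in [0, 1)")
        if self.nominal_diameter_mm <= 0 or self.length_mm <= 0:
            raise ValueError("shunt diameter and length must be positive")

    @property
    def effective_diameter_mm(self) -> float:
        return self.nominal_diameter_mm * (1.0 - self.pinch_fraction)

    @property
    def display_diameter_mm(self) -> float:
        """Effective diameter rounded to 2 significant figures (for display)."""
        d = self.effective_diameter_mm
        if d == 0:
            return 0.0
        exp = math.floor(math.log10(abs(d)))
        return round(d, 1 - exp)

    @property
    def effective_radius_cm(self) -> float:
        return mm_to_cm(self.effective_diameter_mm) / 2.0

    @property
    def effective_area_cm2(self) -> float:
        return math.pi * self.effective_radius_cm**2


# -- elementary reductions ----------------------------------------------------

def poiseuille_resistance(mu: float, length_cm: float, radius_cm: float) -> float:
    """R = 8 mu L / (pi r^4), dyn*s/cm^5."""
    if mu <= 0 or length_cm <= 0 or radius_cm <= 0:
        raise ValueError("viscosity, length and radius must be positive")
    return 8.0 * mu * length_cm / (math.pi * radius_cm**4)


def segment_compliance(radius_cm: float, length_cm: float, E: float, h_cm: float) -> float:
    """Thin-walled tube-law volume compliance C = 3 pi r^3 L / (2 E h)."""
    if min(radius_cm, length_cm, E, h_cm) <= 0:
        raise ValueError("radius, length, stiffness and thickness must be positive")
    return 3.0 * math.pi * radius_cm**3 * length_cm / (2.0 * E * h_cm)


def segment_inertance(rho: float, length_cm: float, area_cm2: float) -> float:
    """Blood inertance L = rho l / A, dyn*s^2/cm^5."""
    if min(rho, length_cm, area_cm2) <= 0:
        raise ValueError("density, length and area must be positive")
    return rho * length_cm / area_cm2


def linearized_stiffness_from_area(
    p_sys_mmhg: float,
    p_dia_mmhg: float,
    a_sys_cm2: float,
    a_dia_cm2: float,
    radius_cm: float,
    h_cm: float,
) -> float:
    """Linearized elastic modulus from a systolic/diastolic luminal area swing.

    Distensibility D = dA/(A_dia dP); E = 2 r / (h D), the Moens-Korteweg
    consistent inversion of the tube law. A vanishing area swing means a
    rigid wall (E -> infinity); that case raises.
    """
    if p_sys_mmhg <= p_dia_mmhg:
        raise ValueError("need p_sys > p_dia")
    if a_sys_cm2 <= a_dia_cm2 or a_dia_cm2 <= 0:
        raise ValueError("non-distensible: need a_sys > a_dia > 0")
    dp = (p_sys_mmhg - p_dia_mmhg) * MMHG
    distensibility = (a_sys_cm2 - a_dia_cm2) / (a_dia_cm2 * dp)
    return 2.0 * radius_cm / (h_cm * distensibility)


def scale_segment(
    baseline_diameter_mm: float, target_diameter_mm: float, segment: VesselSegment
) -> VesselSegment:
    """Scale a segment to a target diameter; length scales isometrically."""
    if baseline_diameter_mm <= 0 or target_diameter_mm <= 0:
        raise ValueError("diameters must be positive")
    ratio = target_diameter_mm / baseline_diameter_mm
    return replace(
        segment,
        diameter_mm=target_diameter_mm,
        length_mm=segment.length_mm * ratio,
    )


def apply_anastomotic_pinch(shunt: ShuntSpec, pinch_fraction: float) -> ShuntSpec:
    """Return the shunt with suture-line pinch applied (fractional diameter loss)."""
    if not (0.0 <= pinch_fraction < 1.0):
        raise ValueError("pinch_fraction must lie in [0, 1)")
    return replace(shunt, pinch_fraction=pinch_fraction)


def shunt_coefficients(
    shunt: ShuntSpec, blood: BloodProperties
) -> tuple[float, float, float]:
    """(a_quad, r_lin, inertance) of the trans-shunt law dP = a Q|Q| + r Q."""
    r_lin = poiseuille_resistance(blood.mu, mm_to_cm(shunt.length_mm), shunt.effective_radius_cm)
    a_quad = shunt.K * blood.rho / (2.0 * shunt.effective_area_cm2**2)
    inertance = segment_inertance(blood.rho, mm_to_cm(shunt.length_mm), shunt.effective_area_cm2)
    return a_quad, r_lin, inertance


def shunt_pressure_drop(shunt: ShuntSpec, blood: BloodProperties, q_cm3s: float) -> float:
    """Trans-shunt pressure drop (dyn/cm^2) at flow Q (cm^3/s), sign-preserving."""
    a_quad, r_lin, _ = shunt_coefficients(shunt, blood)
    return r_lin * q_cm3s + a_quad * q_cm3s * abs(q_cm3s)


# -- the Norwood network template --------------------------------------------

#: segment name -> (upstream node, downstream node)
NORWOOD_SEGMENTS: dict[str, tuple[str, str]] = {
    "AAo": ("inlet", "n1"),
    "arch_a": ("n1", "n2"),
    "arch_b": ("n2", "n3"),
    "DAo": ("n3", "DAo"),
    "RC": ("n1", "RC"),
    "RS": ("n1", "RS"),
    "LC": ("n2", "LC"),
    "LS": ("n3", "LS"),
    "LPA": ("pa", "LPA"),
    "RPA": ("pa", "RPA"),
}

OUTLETS = ["LPA", "RPA", "DAo", "RC", "RS", "LC", "LS"]


class TopologyError(ValueError):
    """A required segment is missing from the network template."""


def build_network(
    segments: Sequence[VesselSegment],
    shunt: ShuntSpec | None,
    blood: BloodProperties = BloodProperties(),
    include_inertance: bool = True,
    topology: str = "norwood",
) -> Netlist:
    """Assemble the Norwood arterial netlist fragment.

    One inlet (ascending neo-aorta) and seven outlets; the shunt leaves the
    arch at the brachiocephalic origin (node n1) and feeds the PA junction.
    Windkessels and the heart are attached afterwards (see
    :mod:`norwoodlpn.engine`). Raises :class:`TopologyError` naming any
    missing required segment.
    """
    if topology != "norwood":
        raise TopologyError(f"unknown topology {topology!r}")
    by_name = {s.name: s for s in segments}
    missing = set(NORWOOD_SEGMENTS) - set(by_name)
    if missing:
        raise TopologyError(f"missing segments: {sorted(missing)}")
    if shunt is None:
        raise TopologyError("missing segments: ['shunt']")

    nl = Netlist(inlet="inlet", outlets=list(OUTLETS))
    caps: dict[str, float] = {}
    for name, (a, b) in NORWOOD_SEGMENTS.items():
        seg = by_name[name]
        r = seg.resistance(blood)
        if include_inertance:
            nl.add("inductor", f"seg_{name}", a, b, L=seg.inertance(blood), R=r)
        else:
            nl.add("resistor", f"seg_{name}", a, b, R=r)
        c = seg.compliance()
        if c > 0.0:
            caps[a] = caps.get(a, 0.0) + c / 2.0
            caps[b] = caps.get(b, 0.0) + c / 2.0

    a_quad, r_lin, inertance = shunt_coefficients(shunt, blood)
    nl.add("nonlinear_resistor", "shunt", "n1", "pa",
           a_quad=a_quad, r_lin=r_lin, L=inertance)

    for node, c in caps.items():
        nl.add("capacitor", f"cap_{node}", node, "ground", C=c)

    nl.meta["segments"] = {
        s.name: {"diameter_mm": s.diameter_mm, "length_mm": s.length_mm, "rigid": s.rigid}
        for s in segments
    }
    nl.meta["shunt"] = {
        "nominal_diameter_mm": shunt.nominal_diameter_mm,
        "pinch_fraction": shunt.pinch_fraction,
        "effective_diameter_mm": shunt.effective_diameter_mm,
        "length_mm": shunt.length_mm,
        "K": shunt.K,
    }
    nl.meta["blood"] = {"rho": blood.rho, "mu": blood.mu}
    nl.validate_connected()
    return nl


# -- stage default geometries -------------------------------------------------

# Default lengths (mm) for the post-S1 template; native segments grow
# allometrically with sqrt(BSA ratio) toward pre-S2, the prosthetic shunt
# does not.
_DEFAULT_LENGTHS = {
    "AAo": 15.0, "arch_a": 12.5, "arch_b": 12.5, "DAo": 40.0,
    "RC": 20.0, "RS": 20.0, "LC": 20.0, "LS": 20.0, "LPA": 20.0, "RPA": 20.0,
}

# Relative systolic-diastolic luminal area excursion used to derive default
# linearized stiffness per region (reconstructed arch is graft-stiff).
_AREA_SWING = {
    "AAo": 0.20, "arch_a": 0.08, "arch_b": 0.08, "DAo": 0.20,
    "RC": 0.15, "RS": 0.15, "LC": 0.15, "LS": 0.15, "LPA": 0.25, "RPA": 0.25,
}

_NECK = {"RC", "RS", "LC", "LS"}

# Reference pressures for the stiffness derivation (kept constant across
# stages, as wall properties change little over the first year).
_STIFFNESS_P = (72.4, 37.8)


def _default_diameters(stage: str, pooled: dict[str, float] | None) -> dict[str, float]:
    pooled = pooled or {}
    if stage == "post_s1":
        # Native PAs/DAo take healthy neonatal diameters; the reconstructed
        # region (AAo..arch) takes the post-S1 arch measurement.
        arch = pooled.get("transverse_arch_diameter", 11.6)
        d = {
            "AAo": arch, "arch_a": arch, "arch_b": arch,
            "DAo": pooled.get("descending_aorta_diameter", 6.1),
            "LPA": pooled.get("lpa_diameter", 4.6),
            "RPA": pooled.get("rpa_diameter", 4.9),
        }
        neck = 3.5
    elif stage == "pre_s2":
        arch = pooled.get("transverse_arch_diameter", 12.96)
        d = {
            "AAo": pooled.get("ascending_aorta_diameter", 14.51),
            "arch_a": arch, "arch_b": arch,
            "DAo": pooled.get("descending_aorta_diameter", 8.04),
            "LPA": pooled.get("lpa_diameter", 5.0),
            "RPA": pooled.get("rpa_diameter", 5.13),
        }
        neck = 4.25
    else:
        raise ValueError(f"unknown stage {stage!r}")
    for name in _NECK:
        d[name] = neck
    return d


def default_geometry(
    stage: str,
    pooled_diameters: dict[str, float] | None = None,
    length_scale: float | None = None,
    pinch_fraction: float = 0.10,
    shunt_K: float = 2.0,
) -> tuple[list[VesselSegment], ShuntSpec]:
    """Population-scaled default segments and shunt for a stage.

    ``pooled_diameters`` maps literature parameter names (``lpa_diameter``
    etc.) to pooled values in mm; unspecified entries use packaged-table
    pooled defaults. ``length_scale`` overrides the allometric length factor
    (default 1.0 post-S1, sqrt(0.31/0.23) pre-S2).
    """
    if length_scale is None:
        length_scale = 1.0 if stage == "post_s1" else math.sqrt(0.31 / 0.23)
    diameters = _default_diameters(stage, pooled_diameters)
    p_sys, p_dia = _STIFFNESS_P
    segments = []
    for name, (a, b) in NORWOOD_SEGMENTS.items():
        dia = diameters[name]
        r = mm_to_cm(dia) / 2.0
        thickness_mm = None if name in _NECK else 1.5
        h = 0.15 * r if name in _NECK else mm_to_cm(1.5)
        swing = _AREA_SWING[name]
        a_dia = math.pi * r**2
        stiffness = linearized_stiffness_from_area(
            p_sys, p_dia, a_dia * (1.0 + swing), a_dia, r, h
        )
        segments.append(
            VesselSegment(
                name=name,
                diameter_mm=dia,
                length_mm=_DEFAULT_LENGTHS[name] * length_scale,
                thickness_mm=thickness_mm,
                stiffness=stiffness,
            )
        )
    shunt = ShuntSpec(nominal_diameter_mm=3.5, pinch_fraction=pinch_fraction,
                      length_mm=20.0, K=shunt_K)
    return segments, shunt
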