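"""Synthetic inputs: study tables with known truth, inflow waveforms, fixtures.

Everything the pipeline consumes can be generated here without any external
data: literature-style study tables drawn from a known population
mean/SD in the mixed reporting formats the real tables use, pulsatile
aortic inflow pulses with prescribed cardiac output, and a small collection
of closed-form benchmark netlists. All generators are pure functions of
(spec, seed).
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np

from . import circuits, geometry
from .meta import StudyRecord
from .netlist import GROUND, Netlist
from .units import MMHG, lmin_to_cgs

__all__ = [
    "SyntheticStudySpec",
    "InflowSpec",
    "generate_study_table",
    "generate_inflow_waveform",
    "inflow_function",
    "flow_source_function",
    "fixture_netlists",
]


@dataclass(frozen=True)
class SyntheticStudySpec:
    """A synthetic literature pool drawn from a known population."""

    parameter: str = "mean_pa_pressure"
    stage: str = "pre_s2"
    true_mean: float = 14.2
    true_sd: float = 3.0
    sample_sizes: tuple[int, ...] = (170, 78, 22, 10, 10)
    format_fractions: tuple[float, float, float] = (0.4, 0.4, 0.2)
    # (mean_sd, median_range, mean_only); must sum to 1
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.format_fractions) - 1.0) > 1e-9:
            raise ValueError("format_fractions must sum to 1")
        if any(n < 2 for n in self.sample_sizes):
            raise ValueError("sample sizes must be >= 2")


def generate_study_table(spec: SyntheticStudySpec) -> list[StudyRecord]:
    """Draw a study table from Normal(true_mean, true_sd) populations.

    Study means are exact sample means of simulated raw cohorts, so
    median_range records report the genuine sample median and min/max and
    mean_sd records the genuine sample SD — reporting format is the only
    thing that varies between records.
    """
    rng = np.random.default_rng(spec.seed)
    forms = rng.choice(
        ["mean_sd", "median_range", "mean_only"],
        size=len(spec.sample_sizes),
        p=list(spec.format_fractions),
    )
    records = []
    for i, (n, form) in enumerate(zip(spec.sample_sizes, forms)):
        sample = rng.normal(spec.true_mean, spec.true_sd, size=int(n))
        sid = f"synth{i:02d}"
        if form == "mean_sd":
            rec = StudyRecord(sid, spec.parameter, spec.stage, int(n), "mean_sd",
                              float(sample.mean()), float(sample.std(ddof=1)))
        elif form == "median_range":
            rec = StudyRecord(sid, spec.parameter, spec.stage, int(n), "median_range",
                              float(np.median(sample)), None,
                              float(sample.min()), float(sample.max()))
        else:
            rec = StudyRecord(sid, spec.parameter, spec.stage, int(n), "mean_only",
                              float(sample.mean()))
        records.append(rec)
    return records


# -- pulsatile inflow ---------------------------------------------------------

@dataclass(frozen=True)
class InflowSpec:
    """Aortic inflow pulse: ejection over a systolic fraction, zero diastole.

    ``shape="hann"`` (default) is the C1-smooth squared half-sine ejection
    pulse; ``shape="half_sine"`` is the raw half-sine (kinked at the
    ejection boundaries). The pulse is scaled so the cycle-mean flow equals
    the prescribed cardiac output exactly.
    """

    cardiac_output_lmin: float = 1.265
    period_s: float = 0.429
    systolic_fraction: float = 0.35
    shape: str = "hann"
    seed: int = 0  # unused; deterministic generator

    def __post_init__(self) -> None:
        if not (0.0 < self.systolic_fraction < 1.0):
            raise ValueError("systolic_fraction must lie in (0, 1)")
        if self.cardiac_output_lmin < 0 or self.period_s <= 0:
            raise ValueError("need cardiac_output >= 0 and period > 0")
        if self.shape not in ("hann", "half_sine"):
            raise ValueError(f"unknown shape {self.shape!r}")

    @property
    def mean_flow_cgs(self) -> float:
        return lmin_to_cgs(self.cardiac_output_lmin)


def inflow_function(spec: InflowSpec) -> Callable[[np.ndarray], np.ndarray]:
    """Vectorized Q(t) in cm^3/s for an inflow spec."""
    q_mean = spec.mean_flow_cgs
    T, fs = spec.period_s, spec.systolic_fraction
    ts = fs * T
    if spec.shape == "hann":
        peak = 2.0 * q_mean / fs

        def fn(t):
            tm = np.asarray(t) % T
            return np.where(tm < ts, peak * np.sin(np.pi * tm / ts) ** 2, 0.0)
    else:
        peak = 0.5 * math.pi * q_mean / fs

        def fn(t):
            tm = np.asarray(t) % T
            return np.where(tm < ts, peak * np.sin(np.pi * np.minimum(tm, ts) / ts), 0.0)

    return fn


def generate_inflow_waveform(
    spec: InflowSpec, n_samples: int = 1000
) -> tuple[np.ndarray, np.ndarray]:
    """Sampled (t, Q) over one period; cycle mean equals CO to quadrature."""
    t = np.linspace(0.0, spec.period_s, n_samples, endpoint=False)
    return t, inflow_function(spec)(t)


def flow_source_profile(spec: InflowSpec) -> dict:
    """JSON-serialisable flow_source ``profile`` parameter block."""
    return {
        "type": spec.shape,
        "cardiac_output_lmin": spec.cardiac_output_lmin,
        "period_s": spec.period_s,
        "systolic_fraction": spec.systolic_fraction,
    }


def flow_source_function(params: dict) -> Callable[[np.ndarray], np.ndarray]:
    """Resolve a flow_source parameter set to a vectorized Q(t)."""
    if "fn" in params:
        return params["fn"]
    if "value" in params:
        q0 = float(params["value"])
        return lambda t: np.full_like(np.asarray(t, dtype=float), q0)
    if "profile" in params:
        prof = params["profile"]
        if prof["type"] in ("hann", "half_sine"):
            spec = InflowSpec(
                cardiac_output_lmin=prof["cardiac_output_lmin"],
                period_s=prof["period_s"],
                systolic_fraction=prof.get("systolic_fraction", 0.35),
                shape=prof["type"],
            )
            return inflow_function(spec)
        if prof["type"] == "sinusoid":
            mean, amp, freq = prof["mean"], prof["amplitude"], prof["frequency_hz"]
            phase = prof.get("phase", 0.0)
            return lambda t: mean + amp * np.sin(2.0 * np.pi * freq * np.asarray(t) + phase)
        raise ValueError(f"unknown flow profile {prof['type']!r}")
    raise ValueError("flow_source needs one of: fn, value, profile")


# -- benchmark netlists -------------------------------------------------------

def fixture_netlists() -> dict[str, Netlist]:
    """Closed-form and template benchmark circuits.

    ``rc``: constant inflow into a 2-element Windkessel (exponential charge,
    closed form). ``wk3``: 3-element Windkessel under sinusoidal inflow
    (analytic complex impedance). ``heart_wk``: minimal beating heart —
    atrium, two valves, elastance chamber, single Windkessel. ``post_s1`` /
    ``pre_s2``: full Norwood templates with literature-style seed values
    (pre-calibration).
    """
    out: dict[str, Netlist] = {}

    rc = Netlist(inlet="n")
    rc.add("flow_source", "inflow", GROUND, "n", value=10.0)
    rc.add("capacitor", "cap_n", "n", GROUND, C=1.0e-4)
    rc.add("resistor", "r_out", "n", GROUND, R=1000.0)
    rc.meta.update(Q0=10.0, R=1000.0, C=1.0e-4)
    out["rc"] = rc

    wk = Netlist(inlet="out", outlets=["out"])
    freq = 2.0
    wk.add("flow_source", "inflow", GROUND, "out",
           profile={"type": "sinusoid", "mean": 10.0, "amplitude": 5.0,
                    "frequency_hz": freq})
    circuits.attach_windkessel(
        wk, "out", circuits.WindkesselParams(R_p=300.0, R_d=2700.0, C=1.0e-4)
    )
    wk.meta.update(R_p=300.0, R_d=2700.0, C=1.0e-4, frequency_hz=freq,
                   q_mean=10.0, q_amp=5.0)
    out["wk3"] = wk

    hw = Netlist(inlet="ao", outlets=["ao"])
    hw.add("capacitor", "cap_ao", "ao", GROUND, C=2.0e-5)
    circuits.attach_windkessel(
        hw, "ao", circuits.WindkesselParams(R_p=320.0, R_d=2880.0, C=6.0e-5,
                                            P_ref=5.0 * MMHG)
    )
    heart = circuits.HeartParams.from_clinical(
        p_ra_mmhg=5.4, e_max_mmhg_ml=8.0, e_min_mmhg_ml=0.4, v0_ml=2.0,
        period_s=0.429)
    circuits.attach_heart(hw, heart, inlet="ao")
    hw.meta.update(period_s=0.429)
    out["heart_wk"] = hw

    for stage, pinch, p_ra, table4 in (
        ("post_s1", 0.10, 5.4, _TABLE4_POST_S1),
        ("pre_s2", 0.17, 7.2, _TABLE4_PRE_S2),
    ):
        segments, shunt = geometry.default_geometry(stage, pinch_fraction=pinch)
        nl = geometry.build_network(segments, shunt)
        for outlet, (rp, rd, c) in table4.items():
            p_ref = 6.0 * MMHG if outlet in ("LPA", "RPA") else p_ra * MMHG
            circuits.attach_windkessel(
                nl, outlet,
                circuits.WindkesselParams(R_p=rp * 1e4, R_d=rd * 1e4,
                                          C=c * 1e-4, P_ref=p_ref),
            )
        heart = circuits.HeartParams.from_clinical(
            p_ra_mmhg=p_ra, e_max_mmhg_ml=8.0, e_min_mmhg_ml=0.4, v0_ml=2.0,
            period_s=0.429 if stage == "post_s1" else 0.5)
        circuits.attach_heart(nl, heart)
        nl.meta["stage"] = stage
        out[stage] = nl
    return out


# Published tuned Windkessel values (R_p, R_d, C) used purely as
# literature-style seeds, read in the Pa-mm unit system.
_TABLE4_POST_S1 = {
    "LPA": (0.053, 0.466, 0.134),
    "RPA": (0.039, 0.402, 0.250),
    "DAo": (0.100, 1.718, 1.326),
    "RC": (0.419, 7.455, 1.516),
    "RS": (0.498, 7.376, 1.341),
    "LC": (0.298, 5.293, 1.524),
    "LS": (0.397, 7.057, 1.535),
}
_TABLE4_PRE_S2 = {
    "LPA": (0.058, 0.192, 0.239),
    "RPA": (0.041, 0.163, 0.444),
    "DAo": (0.170, 1.175, 2.357),
    "RC": (0.667, 4.823, 0.750),
    "RS": (0.781, 4.709, 0.645),
    "LC": (0.473, 3.424, 0.755),
    "LS": (0.631, 4.566, 0.761),
}
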