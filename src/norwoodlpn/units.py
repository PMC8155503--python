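"""Unit conversions.

All internal computation runs in CGS (cm, g, s): pressure in dyn/cm^2, flow
in cm^3/s, resistance in dyn*s/cm^5, compliance in cm^5/dyn, inertance in
dyn*s^2/cm^5. Interfaces (targets, reports, CSV/JSON files) use the clinical
units mmHg and L/min.
"""

MMHG = 1333.22          # dyn/cm^2 per mmHg
LMIN = 16.6667          # cm^3/s per L/min
MM = 0.1                # cm per mm


def mmhg_to_cgs(p: float) -> float:
    return p * MMHG


def cgs_to_mmhg(p: float) -> float:
    return p / MMHG


def lmin_to_cgs(q: float) -> float:
    return q * LMIN


def cgs_to_lmin(q: float) -> float:
    return q / LMIN


def mm_to_cm(x: float) -> float:
    return x * MM
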