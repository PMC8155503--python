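"""Fixed-effect pooling of study-level literature data.

Hemodynamic and morphometric parameters of post-Norwood (post-S1) and
pre-Glenn (pre-S2) HLHS patients are reported across small catheterisation
and echo series in heterogeneous formats: mean +/- SD, bare means, or
median (range). This module converts every record to a mean/SD pair
(size-stratified median/range approximation) and pools each parameter with
a fixed-effect weighted mean, yielding the population targets that drive
geometry scaling and boundary-condition calibration.

Weighting schemes
-----------------
``inverse_sd2`` (default)
    w_i = 1/sd_i^2 (inverse study variance). When any record in a pool has
    no usable dispersion the whole pool falls back to sample-size weights
    w_i = n_i, which is the behaviour the printed pooled literature table
    is consistent with.
``inverse_se2``
    Textbook fixed-effect inverse-variance weights w_i = n_i/sd_i^2
    (SE_i = sd_i/sqrt(n_i)).
``n``
    Sample-size weights only.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "StudyRecord",
    "PooledEstimate",
    "PopulationTargets",
    "estimate_mean_sd_from_median_range",
    "pooled_fixed_effect",
    "build_population_targets",
    "load_study_table",
    "packaged_table",
    "PARAMETERS",
]

Stage = Literal["post_s1", "pre_s2", "healthy"]

#: Controlled vocabulary of literature parameters with display units.
PARAMETERS: dict[str, str] = {
    "age": "months",
    "systolic_pressure": "mmHg",
    "diastolic_pressure": "mmHg",
    "mean_pressure": "mmHg",
    "mean_pa_pressure": "mmHg",
    "qp_qs": "",
    "cardiac_index": "L/min/m^2",
    "cardiac_output": "L/min",
    "bsa": "m^2",
    "lpa_diameter": "mm",
    "rpa_diameter": "mm",
    "ascending_aorta_diameter": "mm",
    "transverse_arch_diameter": "mm",
    "descending_aorta_diameter": "mm",
}

_VALUE_FORMS = {"mean_sd", "mean_only", "median_range", "value_only"}


class InvalidRecordError(ValueError):
    """A study record violates its declared reporting format."""


class NoDataError(ValueError):
    """A pooling request contained no records."""


@dataclass(frozen=True)
class StudyRecord:
    """One literature measurement of one parameter in one cohort."""

    study_id: str
    parameter: str
    stage: Stage
    n: int
    value_form: str
    center: float
    dispersion: float | None = None
    range_low: float | None = None
    range_high: float | None = None

    def __post_init__(self) -> None:
        if self.parameter not in PARAMETERS:
            raise InvalidRecordError(
                f"unknown parameter {self.parameter!r}; known: {sorted(PARAMETERS)}"
            )
        if self.value_form not in _VALUE_FORMS:
            raise InvalidRecordError(f"unknown value_form {self.value_form!r}")
        if self.n < 1:
            raise InvalidRecordError(f"{self.study_id}: n must be >= 1, got {self.n}")
        if self.value_form == "median_range":
            if self.range_low is None or self.range_high is None:
                raise InvalidRecordError(f"{self.study_id}: median_range needs range_low/high")
            if not (self.range_low <= self.center <= self.range_high):
                raise InvalidRecordError(
                    f"{self.study_id}: need range_low <= median <= range_high, "
                    f"got {self.range_low} <= {self.center} <= {self.range_high}"
                )
        elif self.value_form == "mean_sd":
            if self.dispersion is None or self.dispersion < 0:
                raise InvalidRecordError(f"{self.study_id}: mean_sd needs dispersion >= 0")
        elif self.dispersion is not None:
            raise InvalidRecordError(
                f"{self.study_id}: dispersion only allowed for mean_sd records"
            )

    def as_mean_sd(
        self, method: Literal["size_stratified", "quantile"] = "size_stratified"
    ) -> tuple[float, float | None]:
        """Mean/SD pair; median_range records are converted, bare means keep SD None."""
        if self.value_form == "mean_sd":
            return self.center, self.dispersion
        if self.value_form == "median_range":
            return estimate_mean_sd_from_median_range(
                self.center, self.range_low, self.range_high, self.n, method=method
            )
        return self.center, None


def estimate_mean_sd_from_median_range(
    median: float,
    low: float,
    high: float,
    n: int,
    method: Literal["size_stratified", "quantile"] = "size_stratified",
) -> tuple[float, float]:
    """Approximate mean and SD from a reported median and range.

    The mean is (low + 2*median + high)/4 for either method. The default
    size-stratified SD rule uses the full range-based variance formula for
    n <= 15, range/4 for 15 < n <= 70 and range/6 for n > 70. The
    ``quantile`` alternative uses range/(2*Phi^-1((n-0.375)/(n+0.25))).
    """
    if not (low <= median <= high):
        raise InvalidRecordError(f"need low <= median <= high, got {low}, {median}, {high}")
    if n < 1:
        raise InvalidRecordError("n must be >= 1")
    mean = (low + 2.0 * median + high) / 4.0
    rng = high - low
    if method == "quantile":
        from scipy.stats import norm

        z = norm.ppf((n - 0.375) / (n + 0.25))
        sd = rng / (2.0 * z) if z > 0 else 0.0
    elif n <= 15:
        var = ((low - 2.0 * median + high) ** 2 / 4.0 + rng**2) / 12.0
        sd = math.sqrt(var)
    elif n <= 70:
        sd = rng / 4.0
    else:
        sd = rng / 6.0
    return mean, sd


@dataclass(frozen=True)
class PooledEstimate:
    """Pooled mean of one parameter at one stage."""

    parameter: str
    stage: Stage
    pooled_mean: float
    pooled_se: float
    n_studies: int
    total_n: int
    method_notes: str = ""


def pooled_fixed_effect(
    records: Sequence[StudyRecord],
    weighting: Literal["inverse_sd2", "inverse_se2", "n"] = "inverse_sd2",
    fallback: Literal["n", "impute"] = "n",
    sd_method: Literal["size_stratified", "quantile"] = "size_stratified",
    sd_floor_frac: float = 0.01,
) -> PooledEstimate:
    """Pool several study records of one parameter/stage into a single mean.

    ``fallback`` controls pools with missing dispersions: ``"n"`` switches
    the whole pool to sample-size weights, ``"impute"`` fills each missing
    SD with the n-weighted mean SD of the records that report one. SDs of
    exactly zero are floored at ``sd_floor_frac`` of |study mean| to avoid
    infinite weight.
    """
    if not records:
        raise NoDataError("cannot pool an empty record list")
    params = {r.parameter for r in records}
    stages = {r.stage for r in records}
    if len(params) > 1 or len(stages) > 1:
        raise InvalidRecordError(f"mixed pools not allowed: {params}, {stages}")

    notes: list[str] = []
    means, sds, ns, se_factors = [], [], [], []
    for r in records:
        m, sd = r.as_mean_sd(method=sd_method)
        if sd is not None and sd == 0.0 and r.n > 1:
            sd = sd_floor_frac * abs(m)
            notes.append(f"{r.study_id}: zero SD floored at {sd_floor_frac:.0%} of mean")
        means.append(m)
        sds.append(sd)
        ns.append(r.n)
        # A median/range-converted mean rides on the sample extremes, whose
        # sampling error decays only logarithmically; its standard error is
        # the asymptotic Var[(L + 2M + H)/4] for a normal sample, not sd/sqrt(n).
        if r.value_form == "median_range" and r.n > 1:
            se_factors.append(
                math.sqrt(math.pi / (8 * r.n)
                          + math.pi**2 / (48 * math.log(r.n))))
        else:
            se_factors.append(1.0 / math.sqrt(r.n))
    means_a = np.asarray(means, dtype=float)
    ns_a = np.asarray(ns, dtype=float)
    se_f = np.asarray(se_factors)

    missing = [sd is None or sd == 0.0 for sd in sds]
    approximate = False
    if weighting == "n":
        w = ns_a.copy()
        se = np.array([sd if sd is not None else np.nan for sd in sds]) * se_f
    elif any(missing):
        approximate = True
        if fallback == "impute" and not all(missing):
            have = [i for i, miss in enumerate(missing) if not miss]
            pooled_sd = float(
                np.average([sds[i] for i in have], weights=[ns[i] for i in have])
            )
            sds = [pooled_sd if miss else sd for sd, miss in zip(sds, missing)]
            notes.append(f"missing SDs imputed as n-weighted mean SD {pooled_sd:.4g}")
            sd_a = np.asarray(sds, dtype=float)
            w = _weights(weighting, sd_a, ns_a)
            se = sd_a * se_f
        else:
            notes.append("dispersion missing; whole pool fell back to sample-size weights")
            w = ns_a.copy()
            if not all(missing):
                # n-weights for the mean, but a model-based pooled SE from
                # the reported SDs with the missing ones imputed
                have = [i for i, miss in enumerate(missing) if not miss]
                pooled_sd = float(np.average([sds[i] for i in have],
                                             weights=[ns[i] for i in have]))
                sd_a = np.array([pooled_sd if miss else sd
                                 for sd, miss in zip(sds, missing)])
                se = sd_a * se_f
            else:
                se = np.full(len(records), np.nan)
    else:
        sd_a = np.asarray(sds, dtype=float)
        w = _weights(weighting, sd_a, ns_a)
        se = sd_a * se_f

    pooled_mean = float(np.sum(w * means_a) / np.sum(w))
    if np.all(np.isfinite(se)):
        # Var(sum w m / sum w) with arbitrary fixed weights.
        pooled_se = float(np.sqrt(np.sum(w**2 * se**2)) / np.sum(w))
    else:
        # No usable per-study SEs: fall back to the n-weighted SE of the
        # between-study spread (conservative, flagged approximate).
        if len(records) > 1:
            spread = float(np.sqrt(np.average((means_a - pooled_mean) ** 2, weights=w)))
        else:
            spread = 0.0
        pooled_se = spread / math.sqrt(len(records))
        approximate = True
    if approximate:
        notes.append("pooled_se approximate")
    return PooledEstimate(
        parameter=records[0].parameter,
        stage=records[0].stage,
        pooled_mean=pooled_mean,
        pooled_se=pooled_se,
        n_studies=len(records),
        total_n=int(ns_a.sum()),
        method_notes="; ".join(notes),
    )


def _weights(weighting: str, sd: np.ndarray, n: np.ndarray) -> np.ndarray:
    if weighting == "inverse_sd2":
        return 1.0 / sd**2
    if weighting == "inverse_se2":
        return n / sd**2
    raise ValueError(f"unknown weighting {weighting!r}")


# -- population targets -------------------------------------------------------

#: Relative calibration tolerances per parameter (pressures/flows 10%, CO 5%).
DEFAULT_TOLERANCES: dict[str, float] = {
    "systolic_pressure": 0.10,
    "diastolic_pressure": 0.10,
    "mean_pressure": 0.10,
    "pulse_pressure": 0.10,
    "mean_pa_pressure": 0.10,
    "qp_qs": 0.10,
    "cardiac_output": 0.05,
}


@dataclass
class PopulationTargets:
    """Pooled per-stage targets: parameter -> (value, relative tolerance)."""

    stage: Stage
    values: dict[str, float] = field(default_factory=dict)
    tolerances: dict[str, float] = field(default_factory=dict)
    estimates: dict[str, PooledEstimate] = field(default_factory=dict)
    notes: list[str] = field(default_factory=list)

    def __getitem__(self, parameter: str) -> float:
        return self.values[parameter]

    def __contains__(self, parameter: str) -> bool:
        return parameter in self.values

    def get(self, parameter: str, default=None):
        return self.values.get(parameter, default)

    def tolerance(self, parameter: str) -> float:
        return self.tolerances.get(parameter, 0.10)

    def to_dict(self) -> dict:
        units = dict(PARAMETERS, pulse_pressure="mmHg")
        return {
            "stage": self.stage,
            "targets": {
                p: {
                    "value": v,
                    "units": units.get(p, ""),
                    "tolerance": self.tolerances.get(p, 0.10),
                }
                for p, v in self.values.items()
            },
            "notes": list(self.notes),
        }


def build_population_targets(
    table: Iterable[StudyRecord],
    stage: Stage,
    weighting: Literal["inverse_sd2", "inverse_se2", "n"] = "inverse_sd2",
    cardiac_index: float | None = None,
) -> PopulationTargets:
    """Pool every parameter present at ``stage`` and attach tolerances.

    Derived closures: cardiac output = pooled cardiac index x pooled BSA when
    not directly reported (the index is assumed stage-invariant, so a pool
    from another stage may be passed via ``cardiac_index``); mean pressure =
    (systolic + 2*diastolic)/3 when no direct records exist; pulse pressure =
    systolic - diastolic.
    """
    table = list(table)
    recs = [r for r in table if r.stage == stage]
    targets = PopulationTargets(stage=stage)
    by_param: dict[str, list[StudyRecord]] = {}
    for r in recs:
        by_param.setdefault(r.parameter, []).append(r)
    for param, group in sorted(by_param.items()):
        est = pooled_fixed_effect(group, weighting=weighting)
        targets.estimates[param] = est
        targets.values[param] = est.pooled_mean
        targets.tolerances[param] = DEFAULT_TOLERANCES.get(param, 0.10)

    v = targets.values
    if "mean_pressure" not in v and {"systolic_pressure", "diastolic_pressure"} <= v.keys():
        v["mean_pressure"] = (v["systolic_pressure"] + 2.0 * v["diastolic_pressure"]) / 3.0
        targets.tolerances["mean_pressure"] = DEFAULT_TOLERANCES["mean_pressure"]
        targets.notes.append("mean_pressure composed as (sys + 2*dia)/3")
    if {"systolic_pressure", "diastolic_pressure"} <= v.keys():
        v["pulse_pressure"] = v["systolic_pressure"] - v["diastolic_pressure"]
        targets.tolerances["pulse_pressure"] = DEFAULT_TOLERANCES["pulse_pressure"]
    if "cardiac_output" not in v and "bsa" in v:
        ci = v.get("cardiac_index", cardiac_index)
        if ci is not None:
            v["cardiac_output"] = ci * v["bsa"]
            targets.tolerances["cardiac_output"] = DEFAULT_TOLERANCES["cardiac_output"]
            targets.notes.append(
                f"cardiac_output composed as cardiac index {ci:.3g} x BSA {v['bsa']:.3g}"
            )
    return targets


# -- study-table I/O ----------------------------------------------------------

_CSV_COLUMNS = [
    "study_id",
    "parameter",
    "stage",
    "n",
    "value_form",
    "center",
    "dispersion",
    "range_low",
    "range_high",
]


def load_study_table(path_or_buf) -> list[StudyRecord]:
    """Read a study-table CSV into validated records.

    Malformed rows raise :class:`InvalidRecordError` with the offending line
    number (header = line 1).
    """
    df = pd.read_csv(path_or_buf, float_precision="round_trip")
    missing_cols = set(_CSV_COLUMNS) - set(df.columns)
    if missing_cols:
        raise InvalidRecordError(f"study table missing columns: {sorted(missing_cols)}")
    records: list[StudyRecord] = []
    for i, row in df.iterrows():
        def opt(x):
            return None if pd.isna(x) else float(x)

        try:
            records.append(
                StudyRecord(
                    study_id=str(row["study_id"]),
                    parameter=str(row["parameter"]),
                    stage=str(row["stage"]),
                    n=int(row["n"]),
                    value_form=str(row["value_form"]),
                    center=float(row["center"]),
                    dispersion=opt(row["dispersion"]),
                    range_low=opt(row["range_low"]),
                    range_high=opt(row["range_high"]),
                )
            )
        except (InvalidRecordError, ValueError) as exc:
            raise InvalidRecordError(f"line {i + 2}: {exc}") from exc
    return records


def write_study_csv(records: Sequence[StudyRecord], path_or_buf) -> None:
    """Write records as CSV with repr-exact floats (bit-identical round trip)."""
    records_to_frame(records).to_csv(
        path_or_buf, index=False, float_format=lambda v: repr(float(v)))


def records_to_frame(records: Sequence[StudyRecord]) -> pd.DataFrame:
    rows = [
        {
            "study_id": r.study_id,
            "parameter": r.parameter,
            "stage": r.stage,
            "n": r.n,
            "value_form": r.value_form,
            "center": r.center,
            "dispersion": r.dispersion,
            "range_low": r.range_low,
            "range_high": r.range_high,
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=_CSV_COLUMNS)


def packaged_table(name: Literal["table2", "table3"]) -> list[StudyRecord]:
    """Load one of the packaged literature-table transcriptions."""
    ref = resources.files("norwoodlpn.data") / f"{name}.csv"
    with resources.as_file(ref) as path:
        return load_study_table(path)


def default_targets(stage: Stage, weighting: str = "inverse_sd2") -> PopulationTargets:
    """Pooled targets for a stage from the packaged study tables.

    post-S1 borrows the (stage-invariant) cardiac index pooled from the
    pre-S2 table to compose cardiac output.
    """
    if stage == "pre_s2":
        return build_population_targets(packaged_table("table3"), "pre_s2", weighting=weighting)
    table = packaged_table("table2")
    ci_recs = [r for r in packaged_table("table3") if r.parameter == "cardiac_index"]
    ci = pooled_fixed_effect(ci_recs, weighting=weighting).pooled_mean if ci_recs else None
    return build_population_targets(table, stage, weighting=weighting, cardiac_index=ci)
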