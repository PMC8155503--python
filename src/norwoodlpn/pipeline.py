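"""End-to-end pipeline: pool -> build -> calibrate -> simulate -> indices.

Reproduces the whole workflow for one stage from the packaged (or a
user-supplied) study table, writing every artifact plus a provenance
manifest. All randomness (none in the default pipeline; synthetic-table
workflows excepted) flows from the single config seed.
"""
from __future__ import annotations

import json
import logging
from pathlib import Path

from . import meta
from .calibration import CalibrationTargets
from .geometry import BloodProperties, default_geometry
from .io import PipelineConfig, config_hash, write_manifest, write_report, write_targets
from .model import NorwoodLPN, NorwoodResults

logger = logging.getLogger("norwoodlpn")

__all__ = ["run_pipeline"]


def build_model(config: PipelineConfig) -> NorwoodLPN:
    config.validate()
    if config.study_table is None:
        pop = meta.default_targets(config.stage, weighting=config.weighting)
    else:
        table = meta.load_study_table(config.study_table)
        ci = None
        ci_recs = [r for r in table if r.parameter == "cardiac_index"]
        if ci_recs:
            ci = meta.pooled_fixed_effect(ci_recs, weighting=config.weighting).pooled_mean
        pop = meta.build_population_targets(
            table, config.stage, weighting=config.weighting, cardiac_index=ci)
    target_kw = {}
    if config.period_s is not None:
        target_kw["period_s"] = config.period_s
    targets = CalibrationTargets.from_population(pop, **target_kw)
    pooled_diam = {k: pop[k] for k in (
        "lpa_diameter", "rpa_diameter", "ascending_aorta_diameter",
        "transverse_arch_diameter", "descending_aorta_diameter") if k in pop}
    if config.stage == "post_s1" and config.study_table is None:
        healthy = [r for r in meta.packaged_table("table2") if r.stage == "healthy"]
        for k in ("lpa_diameter", "rpa_diameter", "descending_aorta_diameter"):
            recs = [r for r in healthy if r.parameter == k]
            if recs:
                pooled_diam[k] = meta.pooled_fixed_effect(
                    recs, weighting=config.weighting).pooled_mean
    blood = BloodProperties(rho=config.blood_rho, mu=config.blood_mu)
    segments, shunt = default_geometry(
        config.stage, pooled_diam, pinch_fraction=config.pinch_fraction,
        shunt_K=config.shunt_K)
    return NorwoodLPN(targets, segments, shunt, blood=blood,
                      population=pop, stage=config.stage)


def run_pipeline(config: PipelineConfig, write: bool = True) -> NorwoodResults:
    """Execute the full stage workflow; optionally write all artifacts.

    Artifacts in ``config.out_dir``: pooled targets (``targets.yaml``),
    tuned netlist (``netlist.json``), periodic waveforms (``waves.csv``),
    index report (``report.json``), calibration iteration log
    (``calibration.jsonl``) and ``manifest.json`` with the config hash.
    """
    logger.info("stage %s: pooling literature tables", config.stage)
    model = build_model(config)
    logger.info("stage %s: calibrating", config.stage)
    results = model.fit(
        inner_tol=config.inner_tol,
        co_tol=config.co_tol,
        solve_shunt_pinch=config.solve_shunt_pinch,
        dt=config.dt_s,
        max_cycles=config.max_cycles,
        periodicity_tol=config.periodicity_tol,
    )
    logger.info("stage %s: max index deviation %.2f%%",
                config.stage, 100 * results.max_rel_dev)
    if write:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_targets(model.population, out / "targets.yaml")
        results.netlist.meta["config_hash"] = config_hash(config)
        results.netlist.to_json(out / "netlist.json")
        results.waveforms.to_csv(out / "waves.csv")
        write_report(results.report, out / "report.json")
        with open(out / "calibration.jsonl", "w") as fh:
            for rec in results.calibration.iterations:
                fh.write(json.dumps(rec) + "\n")
        write_manifest(config, out, extra={
            "converged": results.calibration.converged,
            "max_rel_dev": results.max_rel_dev,
            "pinch_fraction": results.pinch_fraction,
        })
    return results
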