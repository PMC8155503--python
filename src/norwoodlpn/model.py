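"""Model/Results interface to the population-calibrated Norwood circulation.

:class:`NorwoodLPN` bundles the pooled hemodynamic targets, the scaled
vessel geometry and the heart parameterisation for one stage; ``fit()``
runs the two-step boundary-condition calibration (plus the pre-S2 pinch
inverse problem) and returns a :class:`NorwoodResults` carrying the tuned
parameters, the periodic waveforms, the index report and a summary table.

>>> model = NorwoodLPN.from_literature("pre_s2")
>>> res = model.fit()
>>> print(res.summary())
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Any

import numpy as np
import pandas as pd

from . import calibration as cal
from . import engine, geometry, indices, meta
from .circuits import HeartParams
from .netlist import Netlist
from .units import MMHG

__all__ = ["NorwoodLPN", "NorwoodResults"]

_STAGE_DEFAULTS = {
    "post_s1": {"period_s": 0.429, "p_ra_mmhg": 5.4, "pinch": 0.10},
    "pre_s2": {"period_s": 0.5, "p_ra_mmhg": 7.2, "pinch": 0.10},
}


class NorwoodLPN:
    """Population-calibrated 0D model of one palliation stage.

    Parameters
    ----------
    targets
        Calibration targets (clinical units).
    segments, shunt
        Vessel geometry; defaults come from the pooled literature tables.
    heart_init
        Initial heart parameterisation; the elastance amplitude and atrial
        pressure are calibration outputs.
    population
        Optional pooled :class:`~norwoodlpn.meta.PopulationTargets` kept for
        reporting.
    """

    def __init__(
        self,
        targets: cal.CalibrationTargets,
        segments: list[geometry.VesselSegment],
        shunt: geometry.ShuntSpec,
        heart_init: HeartParams | None = None,
        blood: geometry.BloodProperties = geometry.BloodProperties(),
        population: meta.PopulationTargets | None = None,
        stage: str | None = None,
    ):
        self.targets = targets
        self.segments = segments
        self.shunt = shunt
        self.blood = blood
        self.population = population
        self.stage = stage or targets.stage
        if heart_init is None:
            heart_init = HeartParams.from_clinical(
                p_ra_mmhg=targets.p_ra_mmhg,
                e_max_mmhg_ml=16.0,
                e_min_mmhg_ml=0.4,
                v0_ml=2.0 if self.stage == "post_s1" else 3.0,
                period_s=targets.period_s,
            )
        self.heart_init = heart_init

    # -- constructors ---------------------------------------------------------
    @classmethod
    def from_literature(
        cls,
        stage: str,
        weighting: str = "inverse_sd2",
        pinch_fraction: float | None = None,
        shunt_K: float = 2.0,
        **target_kw,
    ) -> "NorwoodLPN":
        """Build the stage model by pooling the packaged literature tables.

        Post-S1 native segments (PAs, descending aorta) take healthy
        neonatal diameters; the reconstructed region takes the pooled HLHS
        arch measurement. The pre-S2 pinch starts at the post-S1 value and
        is solved during ``fit``.
        """
        if stage not in _STAGE_DEFAULTS:
            raise ValueError(f"unknown stage {stage!r}")
        pop = meta.default_targets(stage, weighting=weighting)
        targets = cal.CalibrationTargets.from_population(pop, **target_kw)

        pooled_diam = {
            k: pop[k]
            for k in ("lpa_diameter", "rpa_diameter", "ascending_aorta_diameter",
                      "transverse_arch_diameter", "descending_aorta_diameter")
            if k in pop
        }
        if stage == "post_s1":
            healthy = [r for r in meta.packaged_table("table2") if r.stage == "healthy"]
            for k in ("lpa_diameter", "rpa_diameter", "descending_aorta_diameter"):
                recs = [r for r in healthy if r.parameter == k]
                if recs:
                    pooled_diam[k] = meta.pooled_fixed_effect(
                        recs, weighting=weighting).pooled_mean
        if pinch_fraction is None:
            pinch_fraction = _STAGE_DEFAULTS[stage]["pinch"]
        segments, shunt = geometry.default_geometry(
            stage, pooled_diam, pinch_fraction=pinch_fraction, shunt_K=shunt_K)
        return cls(targets, segments, shunt, population=pop, stage=stage)

    @classmethod
    def from_targets(cls, targets: cal.CalibrationTargets, **kw) -> "NorwoodLPN":
        segments, shunt = geometry.default_geometry(targets.stage)
        return cls(targets, segments, shunt, **kw)

    # -- fitting --------------------------------------------------------------
    def build_netlist(self) -> Netlist:
        """Arterial netlist fragment (no Windkessels/heart attached yet)."""
        nl = geometry.build_network(self.segments, self.shunt, self.blood)
        nl.meta["stage"] = self.stage
        nl.meta["p_ra_mmhg"] = self.targets.p_ra_mmhg
        return nl

    def fit(
        self,
        inner_tol: float = 0.02,
        co_tol: float = 0.02,
        solve_shunt_pinch: bool | None = None,
        dt: float | None = None,
        max_cycles: int = 10,
        periodicity_tol: float = 0.01,
        **cal_kw,
    ) -> "NorwoodResults":
        """Run the two-step calibration and return fitted results.

        The pre-S2 pinch inverse problem runs automatically whenever the
        targets include a mean PA pressure (override with
        ``solve_shunt_pinch``).
        """
        if solve_shunt_pinch is None:
            solve_shunt_pinch = self.targets.mean_pa_mmhg is not None
        nl = self.build_netlist()
        log: list[dict] = []
        sim_kw: dict[str, Any] = {"max_cycles": max_cycles,
                                  "periodicity_tol": periodicity_tol}
        if dt is not None:
            sim_kw["dt"] = dt
        result, waves = cal.two_step_calibration(
            nl, self.targets, self.heart_init,
            inner_tol=inner_tol, co_tol=co_tol,
            solve_shunt_pinch=solve_shunt_pinch, log=log, **sim_kw, **cal_kw)
        report = indices.compute_report(
            waves, nl.meta, blood=self.blood, stage=self.stage)
        return NorwoodResults(self, nl, result, waves, report)

    def simulate(self, netlist: Netlist | None = None, cycles: int = 10,
                 **sim_kw) -> engine.WaveformSet:
        """Simulate a (possibly uncalibrated) netlist for this stage."""
        nl = netlist if netlist is not None else self.build_netlist()
        return engine.simulate(nl, T=self.targets.period_s, max_cycles=cycles,
                               **sim_kw)


@dataclass
class NorwoodResults:
    """Calibrated-model results: parameters, waveforms, indices, diagnostics."""

    model: NorwoodLPN
    netlist: Netlist
    calibration: cal.CalibrationResult
    waveforms: engine.WaveformSet
    report: indices.IndexReport

    # -- parameter views ------------------------------------------------------
    @property
    def windkessel_frame(self) -> pd.DataFrame:
        rows = {}
        for outlet, wk in self.calibration.windkessels.items():
            rows[outlet] = {
                "R_p (dyn s/cm^5)": wk.R_p,
                "R_d (dyn s/cm^5)": wk.R_d,
                "C (cm^5/dyn)": wk.C,
                "P_ref (mmHg)": wk.P_ref / MMHG,
            }
        return pd.DataFrame(rows).T

    @property
    def heart_frame(self) -> pd.Series:
        h = self.calibration.heart
        return pd.Series({
            "P_RA (mmHg)": h.P_RA / MMHG,
            "E_max (mmHg/mL)": h.E_max / MMHG,
            "E_min (mmHg/mL)": h.E_min / MMHG,
            "V_0 (mL)": h.V0,
            "period (s)": h.T,
        })

    @property
    def pinch_fraction(self) -> float | None:
        return self.calibration.pinch_fraction

    @property
    def max_rel_dev(self) -> float:
        return self.calibration.max_rel_dev

    def summary(self) -> str:
        """Human-readable fit summary (targets vs achieved, parameters)."""
        t = self.model.targets
        lines = [
            f"Norwood 0D circulation - stage {self.model.stage}",
            "=" * 58,
            f"converged: {self.calibration.converged}   "
            f"max index deviation: {100 * self.max_rel_dev:.2f}%",
            "",
            f"{'index':<22}{'target':>10}{'fitted':>10}{'dev %':>8}",
            "-" * 50,
        ]
        dev = self.calibration.deviations
        rep = self.report
        p = rep.pressures.get("inlet", {})
        fitted = {
            "systolic_pressure": p.get("systolic"),
            "diastolic_pressure": p.get("diastolic"),
            "mean_pressure": p.get("mean"),
            "pulse_pressure": p.get("pulse"),
            "cardiac_output": rep.cardiac_output_lmin,
            "qp_qs": rep.qp_qs,
            "mean_pa_pressure": rep.mean_pa_pressure_mmhg,
        }
        targets = {
            "systolic_pressure": t.systolic_mmhg,
            "diastolic_pressure": t.diastolic_mmhg,
            "mean_pressure": t.mean_mmhg,
            "pulse_pressure": t.pulse_mmhg,
            "cardiac_output": t.cardiac_output_lmin,
            "qp_qs": t.qp_qs,
            "mean_pa_pressure": t.mean_pa_mmhg,
        }
        for k, tv in targets.items():
            fv = fitted.get(k)
            if tv is None or fv is None or (isinstance(fv, float) and np.isnan(fv)):
                continue
            d = 100 * dev.get(k, abs(fv - tv) / abs(tv))
            lines.append(f"{k:<22}{tv:>10.3g}{fv:>10.3g}{d:>8.2f}")
        if rep.mean_pa_pressure_mmhg == rep.mean_pa_pressure_mmhg and (
                "mean_pa_pressure" not in targets or targets["mean_pa_pressure"] is None):
            lines.append(
                f"{'mean_pa_pressure':<22}{'(none)':>10}"
                f"{rep.mean_pa_pressure_mmhg:>10.3g}{'':>8}")
        shunt = self.netlist.meta["shunt"]
        lines += [
            "",
            f"shunt: nominal {shunt['nominal_diameter_mm']:.2f} mm, pinch "
            f"{shunt['pinch_fraction']:.3f} -> effective "
            f"{shunt['effective_diameter_mm']:.3g} mm (K={shunt['K']:.2f})",
            "",
            "Windkessel parameters (CGS):",
            self.windkessel_frame.to_string(float_format=lambda x: f"{x:.4g}"),
            "",
            "Heart parameters:",
            self.heart_frame.to_string(float_format=lambda x: f"{x:.4g}"),
        ]
        if "shunt" in rep.reynolds:
            re = rep.reynolds["shunt"]
            lines.append(
                f"\nshunt Reynolds: Re_avg {re['Re_avg']:.0f}, "
                f"Re_max {re['Re_max']:.0f}")
        return "\n".join(lines)

    def resimulate(self, **sim_kw) -> engine.WaveformSet:
        """Re-run the calibrated netlist (e.g. at a finer dt)."""
        sim_kw.setdefault("x0", self.waveforms.meta["final_state"])
        return engine.simulate(self.netlist, T=self.model.targets.period_s,
                               **sim_kw)

    def plot_waveforms(self, path=None):
        """Pressure/flow waveform panel (matplotlib figure)."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        w = self.waveforms
        s = w.cycle_slice(-1)
        t = w.time[s] - w.time[s][0]
        fig, axes = plt.subplots(2, 1, figsize=(7, 6), sharex=True)
        for node in ("inlet", "pa"):
            if node in w.pressures:
                axes[0].plot(t, w.pressures[node][s] / MMHG, label=node)
        axes[0].set_ylabel("pressure (mmHg)")
        axes[0].legend(loc="upper right", fontsize=8)
        for cid in ("heart_naov", "inflow", "shunt", "seg_LPA", "seg_RPA", "seg_DAo"):
            if cid in w.flows:
                axes[1].plot(t, w.flows[cid][s], label=cid)
        axes[1].set_ylabel("flow (cm$^3$/s)")
        axes[1].set_xlabel("time in cycle (s)")
        axes[1].legend(loc="upper right", fontsize=8)
        fig.suptitle(f"stage {self.model.stage}")
        fig.tight_layout()
        if path is not None:
            fig.savefig(path, dpi=120)
            plt.close(fig)
        return fig
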