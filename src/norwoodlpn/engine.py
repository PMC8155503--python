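"""0D circuit simulator: stiff ODE integration of arbitrary netlists.

The state vector holds the pressure of every capacitive node, the volume of
every elastance chamber, and the flow of every branch with inertance
(inductors, diode valves, nonlinear shunt). Nodes without storage are
eliminated algebraically at every right-hand-side evaluation (linear nodal
analysis). Diode valves are pressure/flow-controlled switches regularized
by a steep but smooth closed-state resistance, so the whole system stays an
ODE and is integrated with a stiff (BDF) scheme cycle by cycle until
cycle-to-cycle periodicity of the pressure field.
"""
from __future__ import annotations

import io
from dataclasses import dataclass, field
from functools import lru_cache
import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.linalg import lu_factor, lu_solve

from .circuits import HeartParams, WindkesselParams  # re-exported engine types
from .netlist import GROUND, Netlist, SchemaError
from .synth import flow_source_function
from .units import MMHG, cgs_to_lmin, cgs_to_mmhg

__all__ = [
    "WaveformSet",
    "LPNSystem",
    "assemble",
    "simulate",
    "check_periodicity",
    "elastance",
    "normalized_activation",
    "dc_operating_point",
    "SimulationError",
    "WindkesselParams",
    "HeartParams",
]

# Diode regularization: closed-state resistance and smooth-switch widths.
R_CLOSED = 1.0e10          # dyn*s/cm^5
EPS_P = 1.0e-3 * MMHG      # pressure switch width
EPS_Q = 1.0e-5             # flow switch width, cm^3/s


class SimulationError(RuntimeError):
    """Integration failed; carries the last valid state for diagnosis."""

    def __init__(self, message: str, t: float | None = None, state=None):
        super().__init__(message)
        self.t = t
        self.state = state


# -- elastance ---------------------------------------------------------------

@lru_cache(maxsize=64)
def _activation_norm(m1: float, m2: float, tau1_frac: float, tau2_frac: float) -> float:
    x = np.linspace(0.0, 1.0, 4001)
    return float(_raw_activation(x, m1, m2, tau1_frac, tau2_frac).max())


def _raw_activation(x, m1, m2, tau1_frac, tau2_frac):
    g1 = (x / tau1_frac) ** m1
    g2 = (x / tau2_frac) ** m2
    return (g1 / (1.0 + g1)) / (1.0 + g2)


def normalized_activation(t, T, m1=1.32, m2=27.4, tau1_frac=0.269, tau2_frac=0.452):
    """Double-Hill activation e_n(t), periodic in T, normalized to max 1."""
    x = (np.asarray(t, dtype=float) % T) / T
    return _raw_activation(x, m1, m2, tau1_frac, tau2_frac) / _activation_norm(
        m1, m2, tau1_frac, tau2_frac
    )


def elastance(t, params: HeartParams):
    """Time-varying chamber elastance E(t) = (E_max-E_min) e_n(t) + E_min (CGS)."""
    e_n = normalized_activation(
        t, params.T, params.m1, params.m2, params.tau1_frac, params.tau2_frac
    )
    return (params.E_max - params.E_min) * e_n + params.E_min


# -- waveforms ---------------------------------------------------------------

@dataclass
class WaveformSet:
    """Simulated periodic pressure/flow traces on a uniform time grid."""

    time: np.ndarray                       # s
    pressures: dict[str, np.ndarray]       # node -> dyn/cm^2
    flows: dict[str, np.ndarray]           # component id -> cm^3/s
    period: float
    dt: float
    cycles_run: int
    periodicity_achieved: bool
    cycle_index: int | None = None         # first cycle meeting the criterion
    volumes: dict[str, np.ndarray] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    @property
    def samples_per_cycle(self) -> int:
        return int(round(self.period / self.dt))

    def cycle_slice(self, k: int = -1) -> slice:
        n = self.samples_per_cycle
        if k < 0:
            k += self.cycles_run
        return slice(k * n, (k + 1) * n + 1)

    def last_cycle(self, signal: np.ndarray) -> np.ndarray:
        return signal[self.cycle_slice(-1)]

    def cycle_mean(self, signal: np.ndarray) -> float:
        s = self.cycle_slice(-1)
        return float(np.trapezoid(signal[s], self.time[s]) / self.period)

    def mean_pressure(self, node: str) -> float:
        return self.cycle_mean(self.pressures[node])

    def mean_flow(self, comp_id: str) -> float:
        return self.cycle_mean(self.flows[comp_id])

    def to_frame(self) -> pd.DataFrame:
        """Clinical-unit DataFrame: time_s, P_<node>_mmHg, Q_<id>_Lmin."""
        data = {"time_s": self.time}
        for node, p in self.pressures.items():
            data[f"P_{node}_mmHg"] = cgs_to_mmhg(p)
        for cid, q in self.flows.items():
            data[f"Q_{cid}_Lmin"] = cgs_to_lmin(q)
        return pd.DataFrame(data)

    def to_csv(self, path) -> None:
        header = (
            f"# norwoodlpn waveforms: period_s={self.period} dt_s={self.dt} "
            f"cycles={self.cycles_run} periodic={self.periodicity_achieved}\n"
        )
        buf = io.StringIO()
        self.to_frame().to_csv(buf, index=False)
        with open(path, "w") as fh:
            fh.write(header + buf.getvalue())


def check_periodicity(w: WaveformSet, tol: float = 0.01) -> tuple[bool, int | None]:
    """Cycle-to-cycle periodicity of the pressure field.

    Achieved at cycle k when, for every pressure signal, the maximum
    difference from the previous cycle is at most ``tol`` of that signal's
    pulse pressure (floored to avoid zero-pulse degeneracy).
    """
    if w.cycles_run < 2:
        raise ValueError("periodicity check needs at least 2 complete cycles")
    n = w.samples_per_cycle
    for k in range(1, w.cycles_run):
        ok = True
        for p in w.pressures.values():
            prev = p[(k - 1) * n: k * n + 1]
            cur = p[k * n: (k + 1) * n + 1]
            pulse = cur.max() - cur.min()
            scale = max(pulse, 0.05 * abs(cur).max(), 1e-9)
            if np.max(np.abs(cur - prev)) / scale > tol:
                ok = False
                break
        if ok:
            return True, k
    return False, None


# -- assembly ----------------------------------------------------------------

class LPNSystem:
    """Assembled dynamical system for one netlist.

    State layout: capacitive node pressures, chamber volumes, inductive
    branch flows (inductors, valves, nonlinear resistors), in that order.
    """

    def __init__(self, nl: Netlist):
        self.netlist = nl
        nl.validate_connected()

        caps = nl.node_capacitance()
        self.sources = {c.a: c for c in nl.components if c.kind == "pressure_source"}
        self.chambers = [c for c in nl.components if c.kind == "elastance_chamber"]
        for c in self.chambers:
            if c.b != GROUND:
                raise SchemaError(f"{c.id}: chamber must reference ground")
            if c.a in caps or c.a in self.sources:
                raise SchemaError(f"{c.id}: chamber node cannot carry C or a source")
        for node in self.sources:
            if node in caps:
                raise SchemaError(f"source node {node} cannot also carry capacitance")

        nodes = [GROUND] + nl.nodes
        self.node_index = {n: i for i, n in enumerate(nodes)}
        self.n_nodes = len(nodes)
        ni = self.node_index

        self.cap_nodes = [n for n in nl.nodes if n in caps]
        self.cap_idx = np.array([ni[n] for n in self.cap_nodes], dtype=int)
        self.cap_C = np.array([caps[n] for n in self.cap_nodes])
        self.ch_idx = np.array([ni[c.a] for c in self.chambers], dtype=int)
        self.ch_V0 = np.array([c.params["V0"] for c in self.chambers])
        self.ch_par = [c.params for c in self.chambers]
        self.src_idx = np.array([ni[n] for n in self.sources], dtype=int)
        self.src_P = np.array([c.params["P"] for c in self.sources.values()])

        # branch families
        self.res = [c for c in nl.components if c.kind == "resistor"]
        self.ind = [c for c in nl.components
                    if c.kind in ("inductor", "diode_valve", "nonlinear_resistor")]
        self.flow_sources = [c for c in nl.components if c.kind == "flow_source"]
        self.fs_fn = [flow_source_function(c.params) for c in self.flow_sources]
        self.fs_a = np.array([ni[c.a] for c in self.flow_sources], dtype=int)
        self.fs_b = np.array([ni[c.b] for c in self.flow_sources], dtype=int)

        self.res_a = np.array([ni[c.a] for c in self.res], dtype=int)
        self.res_b = np.array([ni[c.b] for c in self.res], dtype=int)
        self.res_g = np.array([1.0 / c.params["R"] for c in self.res])

        self.ind_a = np.array([ni[c.a] for c in self.ind], dtype=int)
        self.ind_b = np.array([ni[c.b] for c in self.ind], dtype=int)
        self.ind_L = np.array([c.params["L"] for c in self.ind])
        if np.any(self.ind_L <= 0):
            raise SchemaError("all inductive branches need L > 0")
        self.ind_R = np.array([c.params.get("R", c.params.get("r_lin", 0.0))
                               for c in self.ind])
        self.ind_quad = np.array([c.params.get("a_quad", 0.0) for c in self.ind])
        self.is_valve = np.array([c.kind == "diode_valve" for c in self.ind])
        self.valve_Ropen = np.array(
            [c.params.get("R_open", 0.0) for c in self.ind])

        # node classification
        known = set(self.cap_idx) | set(self.ch_idx) | set(self.src_idx) | {0}
        self.alg_idx = np.array(
            [ni[n] for n in nl.nodes if ni[n] not in known], dtype=int)
        self._build_algebraic()

        self.n_cap = len(self.cap_idx)
        self.n_ch = len(self.ch_idx)
        self.n_ind = len(self.ind)
        self.n_state = self.n_cap + self.n_ch + self.n_ind

    # dims: state = #capacitors + #chambers + #inductive branches
    @property
    def state_names(self) -> list[str]:
        return (
            [f"P:{n}" for n in self.cap_nodes]
            + [f"V:{c.id}" for c in self.chambers]
            + [f"Q:{c.id}" for c in self.ind]
        )

    def _build_algebraic(self) -> None:
        na = len(self.alg_idx)
        self._alg_pos = {int(g): i for i, g in enumerate(self.alg_idx)}
        if na == 0:
            self._alg_lu = None
            return
        G = np.zeros((na, na))
        for a, b, g in zip(self.res_a, self.res_b, self.res_g):
            ia, ib = self._alg_pos.get(int(a)), self._alg_pos.get(int(b))
            if ia is not None:
                G[ia, ia] += g
                if ib is not None:
                    G[ia, ib] -= g
            if ib is not None:
                G[ib, ib] += g
                if ia is not None:
                    G[ib, ia] -= g
        if np.linalg.matrix_rank(G) < na:
            bad = [n for n, i in self.node_index.items()
                   if i in set(map(int, self.alg_idx))]
            raise SchemaError(
                f"nodes {bad} have no storage and no resistive path to a known "
                "pressure; circuit is not well-posed")
        self._alg_lu = lu_factor(G)

    # -- pressure solution ----------------------------------------------------
    def _pressures(self, t: float, y: np.ndarray) -> np.ndarray:
        P = np.zeros(self.n_nodes)
        if self.n_cap:
            P[self.cap_idx] = y[: self.n_cap]
        if self.n_ch:
            V = y[self.n_cap: self.n_cap + self.n_ch]
            for i, par in enumerate(self.ch_par):
                E = (par["E_max"] - par["E_min"]) * normalized_activation(
                    t, par["T"], par.get("m1", 1.32), par.get("m2", 27.4),
                    par.get("tau1_frac", 0.269), par.get("tau2_frac", 0.452)
                ) + par["E_min"]
                P[self.ch_idx[i]] = E * (V[i] - self.ch_V0[i])
        if len(self.src_idx):
            P[self.src_idx] = self.src_P
        if self._alg_lu is not None:
            q = y[self.n_cap + self.n_ch:]
            rhs = np.zeros(len(self.alg_idx))
            # resistive coupling to known nodes
            for a, b, g in zip(self.res_a, self.res_b, self.res_g):
                ia, ib = self._alg_pos.get(int(a)), self._alg_pos.get(int(b))
                if ia is not None and ib is None:
                    rhs[ia] += g * P[b]
                if ib is not None and ia is None:
                    rhs[ib] += g * P[a]
            # injected known flows (inductive branches, flow sources)
            for qi, a, b in zip(q, self.ind_a, self.ind_b):
                ia, ib = self._alg_pos.get(int(a)), self._alg_pos.get(int(b))
                if ia is not None:
                    rhs[ia] -= qi
                if ib is not None:
                    rhs[ib] += qi
            for fn, a, b in zip(self.fs_fn, self.fs_a, self.fs_b):
                qs = float(fn(t))
                ia, ib = self._alg_pos.get(int(a)), self._alg_pos.get(int(b))
                if ia is not None:
                    rhs[ia] -= qs
                if ib is not None:
                    rhs[ib] += qs
            P[self.alg_idx] = lu_solve(self._alg_lu, rhs)
        return P

    def _branch_flows(self, t, y, P):
        q_ind = y[self.n_cap + self.n_ch:]
        q_res = (P[self.res_a] - P[self.res_b]) * self.res_g
        q_fs = np.array([float(fn(t)) for fn in self.fs_fn])
        return q_ind, q_res, q_fs

    def rhs(self, t: float, y: np.ndarray) -> np.ndarray:
        P = self._pressures(t, y)
        q_ind, q_res, q_fs = self._branch_flows(t, y, P)

        net = np.zeros(self.n_nodes)
        np.subtract.at(net, self.res_a, q_res)
        np.add.at(net, self.res_b, q_res)
        np.subtract.at(net, self.ind_a, q_ind)
        np.add.at(net, self.ind_b, q_ind)
        np.subtract.at(net, self.fs_a, q_fs)
        np.add.at(net, self.fs_b, q_fs)

        dy = np.empty_like(y)
        dy[: self.n_cap] = net[self.cap_idx] / self.cap_C
        dy[self.n_cap: self.n_cap + self.n_ch] = net[self.ch_idx]

        dp = P[self.ind_a] - P[self.ind_b]
        r_eff = self.ind_R + self.ind_quad * np.abs(q_ind)
        if self.is_valve.any():
            closed = (
                0.25
                * (1.0 - np.tanh(dp / EPS_P))
                * (1.0 - np.tanh(q_ind / EPS_Q))
            )
            r_eff = np.where(
                self.is_valve, self.valve_Ropen + R_CLOSED * closed, r_eff
            )
        dy[self.n_cap + self.n_ch:] = (dp - r_eff * q_ind) / self.ind_L
        return dy

    def initial_state(self) -> np.ndarray:
        """Zero state, except chambers start at their diastolic filling volume."""
        y0 = np.zeros(self.n_state)
        for i, par in enumerate(self.ch_par):
            p_fill = 0.0
            if "heart_Pra" in self.netlist:
                p_fill = self.netlist["heart_Pra"].params["P"]
            y0[self.n_cap + i] = self.ch_V0[i] + p_fill / par["E_min"]
        return y0

    def atol(self) -> np.ndarray:
        a = np.empty(self.n_state)
        a[: self.n_cap] = 1e-1           # dyn/cm^2
        a[self.n_cap: self.n_cap + self.n_ch] = 1e-6   # cm^3
        a[self.n_cap + self.n_ch:] = 1e-7              # cm^3/s
        return a


def assemble(nl: Netlist) -> LPNSystem:
    """Build the dynamical system (validates topology and well-posedness)."""
    return LPNSystem(nl)


def simulate(
    nl: Netlist | LPNSystem,
    T: float,
    dt: float | None = None,
    max_cycles: int = 20,
    periodicity_tol: float = 0.01,
    x0: np.ndarray | None = None,
    min_cycles: int = 2,
    rtol: float = 1e-6,
) -> WaveformSet:
    """Integrate cycle by cycle until cycle-to-cycle pressure periodicity.

    Output is sampled on a uniform grid of spacing ``dt`` (default T/1000;
    must satisfy dt <= T/500). Stops at the first cycle meeting the
    periodicity criterion, or at ``max_cycles`` with the flag unset.
    """
    sys = nl if isinstance(nl, LPNSystem) else assemble(nl)
    if dt is None:
        dt = T / 1000.0
    n = int(round(T / dt))
    if n < 500:
        raise ValueError("need dt <= T/500")
    dt = T / n

    y = sys.initial_state() if x0 is None else np.asarray(x0, dtype=float).copy()
    if y.shape != (sys.n_state,):
        raise ValueError(f"x0 must have shape ({sys.n_state},)")

    states = [y.copy()]
    times = [0.0]
    atol = sys.atol()
    achieved = False
    cycle_index = None
    press_hist: list[np.ndarray] = []

    all_Y = []
    for k in range(max_cycles):
        t_eval = (np.arange(0, n + 1) + k * n) * dt
        sol = solve_ivp(
            sys.rhs, (t_eval[0], t_eval[-1]), y, method="BDF",
            t_eval=t_eval, rtol=rtol, atol=atol,
        )
        if not sol.success:
            raise SimulationError(
                f"integration failed in cycle {k}: {sol.message}",
                t=float(sol.t[-1]) if len(sol.t) else t_eval[0],
                state=sol.y[:, -1] if sol.y.size else y,
            )
        y = sol.y[:, -1].copy()
        block = sol.y[:, 1:] if k > 0 else sol.y
        all_Y.append(block)
        press_hist.append(sol.y[: sys.n_cap, :])
        if k >= 1:
            ok = _cycles_match(press_hist[-2], press_hist[-1], periodicity_tol)
            if ok and k + 1 >= min_cycles:
                achieved = True
                cycle_index = k
                break

    Y = np.concatenate(all_Y, axis=1)
    cycles_run = len(all_Y)
    time = np.arange(Y.shape[1]) * dt
    return _waveforms(sys, time, Y, T, dt, cycles_run, achieved, cycle_index)


def _cycles_match(prev: np.ndarray, cur: np.ndarray, tol: float) -> bool:
    for i in range(cur.shape[0]):
        pulse = cur[i].max() - cur[i].min()
        scale = max(pulse, 0.05 * np.abs(cur[i]).max(), 1e-9)
        if np.max(np.abs(cur[i] - prev[i])) / scale > tol:
            return False
    return True


def _waveforms(sys: LPNSystem, time, Y, T, dt, cycles, achieved, cycle_index):
    nt = Y.shape[1]
    P = np.zeros((sys.n_nodes, nt))
    for j in range(nt):
        P[:, j] = sys._pressures(time[j], Y[:, j])
    pressures = {
        n: P[i] for n, i in sys.node_index.items() if n != GROUND
    }
    flows: dict[str, np.ndarray] = {}
    for i, c in enumerate(sys.ind):
        flows[c.id] = Y[sys.n_cap + sys.n_ch + i]
    for i, c in enumerate(sys.res):
        flows[c.id] = (P[sys.res_a[i]] - P[sys.res_b[i]]) * sys.res_g[i]
    for c, fn in zip(sys.flow_sources, sys.fs_fn):
        flows[c.id] = np.asarray(fn(time), dtype=float)
    volumes = {
        c.id: Y[sys.n_cap + i] for i, c in enumerate(sys.chambers)
    }
    w = WaveformSet(
        time=time, pressures=pressures, flows=flows, period=T, dt=dt,
        cycles_run=cycles, periodicity_achieved=achieved,
        cycle_index=cycle_index, volumes=volumes,
    )
    w.meta["final_state"] = Y[:, -1].copy()
    w.meta["state_names"] = sys.state_names
    return w


# -- DC (cycle-mean) operating point ------------------------------------------

def dc_operating_point(nl: Netlist, n_iter: int = 8) -> tuple[dict, dict]:
    """Mean-flow nodal solution with inductors shorted and capacitors open.

    Valid for source-driven (heartless) netlists; nonlinear shunt branches
    are linearized iteratively at their own operating flow. Returns
    (node pressures, branch flows) in CGS. Used to seed calibration and
    warm-start transients.
    """
    if any(c.kind == "elastance_chamber" for c in nl.components):
        raise SchemaError("DC operating point undefined with an active chamber")
    nodes = [n for n in nl.nodes]
    ni = {n: i for i, n in enumerate(nodes)}
    src = {c.a: c.params["P"] for c in nl.components if c.kind == "pressure_source"}
    unknown = [n for n in nodes if n not in src]
    ui = {n: i for i, n in enumerate(unknown)}
    nb = len(unknown)

    branches = [c for c in nl.components
                if c.kind in ("resistor", "inductor", "diode_valve", "nonlinear_resistor")]
    q_lin = {c.id: 0.0 for c in branches}

    def branch_R(c, q):
        if c.kind == "resistor":
            return c.params["R"]
        if c.kind == "inductor":
            return max(c.params.get("R", 0.0), 1e-12)
        if c.kind == "diode_valve":
            return c.params["R_open"]
        return max(c.params["r_lin"] + c.params["a_quad"] * abs(q), 1e-12)

    def node_P(n, x):
        if n == GROUND:
            return 0.0
        if n in src:
            return src[n]
        return x[ui[n]]

    # mean injected flow per flow source
    inj = np.zeros(nb)
    for c in nl.components:
        if c.kind != "flow_source":
            continue
        fn = flow_source_function(c.params)
        tt = np.linspace(0.0, 1.0, 2001)
        # constant sources are exact; periodic profiles need the real period
        period = c.params.get("profile", {}).get("period_s", 1.0) if isinstance(
            c.params.get("profile"), dict) else 1.0
        qm = float(np.mean(fn(tt * period)))
        if c.a in ui:
            inj[ui[c.a]] -= qm
        if c.b in ui:
            inj[ui[c.b]] += qm

    x = np.zeros(nb)
    for _ in range(n_iter):
        G = np.zeros((nb, nb))
        rhs = inj.copy()
        for c in branches:
            g = 1.0 / branch_R(c, q_lin[c.id])
            ia = ui.get(c.a)
            ib = ui.get(c.b)
            pa_known = 0.0 if c.a in ui else node_P(c.a, x)
            pb_known = 0.0 if c.b in ui else node_P(c.b, x)
            if ia is not None:
                G[ia, ia] += g
                rhs[ia] += g * pb_known
                if ib is not None:
                    G[ia, ib] -= g
            if ib is not None:
                G[ib, ib] += g
                rhs[ib] += g * pa_known
                if ia is not None:
                    G[ib, ia] -= g
        x = np.linalg.solve(G, rhs)
        for c in branches:
            q_lin[c.id] = (node_P(c.a, x) - node_P(c.b, x)) / branch_R(c, q_lin[c.id])

    P = {n: node_P(n, x) for n in nodes}
    Q = {c.id: q_lin[c.id] for c in branches}
    return P, Q
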