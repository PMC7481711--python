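"""Switched lumped-element network: assembly, instantaneous solves, integration.

The pneumatic system maps onto an electrical network: volume <-> charge,
flow <-> current, pressure <-> voltage, tube <-> resistor, lung + chest
wall <-> capacitor (compliance), one-way valve <-> diode (check valve) and
ventilator inspiration/expiration porting <-> phase-gated switches.  All
pressures are gauge (atmosphere = ground = 0).

State variables are the compliance pressures.  At any instant the rest of
the network is resistive, so node pressures follow from a nodal-balance
solve conditioned on the conduction state of each valve; conduction states
are resolved by fixed-point iteration with exhaustive enumeration as a
fallback.  Check valves are piecewise-linear ideal: a small on-resistance
and a very large blocking (leak) resistance keep the nodal system
well-posed without measurably altering results.  Integration restarts at
every phase edge and at every valve conduction change so the ODE seen by
the adaptive solver is smooth within each segment.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np
from scipy.integrate import solve_ivp
from scipy.linalg import lu_factor, lu_solve

from .params import VentilatorSettings
from .waveform import Phase, PhaseSchedule, phase_pressure, schedule

#: On-resistance of a conducting valve, cmH2O/L/s.
R_ON = 1e-4

#: Leak resistance of a blocking valve (and of any zero-valued resistor),
#: cmH2O/L/s.  >9 orders of magnitude above the tubing resistances.
R_LEAK = 1e8

#: Switching tolerances separating genuine reverse flow / forward bias from
#: leak-level artifacts (leak currents are ~1e-9 L/s; real flows ~0.01-1).
#: A conducting valve blocks when its flow drops below -FLOW_TOL; a blocked
#: valve conducts when its forward driving pressure exceeds DP_TOL.
FLOW_TOL = 1e-7   # L/s
DP_TOL = 1e-7     # cmH2O

#: Cap on integration restarts within one phase segment.
_MAX_RESTARTS = 50

GROUND = "atm"


class CircuitError(RuntimeError):
    """A network could not be solved (singular system or no consistent
    valve conduction assignment)."""


class Kind(Enum):
    RESISTOR = "resistor"
    COMPLIANCE = "compliance"
    SOURCE = "source"
    CHECK_VALVE = "check_valve"
    PHASE_VALVE = "phase_valve"


@dataclass(frozen=True)
class Component:
    """Two-terminal element between ``node_a`` and ``node_b``.

    ``value`` is a resistance (cmH2O/L/s) or compliance (L/cmH2O); unused
    for sources and valves.  A CHECK_VALVE permits flow a -> b only.  A
    PHASE_VALVE conducts only while the breath phase equals ``gate``.
    """

    name: str
    kind: Kind
    node_a: str
    node_b: str
    value: float | None = None
    gate: Phase | None = None

    def __post_init__(self) -> None:
        if self.node_a == self.node_b:
            raise ValueError(f"{self.name}: node_a == node_b ({self.node_a})")
        if self.value is not None and self.value < 0:
            raise ValueError(f"{self.name}: value must be non-negative")
        if self.kind is Kind.PHASE_VALVE and self.gate is None:
            raise ValueError(f"{self.name}: phase valve requires a gate phase")


@dataclass(frozen=True)
class PatientProbe:
    """Named nodes/components of one patient branch for signal extraction."""

    name: str
    wye: str
    airway: str
    alveolar: str
    compliance: str
    ett: str
    c_l: float


@dataclass
class Netlist:
    """A connected network with exactly one ground and one pressure source."""

    components: list[Component]
    ground: str = GROUND
    probes: dict[str, PatientProbe] = field(default_factory=dict)
    label: str = ""

    @property
    def state_vars(self) -> list[Component]:
        """Compliance components, in insertion order; one state each."""
        return [c for c in self.components if c.kind is Kind.COMPLIANCE]

    @property
    def check_valves(self) -> list[Component]:
        return [c for c in self.components if c.kind is Kind.CHECK_VALVE]

    def validate(self) -> None:
        names = [c.name for c in self.components]
        if len(set(names)) != len(names):
            raise ValueError("duplicate component names")
        sources = [c for c in self.components if c.kind is Kind.SOURCE]
        if len(sources) != 1:
            raise ValueError(f"expected exactly one source, found {len(sources)}")
        # connectivity (union-find over component endpoints + ground)
        parent: dict[str, str] = {}

        def find(x: str) -> str:
            parent.setdefault(x, x)
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for c in self.components:
            parent[find(c.node_a)] = find(c.node_b)
        roots = {find(n) for n in parent}
        if len(roots) > 1:
            raise ValueError("network is not connected")
        if self.ground not in parent:
            raise ValueError("ground node is not attached to any component")

    def dump(self) -> str:
        """Plain-text netlist: one component per line (kind, nodes, value)."""
        lines = [f"# netlist {self.label} (ground={self.ground})"]
        for c in self.components:
            extra = "" if c.value is None else f" {c.value:g}"
            gate = "" if c.gate is None else f" gate={c.gate.value}"
            lines.append(f"{c.name} {c.kind.value} {c.node_a} {c.node_b}{extra}{gate}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# Compiled nodal solver
# ---------------------------------------------------------------------------

class CompiledNetwork:
    """Netlist compiled to indexed arrays with per-conduction-state LU caches.

    Fixed-pressure nodes are the ground, the source terminal and every
    compliance terminal (the capacitor pressure IS the state variable);
    the remaining nodes are solved from nodal balance.
    """

    def __init__(self, netlist: Netlist, r_on: float = R_ON, r_leak: float = R_LEAK):
        netlist.validate()
        self.netlist = netlist
        self.r_on = r_on
        self.r_leak = r_leak

        (self.source,) = [c for c in netlist.components if c.kind is Kind.SOURCE]
        if self.source.node_b != netlist.ground:
            raise ValueError("source node_b must be the ground node")
        self.compliances = netlist.state_vars
        for c in self.compliances:
            if c.node_b != netlist.ground:
                raise ValueError(f"{c.name}: compliance node_b must be ground")
            if not c.value or c.value <= 0:
                raise ValueError(f"{c.name}: compliance value must be positive")
        self.check_valves = netlist.check_valves

        # node ordering: fixed nodes first (ground, source, compliances)
        fixed = [netlist.ground, self.source.node_a] + [c.node_a for c in self.compliances]
        if len(set(fixed)) != len(fixed):
            raise ValueError("ground, source and compliance nodes must be distinct")
        all_nodes = list(fixed)
        for c in netlist.components:
            for n in (c.node_a, c.node_b):
                if n not in all_nodes:
                    all_nodes.append(n)
        self.nodes = all_nodes
        self.node_index = {n: i for i, n in enumerate(all_nodes)}
        self.n_fixed = len(fixed)
        self.unknown_nodes = all_nodes[self.n_fixed:]

        # resistive elements (everything except source and compliances)
        self.elements = [c for c in netlist.components
                         if c.kind in (Kind.RESISTOR, Kind.CHECK_VALVE, Kind.PHASE_VALVE)]
        self.el_a = np.array([self.node_index[c.node_a] for c in self.elements])
        self.el_b = np.array([self.node_index[c.node_b] for c in self.elements])
        self.el_index = {c.name: i for i, c in enumerate(self.elements)}
        self.cv_el = [self.el_index[c.name] for c in self.check_valves]
        self.comp_nodes = np.array([self.node_index[c.node_a] for c in self.compliances])
        self.c_values = np.array([c.value for c in self.compliances])
        self._cache: dict = {}

    # -- assembly -----------------------------------------------------------

    def _resistances(self, phase: Phase, states: tuple[bool, ...]) -> np.ndarray:
        r = np.empty(len(self.elements))
        icv = 0
        for i, c in enumerate(self.elements):
            if c.kind is Kind.RESISTOR:
                # clamp to the on-resistance so a zero-valued resistor
                # behaves as an ideal connection without a singular stamp
                r[i] = max(c.value, self.r_on)
            elif c.kind is Kind.PHASE_VALVE:
                r[i] = self.r_on if c.gate is phase else self.r_leak
            else:  # CHECK_VALVE
                r[i] = self.r_on if states[icv] else self.r_leak
                icv += 1
        return r

    def _factor(self, phase: Phase, states: tuple[bool, ...]):
        key = (phase, states)
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        nu = len(self.unknown_nodes)
        g = 1.0 / self._resistances(phase, states)
        G = np.zeros((nu, nu))
        B = np.zeros((nu, self.n_fixed))
        for gi, ia, ib in zip(g, self.el_a, self.el_b):
            for me, other in ((ia, ib), (ib, ia)):
                if me >= self.n_fixed:
                    u = me - self.n_fixed
                    G[u, u] += gi
                    if other >= self.n_fixed:
                        G[u, other - self.n_fixed] -= gi
                    else:
                        B[u, other] += gi
        try:
            lu = lu_factor(G)
        except Exception as exc:  # singular nodal system
            raise CircuitError(
                f"singular nodal system among nodes {self.unknown_nodes}: {exc}"
            ) from exc
        diag = np.abs(np.diag(lu[0]))
        if nu and diag.min() < 1e-14 * max(diag.max(), 1.0):
            bad = self.unknown_nodes[int(np.argmin(diag))]
            raise CircuitError(f"floating subnetwork near node {bad!r}")
        out = (lu, B, g)
        self._cache[key] = out
        return out

    # -- instantaneous solves ----------------------------------------------

    def pressures(self, phase: Phase, comp_p: np.ndarray, p_src,
                  states: tuple[bool, ...]) -> np.ndarray:
        """Node pressures for given compliance states and source pressure.

        ``comp_p`` has shape (n_comp,) or (n_comp, m) for a batch of m
        instants; ``p_src`` is a scalar or shape (m,).  Returns pressures
        for every node, shape (n_nodes,) or (n_nodes, m).
        """
        comp_p = np.asarray(comp_p, dtype=float)
        batched = comp_p.ndim == 2
        m = comp_p.shape[1] if batched else 1
        fixed = np.zeros((self.n_fixed, m))
        fixed[1] = p_src
        fixed[2:] = comp_p if batched else comp_p[:, None]
        lu, B, _ = self._factor(phase, states)
        unknown = lu_solve(lu, B @ fixed) if B.shape[0] else np.zeros((0, m))
        P = np.vstack([fixed, unknown])
        return P if batched else P[:, 0]

    def flows(self, phase: Phase, states: tuple[bool, ...], P: np.ndarray) -> np.ndarray:
        """Branch flow through every resistive element, a -> b positive."""
        _, _, g = self._factor(phase, states)
        if P.ndim == 2:
            return g[:, None] * (P[self.el_a] - P[self.el_b])
        return g * (P[self.el_a] - P[self.el_b])

    def compliance_currents(self, flows: np.ndarray) -> np.ndarray:
        """Net flow into each compliance node (its charging current)."""
        shape = (len(self.nodes),) + flows.shape[1:]
        net = np.zeros(shape)
        np.add.at(net, self.el_a, -flows)
        np.add.at(net, self.el_b, flows)
        return net[self.comp_nodes]

    def valve_drive(self, P: np.ndarray) -> np.ndarray:
        """Driving pressure across each check valve in its permitted direction."""
        if not self.cv_el:
            return np.zeros((0,) + P.shape[1:])
        ia = self.el_a[self.cv_el]
        ib = self.el_b[self.cv_el]
        return P[ia] - P[ib]

    def valve_flows(self, phase: Phase, states: tuple[bool, ...],
                    P: np.ndarray) -> np.ndarray:
        """Flow through each check valve, permitted direction positive."""
        if not self.cv_el:
            return np.zeros((0,) + P.shape[1:])
        return self.flows(phase, states, P)[self.cv_el]

    def _switch(self, phase: Phase, states: tuple[bool, ...],
                comp_p: np.ndarray, p_src: float) -> tuple[bool, ...]:
        """One step of the diode switching rule: a conducting valve blocks
        on reverse flow, a blocked valve conducts on forward bias."""
        P = self.pressures(phase, comp_p, p_src, states)
        dp = self.valve_drive(P)
        fl = self.valve_flows(phase, states, P)
        return tuple(
            (f >= -FLOW_TOL) if s else (d > DP_TOL)
            for s, d, f in zip(states, dp, fl)
        )

    def resolve_states(self, phase: Phase, comp_p: np.ndarray, p_src: float,
                       guess: tuple[bool, ...] | None = None) -> tuple[bool, ...]:
        """Find a self-consistent conduction assignment for all check valves.

        Fixed-point iteration on the switching rule, with exhaustive
        enumeration over all 2^n assignments as a fallback.  The tolerance
        band in the rule makes degenerate assignments (valve at zero
        current) converge instead of chattering.
        """
        n = len(self.check_valves)
        if n == 0:
            return ()
        states = guess if guess is not None else tuple([phase is Phase.EXP] * n)
        for _ in range(4 * n + 8):
            new = self._switch(phase, states, comp_p, p_src)
            if new == states:
                return states
            states = new
        for combo in itertools.product((True, False), repeat=n):
            P = self.pressures(phase, comp_p, p_src, combo)
            dp = self.valve_drive(P)
            fl = self.valve_flows(phase, combo, P)
            ok = all((f >= -FLOW_TOL) if s else (d <= DP_TOL)
                     for s, d, f in zip(combo, dp, fl))
            if ok:
                return combo
        raise CircuitError(
            "no consistent valve conduction assignment found "
            f"(phase={phase.value}, states tried exhaustively)")


# ---------------------------------------------------------------------------
# Public instantaneous solve
# ---------------------------------------------------------------------------

@dataclass
class InstantSolution:
    """Result of a conduction-state-consistent nodal solve."""

    node_pressures: dict[str, float]
    branch_flows: dict[str, float]
    conduction: dict[str, bool]


def solve_instant(netlist: Netlist, compliance_pressures, phase: Phase,
                  p_source: float, conduction_guess: dict[str, bool] | None = None,
                  r_on: float = R_ON, r_leak: float = R_LEAK) -> InstantSolution:
    """Solve the network at one instant.

    ``compliance_pressures`` maps compliance component names to pressures
    (or is an ordered sequence matching ``netlist.state_vars``).
    ``p_source`` is the pressure applied by the source in this phase.
    """
    cn = CompiledNetwork(netlist, r_on=r_on, r_leak=r_leak)
    if isinstance(compliance_pressures, dict):
        comp_p = np.array([compliance_pressures[c.name] for c in cn.compliances])
    else:
        comp_p = np.asarray(compliance_pressures, dtype=float)
    if comp_p.shape != (len(cn.compliances),):
        raise ValueError("need one pressure per compliance state variable")
    guess = None
    if conduction_guess is not None:
        guess = tuple(bool(conduction_guess.get(v.name, False)) for v in cn.check_valves)
    states = cn.resolve_states(phase, comp_p, p_source, guess)
    P = cn.pressures(phase, comp_p, p_source, states)
    flows = cn.flows(phase, states, P)
    return InstantSolution(
        node_pressures={n: float(P[i]) for n, i in cn.node_index.items()},
        branch_flows={c.name: float(flows[i]) for i, c in enumerate(cn.elements)},
        conduction={v.name: s for v, s in zip(cn.check_valves, states)},
    )


# ---------------------------------------------------------------------------
# Time series container
# ---------------------------------------------------------------------------

@dataclass
class TimeSeries:
    """Simulated traces: source pressure, per-patient airway/alveolar
    pressure, flow and stored volume, plus valve conduction states.

    Stored volume is derived from the compliance pressure (Q = C * P_alv),
    which coincides with the running integral of patient flow for the
    all-zero initial state and avoids integration drift.
    """

    t: np.ndarray
    phase: np.ndarray            # Phase.value strings
    p_vent: np.ndarray           # source set pressure, cmH2O
    patients: tuple[str, ...]
    p_aw: np.ndarray             # (n_patients, n_t) airway pressure, cmH2O
    p_alv: np.ndarray            # (n_patients, n_t) alveolar pressure, cmH2O
    i_l: np.ndarray              # (n_patients, n_t) flow into patient, L/s
    q_l: np.ndarray              # (n_patients, n_t) stored volume, L
    valve_names: tuple[str, ...]
    valve_open: np.ndarray       # (n_valves, n_t) bool
    schedule: PhaseSchedule

    @property
    def n_patients(self) -> int:
        return len(self.patients)

    def patient_index(self, patient) -> int:
        if isinstance(patient, int):
            idx = patient - 1
            if not 0 <= idx < self.n_patients:
                raise KeyError(f"unknown patient {patient}")
            return idx
        try:
            return self.patients.index(patient)
        except ValueError:
            raise KeyError(f"unknown patient {patient!r}") from None

    def to_frame(self):
        import pandas as pd

        data = {"t_s": self.t, "phase": self.phase, "P_vent_cmH2O": self.p_vent}
        for i in range(self.n_patients):
            data[f"P_aw{i + 1}_cmH2O"] = self.p_aw[i]
        for i in range(self.n_patients):
            data[f"flow{i + 1}_L_s"] = self.i_l[i]
        for i in range(self.n_patients):
            data[f"vol{i + 1}_L"] = self.q_l[i]
        return pd.DataFrame(data)

    def write_csv(self, path: str | Path) -> None:
        """Write the trace, one row per accepted integrator step (edge
        instants included exactly)."""
        self.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Integration
# ---------------------------------------------------------------------------

def simulate(netlist: Netlist, settings: VentilatorSettings, n_cycles: int = 4,
             rtol: float = 1e-8, atol: float = 1e-12, y0=None,
             r_on: float = R_ON, r_leak: float = R_LEAK) -> TimeSeries:
    """Integrate the network over ``n_cycles`` breaths.

    State is the vector of compliance pressures, dP_c/dt = I_c / C with the
    charging current I_c from the instantaneous nodal solve.  Integration
    restarts exactly at every phase edge and at every check-valve
    conduction change (located by the solver's event detection on the
    valve driving pressure).  Initial state defaults to all zeros.
    """
    if n_cycles < 2:
        raise ValueError("n_cycles must be >= 2 (steady behaviour starts after the first breath)")
    sched = schedule(settings)
    cn = CompiledNetwork(netlist, r_on=r_on, r_leak=r_leak)
    n_comp = len(cn.compliances)
    y = np.zeros(n_comp) if y0 is None else np.asarray(y0, dtype=float).copy()
    if y.shape != (n_comp,):
        raise ValueError(f"y0 must have shape ({n_comp},)")

    chunks = []  # (t_array, y_matrix(n_comp, m), phase, states, p_src)
    states: tuple[bool, ...] | None = None
    for _, phase, t0, t1 in sched.segments(n_cycles):
        p_src = phase_pressure(settings, phase)
        t = t0
        restarts = 0
        while t < t1 - 1e-12:
            states = cn.resolve_states(phase, y, p_src, guess=states)

            def rhs(_t, yy, _phase=phase, _states=states, _p=p_src):
                P = cn.pressures(_phase, yy, _p, _states)
                fl = cn.flows(_phase, _states, P)
                return cn.compliance_currents(fl) / cn.c_values

            # events: a conducting valve blocks when flow crosses -FLOW_TOL,
            # a blocked valve opens when forward bias crosses +DP_TOL; the
            # offsets keep leak-level noise from retriggering
            events = []
            for k in range(len(cn.check_valves)):
                def ev(_t, yy, _k=k, _phase=phase, _states=states, _p=p_src):
                    P = cn.pressures(_phase, yy, _p, _states)
                    if _states[_k]:
                        return float(cn.valve_flows(_phase, _states, P)[_k]) + FLOW_TOL
                    return float(cn.valve_drive(P)[_k]) - DP_TOL
                ev.terminal = True
                ev.direction = -1.0 if states[k] else 1.0
                events.append(ev)

            sol = solve_ivp(rhs, (t, t1), y, method="RK45", rtol=rtol, atol=atol,
                            events=events or None, dense_output=False)
            if not sol.success and sol.status != 1:
                raise CircuitError(f"integration failed at t={t}: {sol.message}")
            chunks.append((sol.t, sol.y, phase, states, p_src))
            t_new = float(sol.t[-1])
            y = sol.y[:, -1].copy()
            if sol.status == 1:  # a valve switched; flip it and continue
                restarts += 1
                if restarts > _MAX_RESTARTS:
                    raise CircuitError(
                        f"step-size underflow: >{_MAX_RESTARTS} valve-event "
                        f"restarts within segment starting at t={t0:.6f}")
                flipped = list(states)
                for k, te in enumerate(sol.t_events):
                    if len(te):
                        flipped[k] = not flipped[k]
                states = tuple(flipped)
            t = t_new

    return _collect(cn, netlist, chunks, sched)


def _collect(cn: CompiledNetwork, netlist: Netlist, chunks, sched: PhaseSchedule) -> TimeSeries:
    probes = list(netlist.probes.values())
    aw_idx = [cn.node_index[p.airway] for p in probes]
    alv_idx = [cn.node_index[p.alveolar] for p in probes]
    ett_idx = [cn.el_index[p.ett] for p in probes]
    ett_sign = []
    for p in probes:
        comp = cn.elements[cn.el_index[p.ett]]
        ett_sign.append(1.0 if comp.node_a == p.wye else -1.0)
    c_l = np.array([p.c_l for p in probes])

    ts_t, ts_phase, ts_src = [], [], []
    aw, alv, il, ql, vstates = [], [], [], [], []
    prev_end: tuple[float, Phase] | None = None
    for t_arr, y_mat, phase, states, p_src in chunks:
        start = 0
        if prev_end is not None and len(t_arr) and t_arr[0] == prev_end[0] and phase is prev_end[1]:
            start = 1  # duplicate restart point within the same phase
        if start >= len(t_arr):
            prev_end = (float(t_arr[-1]), phase) if len(t_arr) else prev_end
            continue
        tseg = t_arr[start:]
        yseg = y_mat[:, start:]
        P = cn.pressures(phase, yseg, p_src, states)
        fl = cn.flows(phase, states, P)
        ts_t.append(tseg)
        ts_phase.append(np.full(len(tseg), phase.value, dtype=object))
        ts_src.append(np.full(len(tseg), p_src))
        aw.append(P[aw_idx])
        alv.append(P[alv_idx])
        il.append(np.array(ett_sign)[:, None] * fl[ett_idx])
        ql.append(c_l[:, None] * P[alv_idx])
        vstates.append(np.tile(np.array(states, dtype=bool)[:, None], (1, len(tseg)))
                       if states else np.zeros((0, len(tseg)), dtype=bool))
        prev_end = (float(t_arr[-1]), phase)

    return TimeSeries(
        t=np.concatenate(ts_t),
        phase=np.concatenate(ts_phase),
        p_vent=np.concatenate(ts_src),
        patients=tuple(p.name for p in probes),
        p_aw=np.hstack(aw),
        p_alv=np.hstack(alv),
        i_l=np.hstack(il),
        q_l=np.hstack(ql),
        valve_names=tuple(v.name for v in cn.check_valves),
        valve_open=np.hstack(vstates),
        schedule=sched,
    )
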