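"""Nodal solver and switched-network integration."""

import numpy as np
import pytest

from ventsplit.circuit import (GROUND, CircuitError, Component, Kind, Netlist,
                               simulate, solve_instant)
from ventsplit.metrics import cycle_summaries
from ventsplit.params import SplitterConfig, VentilatorSettings, lung_preset
from ventsplit.splitters import build_single, build_standard
from ventsplit.waveform import Phase


def _divider_netlist():
    return Netlist(components=[
        Component("src", Kind.SOURCE, "vent", GROUND),
        Component("r1", Kind.RESISTOR, "vent", "mid", 10.0),
        Component("r2", Kind.RESISTOR, "mid", GROUND, 10.0),
    ])


def test_voltage_divider_midpoint():
    sol = solve_instant(_divider_netlist(), [], Phase.INSP, p_source=10.0)
    assert sol.node_pressures["mid"] == pytest.approx(5.0, rel=1e-9)
    assert sol.branch_flows["r1"] == pytest.approx(0.5, rel=1e-6)


def test_check_valve_blocks_reverse_flow():
    net = Netlist(components=[
        Component("src", Kind.SOURCE, "vent", GROUND),
        # valve permits x -> vent only; the source drives vent -> x (reverse)
        Component("cv", Kind.CHECK_VALVE, "x", "vent"),
        Component("r", Kind.RESISTOR, "x", GROUND, 10.0),
    ])
    sol = solve_instant(net, [], Phase.INSP, p_source=10.0)
    assert not sol.conduction["cv"]
    assert abs(sol.branch_flows["cv"]) < 1e-6


def test_symmetric_standard_splitter_has_no_cross_flow():
    s = VentilatorSettings(pip=15)
    A = lung_preset("A")
    net = build_standard(s, A, A)
    # mid-inspiration with both lungs equally charged: symmetry forces equal
    # wye pressures, so no current crosses between the patients' arms
    sol = solve_instant(net, {"c_l1": 8.0, "c_l2": 8.0}, Phase.INSP, p_source=15.0)
    assert abs(sol.branch_flows["r_e1"]) < 1e-6
    assert sol.branch_flows["r_ett1"] == pytest.approx(sol.branch_flows["r_ett2"], rel=1e-9)


def test_floating_subnetwork_is_reported():
    net = Netlist(components=[
        Component("src", Kind.SOURCE, "vent", GROUND),
        Component("r1", Kind.RESISTOR, "vent", "mid", 10.0),
        Component("r2", Kind.RESISTOR, "mid", GROUND, 10.0),
        Component("r3", Kind.RESISTOR, "island_a", "island_b", 1.0),
    ])
    with pytest.raises(ValueError, match="not connected"):
        solve_instant(net, [], Phase.INSP, p_source=10.0)


def test_equilibrium_when_pip_equals_peep():
    s = VentilatorSettings(pip=5.0, peep=5.0)
    net = build_single(s, lung_preset("A"))
    ts = simulate(net, s, n_cycles=3)
    # alveolar pressure converges to the constant source; flows die out
    assert ts.p_alv[0, -1] == pytest.approx(5.0, abs=1e-3)
    assert abs(ts.i_l[0, -1]) < 1e-4
    vt = cycle_summaries(ts)[-1].tidal_volume_ml[0]
    assert vt < 0.05


def test_symmetric_pair_traces_identical():
    s = VentilatorSettings(pip=15)
    B = lung_preset("B")
    ts = simulate(build_standard(s, B, B), s, n_cycles=3)
    assert np.allclose(ts.q_l[0], ts.q_l[1], atol=1e-9)
    assert np.allclose(ts.p_aw[0], ts.p_aw[1], atol=1e-9)


def test_passivity_with_zero_source():
    s = VentilatorSettings(pip=0.0, peep=0.0)
    net = build_standard(s, lung_preset("A"), lung_preset("D"))
    ts = simulate(net, s, n_cycles=2, y0=[10.0, 6.0])
    total = ts.q_l.sum(axis=0)
    assert np.all(np.diff(total) <= 1e-9)
    assert total[-1] < total[0]


def test_n_cycles_validation():
    s = VentilatorSettings(pip=15)
    with pytest.raises(ValueError):
        simulate(build_single(s, lung_preset("A")), s, n_cycles=1)


def test_tightening_tolerance_does_not_move_tidal_volume():
    s = VentilatorSettings(pip=15)
    net = build_single(s, lung_preset("A"))
    vt = {}
    for rtol in (1e-6, 1e-8):
        ts = simulate(net, s, n_cycles=3, rtol=rtol)
        vt[rtol] = cycle_summaries(ts)[-1].tidal_volume_ml[0]
    assert abs(vt[1e-6] - vt[1e-8]) < 0.1


def test_stored_volume_consistent_with_compliance_pressure():
    s = VentilatorSettings(pip=15)
    net = build_single(s, lung_preset("C"))
    ts = simulate(net, s, n_cycles=2)
    c_l = lung_preset("C").c_l
    assert np.allclose(ts.q_l[0], c_l * ts.p_alv[0], atol=1e-12)


def test_netlist_dump_lists_components():
    net = build_single(VentilatorSettings(pip=15), lung_preset("A"))
    text = net.dump()
    for name in ("vent_src", "v_insp", "r_ett1", "c_l1"):
        assert name in text
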