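"""Topology builders: single patient, standard and modified splitters."""

import numpy as np
import pytest

from ventsplit.circuit import Component, Kind, simulate, solve_instant
from ventsplit.metrics import steady_state_summary
from ventsplit.oracle import branch_for_patient, steady_state_vt
from ventsplit.params import LungModel, SplitterConfig, VentilatorSettings, lung_preset
from ventsplit.splitters import build, build_modified, build_single, build_standard
from ventsplit.waveform import Phase

S15 = VentilatorSettings(pip=15)


def test_single_patient_matches_closed_form():
    lung = lung_preset("A")
    summary = steady_state_summary(build_single(S15, lung), S15)
    vt_oracle = steady_state_vt(branch_for_patient(lung, SplitterConfig()), S15)
    assert summary.tidal_volume_ml[0] == pytest.approx(vt_oracle, abs=0.5)
    assert summary.tidal_volume_ml[0] == pytest.approx(490, abs=2)


def test_vanishing_compliance_gives_vanishing_tidal_volume():
    stiff = LungModel(c_l=1e-5)
    summary = steady_state_summary(build_single(S15, stiff), S15)
    assert summary.tidal_volume_ml[0] < 0.2


def test_fast_time_constant_limit_is_compliance_times_delta_p():
    # halve dP, double C: VT stays ~C*dP when time constants << phase times
    lung = LungModel(c_l=0.02, r_l=0.5, r_ett=0.5)
    big = LungModel(c_l=0.04, r_l=0.5, r_ett=0.5)
    vt_small = steady_state_summary(build_single(S15, lung), S15).tidal_volume_ml[0]
    s_half = VentilatorSettings(pip=10)
    vt_big = steady_state_summary(build_single(s_half, big), s_half).tidal_volume_ml[0]
    assert vt_big == pytest.approx(vt_small, rel=0.02)


def test_modified_with_zero_restrictors_recovers_standard():
    A, D = lung_preset("A"), lung_preset("D")
    std = steady_state_summary(build_standard(S15, A, D), S15)
    mod = steady_state_summary(
        build_modified(S15, A, D, SplitterConfig(topology="modified")), S15)
    for v_std, v_mod in zip(std.tidal_volume_ml, mod.tidal_volume_ml):
        assert v_mod == pytest.approx(v_std, abs=0.5)


def test_modified_equals_standard_when_valves_shorted():
    # replacing the check valves by wires must reproduce the standard
    # splitter exactly (to within the valves' on-resistance)
    A, D = lung_preset("A"), lung_preset("D")
    net = build_modified(S15, A, D, SplitterConfig(topology="modified"))
    shorted = [Component(c.name, Kind.RESISTOR, c.node_a, c.node_b, 0.0)
               if c.kind is Kind.CHECK_VALVE else c for c in net.components]
    net.components = shorted
    mod = steady_state_summary(net, S15)
    std = steady_state_summary(build_standard(S15, A, D), S15)
    for v_std, v_mod in zip(std.tidal_volume_ml, mod.tidal_volume_ml):
        assert v_mod == pytest.approx(v_std, abs=0.1)


def test_expiration_arms_carry_no_flow_during_inspiration():
    A, D = lung_preset("A"), lung_preset("D")
    net = build_modified(S15, A, D, SplitterConfig(topology="modified"))
    # mid-inspiration state: both valves reverse-biased or at zero current
    sol = solve_instant(net, {"c_l1": 9.0, "c_l2": 10.0}, Phase.INSP, p_source=15.0)
    assert abs(sol.branch_flows["cv1"]) < 1e-6
    assert abs(sol.branch_flows["cv2"]) < 1e-6


def test_raising_own_restrictor_strictly_reduces_tidal_volume():
    A, C = lung_preset("A"), lung_preset("C")
    vts = []
    for r_v2 in (0.0, 5.0, 15.0, 30.0):
        spl = SplitterConfig(topology="modified", r_v2=r_v2)
        summ = steady_state_summary(build_modified(S15, A, C, spl), S15)
        vts.append(summ.tidal_volume_ml[1])
    assert all(a > b for a, b in zip(vts, vts[1:]))


def test_no_net_cross_flow_between_patients_over_a_cycle():
    # modified splitter: valves isolate the patients, so each patient's
    # stored volume returns to its cycle-start value (no steady transfer)
    A, D = lung_preset("A"), lung_preset("D")
    net = build_modified(S15, A, D, SplitterConfig(topology="modified"))
    ts = simulate(net, S15, n_cycles=4)
    period = ts.schedule.period
    i0 = np.searchsorted(ts.t, 3 * period)
    for p in range(2):
        assert abs(ts.q_l[p, -1] - ts.q_l[p, i0]) * 1000 < 0.05


def test_build_dispatch():
    A = lung_preset("A")
    assert build(S15, SplitterConfig(topology="single"), [A]).label == "single"
    assert build(S15, SplitterConfig(topology="standard"), [A, A]).label == "standard"
    assert build(S15, SplitterConfig(topology="modified"), [A, A]).label == "modified"
    with pytest.raises(ValueError):
        build(S15, SplitterConfig(topology="standard"), [A, A, A])
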