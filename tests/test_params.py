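"""Unit conversions, parameter presets and configuration parsing."""

import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from ventsplit.params import (REFERENCE_COMPLIANCE, LungModel, SplitterConfig,
                              VentilatorSettings, cmh2o_to_pa,
                              compliance_clinical_to_si, load_config, lung_preset,
                              pa_to_cmh2o, poiseuille_resistance,
                              resistance_clinical_to_si, resistance_si_to_clinical,
                              si_registry)


@pytest.mark.parametrize("cmh2o, pa", [(15, 1471), (5, 490), (0, 0)])
def test_pressure_conversion_matches_published_values(cmh2o, pa):
    assert round(cmh2o_to_pa(cmh2o)) == pa


@pytest.mark.parametrize("clin, si", [(2, 196133), (0, 0), (8, 784532)])
def test_resistance_conversion(clin, si):
    assert resistance_clinical_to_si(clin) == pytest.approx(si, rel=1e-3)


def test_negative_resistance_rejected():
    with pytest.raises(ValueError):
        resistance_clinical_to_si(-1.0)


@given(st.floats(min_value=1e-6, max_value=1e6))
def test_conversion_round_trips(x):
    assert pa_to_cmh2o(cmh2o_to_pa(x)) == pytest.approx(x, rel=1e-12)
    assert resistance_si_to_clinical(resistance_clinical_to_si(x)) == pytest.approx(x, rel=1e-12)


def test_poiseuille_for_standard_ventilator_tubing():
    # 22 mm diameter, air at 18.13e-6 Pa.s, 1.8 m length
    r = poiseuille_resistance(0.022, 18.13e-6, 1.8)
    assert r == pytest.approx(5676, rel=1e-3)
    # linear in length, inverse fourth power in diameter
    assert poiseuille_resistance(0.022, 18.13e-6, 3.6) == pytest.approx(2 * r)
    assert poiseuille_resistance(0.011, 18.13e-6, 1.8) == pytest.approx(16 * r)
    with pytest.raises(ValueError):
        poiseuille_resistance(0.0, 18.13e-6, 1.8)


@pytest.mark.parametrize("label, reduction", [("A", 0.0), ("B", 0.2), ("C", 0.3), ("D", 0.4)])
def test_lung_presets_scale_reference_compliance(label, reduction):
    lung = lung_preset(label)
    assert lung.c_l == pytest.approx(REFERENCE_COMPLIANCE * (1 - reduction))
    assert lung.r_l == 2.0
    assert lung.r_ett == 8.0


def test_unknown_preset_rejected():
    with pytest.raises(ValueError):
        lung_preset("E")


def test_si_registry_rounded_vs_exact():
    exact = si_registry()
    rounded = si_registry(rounded=True)
    assert rounded["r_ett"] == 784000.0
    assert exact["r_ett"] == pytest.approx(784532, abs=1)
    for key in ("peep", "pip", "r_l", "r_ett"):
        assert exact[key] == pytest.approx(rounded[key], rel=1e-3)
    # printed with only two significant digits
    assert exact["c_l"] == pytest.approx(rounded["c_l"], rel=2e-3)
    # the tubing rows are rounded independently in each unit system: the
    # S.I. figure is the raw Poiseuille value, the clinical one its 2-digit
    # rounding, so they agree only to ~4%
    assert resistance_si_to_clinical(rounded["r_i"]) == pytest.approx(0.06, abs=0.005)
    assert rounded["r_i"] == pytest.approx(poiseuille_resistance(0.022, 18.13e-6, 1.8), rel=2e-3)
    assert exact["c_l"] == pytest.approx(compliance_clinical_to_si(0.054))


def test_ventilator_settings_invariants():
    with pytest.raises(ValueError):
        VentilatorSettings(pip=4.0, peep=5.0)
    with pytest.raises(ValueError):
        VentilatorSettings(pip=15.0, peep=-1.0)
    with pytest.raises(ValueError):
        VentilatorSettings(pip=15.0, rr=0.0)
    with pytest.raises(ValueError):
        VentilatorSettings(pip=15.0, ie_ratio=(1.0, 0.0))
    # equal pressures are the valid constant-pressure degenerate case
    assert VentilatorSettings(pip=5.0, peep=5.0).delta_p == 0.0


def test_lung_and_splitter_invariants():
    with pytest.raises(ValueError):
        LungModel(c_l=0.0)
    with pytest.raises(ValueError):
        LungModel(c_l=0.05, r_l=-1.0)
    with pytest.raises(ValueError):
        SplitterConfig(topology="tee")
    with pytest.raises(ValueError):
        SplitterConfig(r_v1=-0.1)


def test_load_config_yaml_and_json(tmp_path):
    yaml_text = """
ventilator: {pip: 17, peep: 5, rr: 15, ie: [1, 2]}
splitter: {topology: modified, r_v1: 7}
patients: [A, {preset: B}]
"""
    p = tmp_path / "cfg.yaml"
    p.write_text(yaml_text)
    cfg = load_config(p)
    assert cfg.ventilator.pip == 17
    assert cfg.splitter.topology == "modified"
    assert cfg.splitter.r_v1 == 7
    assert [l.label for l in cfg.patients] == ["A", "B"]

    j = tmp_path / "cfg.json"
    j.write_text('{"ventilator": {"pip": 15}, "patients": [{"c_l": 0.04}]}')
    cfg = load_config(j)
    assert cfg.patients[0].c_l == 0.04
    assert cfg.splitter.topology == "standard"
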