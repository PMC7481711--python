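"""Circuit topologies: single patient, standard T-splitter, modified splitter.

All three share the same ventilator porting: the square-wave source feeds
an inspiratory port through a phase valve that conducts during
inspiration, and receives an expiratory port through a phase valve that
conducts during expiration.  A patient branch is R_ETT then R_L in series
from the splitter wye to the alveolar compliance; the airway-pressure
probe sits at the R_ETT/R_L junction (the patient end of the tracheal
tube).

The modified splitter adds an adjustable resistor R_V in series with each
inspiration arm and a one-way valve in each expiration arm oriented to
permit patient-to-ventilator flow only, so the expiration arms cannot act
as a short circuit between the two inspiration arms during inspiration.
"""

from __future__ import annotations

from .circuit import GROUND, Component, Kind, Netlist, PatientProbe
from .params import LungModel, SplitterConfig, VentilatorSettings
from .waveform import Phase


def _ventilator(components: list[Component]) -> None:
    components += [
        Component("vent_src", Kind.SOURCE, "vent", GROUND),
        Component("v_insp", Kind.PHASE_VALVE, "vent", "insp", gate=Phase.INSP),
        Component("v_exp", Kind.PHASE_VALVE, "exp", "vent", gate=Phase.EXP),
    ]


def _patient(idx: int, lung: LungModel) -> tuple[list[Component], PatientProbe]:
    wye, aw, alv = f"wye{idx}", f"aw{idx}", f"alv{idx}"
    comps = [
        Component(f"r_ett{idx}", Kind.RESISTOR, wye, aw, lung.r_ett),
        Component(f"r_l{idx}", Kind.RESISTOR, aw, alv, lung.r_l),
        Component(f"c_l{idx}", Kind.COMPLIANCE, alv, GROUND, lung.c_l),
    ]
    probe = PatientProbe(name=f"patient{idx}", wye=wye, airway=aw, alveolar=alv,
                         compliance=f"c_l{idx}", ett=f"r_ett{idx}", c_l=lung.c_l)
    return comps, probe


def build_single(settings: VentilatorSettings, lung: LungModel,
                 splitter: SplitterConfig | None = None) -> Netlist:
    """One patient directly on the ventilator (validation reduction)."""
    spl = splitter or SplitterConfig(topology="single")
    comps: list[Component] = []
    _ventilator(comps)
    comps.append(Component("r_i1", Kind.RESISTOR, "insp", "wye1", spl.r_i))
    comps.append(Component("r_e1", Kind.RESISTOR, "wye1", "exp", spl.r_e))
    branch, probe = _patient(1, lung)
    comps += branch
    return Netlist(components=comps, probes={probe.name: probe}, label="single")


def build_standard(settings: VentilatorSettings, lung1: LungModel, lung2: LungModel,
                   splitter: SplitterConfig | None = None) -> Netlist:
    """Two patients through plain T-junctions; no valves, no restrictors."""
    spl = splitter or SplitterConfig(topology="standard")
    comps: list[Component] = []
    _ventilator(comps)
    probes = {}
    for idx, lung in ((1, lung1), (2, lung2)):
        comps.append(Component(f"r_i{idx}", Kind.RESISTOR, "insp", f"wye{idx}", spl.r_i))
        comps.append(Component(f"r_e{idx}", Kind.RESISTOR, f"wye{idx}", "exp", spl.r_e))
        branch, probe = _patient(idx, lung)
        comps += branch
        probes[probe.name] = probe
    return Netlist(components=comps, probes=probes, label="standard")


def build_modified(settings: VentilatorSettings, lung1: LungModel, lung2: LungModel,
                   splitter: SplitterConfig | None = None) -> Netlist:
    """Standard splitter plus per-arm inspiratory restrictors R_V1/R_V2 and
    expiratory check valves permitting patient -> ventilator flow only.

    With both R_V at zero this reduces (to within the valves' on-resistance)
    to the standard splitter during expiration while isolating the two
    inspiration arms from each other during inspiration.
    """
    spl = splitter or SplitterConfig(topology="modified")
    comps: list[Component] = []
    _ventilator(comps)
    probes = {}
    for idx, lung, r_v in ((1, lung1, spl.r_v1), (2, lung2, spl.r_v2)):
        comps.append(Component(f"r_v{idx}", Kind.RESISTOR, "insp", f"m{idx}", r_v))
        comps.append(Component(f"r_i{idx}", Kind.RESISTOR, f"m{idx}", f"wye{idx}", spl.r_i))
        comps.append(Component(f"r_e{idx}", Kind.RESISTOR, f"wye{idx}", f"e{idx}", spl.r_e))
        comps.append(Component(f"cv{idx}", Kind.CHECK_VALVE, f"e{idx}", "exp"))
        branch, probe = _patient(idx, lung)
        comps += branch
        probes[probe.name] = probe
    return Netlist(components=comps, probes=probes, label="modified")


def build(settings: VentilatorSettings, splitter: SplitterConfig,
          lungs: list[LungModel]) -> Netlist:
    """Dispatch on splitter topology / number of patients."""
    if splitter.topology == "single" or len(lungs) == 1:
        return build_single(settings, lungs[0], splitter)
    if len(lungs) != 2:
        raise ValueError("two-patient topologies need exactly two lung models")
    if splitter.topology == "standard":
        return build_standard(settings, lungs[0], lungs[1], splitter)
    return build_modified(settings, lungs[0], lungs[1], splitter)
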