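"""Scripted reproduction of the four split-ventilation experiments.

Each ``run_*`` function simulates a family of configurations at published
reference operating points (PIP and restrictor settings that calibrate the
system to ~490 ml tidal volume) and returns a tidy DataFrame with, per
patient, the simulated steady tidal volume, the closed-form RC prediction
and their residual.  Where the experiment involves a calibration
procedure, the table also reports the settings re-derived from scratch by
the tuning module.

The four experiments:

* validation — matched pairs A-A .. D-D on the standard splitter, PIP
  raised per pair to restore ~490 ml.
* standard_mismatch — mismatched pairs on the standard splitter with PIP
  set for patient 1 only; quantifies patient 2's tidal-volume shortfall.
* modified_equalize — mismatched pairs on the modified splitter with
  per-pair (PIP, R_V1) equalizing both patients near 490 ml.
* independent_adjust — a matched moderate-ARDS pair (C-C) on the modified
  splitter, patient 2 driven 30% below or above baseline while patient 1
  is held.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import pandas as pd

from .metrics import steady_state_summary
from .params import DEFAULT_SETTINGS, SplitterConfig, VentilatorSettings, lung_preset
from .oracle import branch_for_patient, steady_state_vt
from .splitters import build
from .tuning import adjust_patient2, tune_modified, tune_pip

#: Matched pairs with the PIP that restores ~490 ml on the standard splitter.
VALIDATION_CASES = [
    ("A", "A", 15.0),
    ("B", "B", 17.0),
    ("C", "C", 18.5),
    ("D", "D", 20.5),
]

#: Pairs ventilated at the PIP calibrated for patient 1 alone.
MISMATCH_CASES = [
    ("A", "A", 15.0),
    ("A", "B", 15.0),
    ("A", "C", 15.0),
    ("A", "D", 15.0),
    ("B", "C", 17.0),
    ("B", "D", 17.0),
    ("C", "D", 18.5),
]

#: Modified splitter: per-pair (PIP, R_V1) equalizing both patients.
EQUALIZE_CASES = [
    ("A", "A", 15.0, 0.0),
    ("A", "B", 17.0, 7.0),
    ("A", "C", 18.33, 11.67),
    ("A", "D", 20.33, 18.0),
    ("B", "C", 18.5, 6.67),
    ("B", "D", 20.3, 11.94),
    ("C", "D", 20.3, 8.67),
]

#: Modified splitter C-C rows: (label, r_v1, r_v2, pip).
INDEPENDENT_CASES = [
    ("C-C", 0.0, 0.0, 18.5),
    ("C-C(-)", 0.0, 16.67, 18.5),
    ("C-C(+)", 16.67, 0.0, 22.67),
]


@dataclass(frozen=True)
class ExperimentSpec:
    """Selects one of the four experiments, optionally restricted to a
    subset of lung-label pairs, with ventilator-setting overrides."""

    name: str
    pairs: list[tuple[str, str]] | None = None
    settings: VentilatorSettings = DEFAULT_SETTINGS
    overrides: dict = field(default_factory=dict)

    _NAMES = ("validation", "standard_mismatch", "modified_equalize", "independent_adjust")

    def __post_init__(self) -> None:
        if self.name not in self._NAMES:
            raise ValueError(f"unknown experiment {self.name!r}; expected one of {self._NAMES}")

    def run(self) -> pd.DataFrame:
        fn = {
            "validation": run_validation,
            "standard_mismatch": run_standard_mismatch,
            "modified_equalize": run_modified_equalize,
            "independent_adjust": run_independent_adjust,
        }[self.name]
        return fn(settings=self.settings, **self.overrides)


def _row(pair_label: str, topology: str, settings: VentilatorSettings,
         splitter: SplitterConfig, lungs) -> dict:
    net = build(settings, splitter, lungs)
    summary = steady_state_summary(net, settings)
    row = {
        "pair": pair_label,
        "topology": topology,
        "pip_cmH2O": settings.pip,
        "rv1": splitter.r_v1 if topology == "modified" else 0.0,
        "rv2": splitter.r_v2 if topology == "modified" else 0.0,
        "vt1_ml": summary.tidal_volume_ml[0],
        "vt2_ml": summary.tidal_volume_ml[-1],
        "peep1": summary.achieved_peep[0],
        "peep2": summary.achieved_peep[-1],
        "steady_cycle": summary.cycle_index,
    }
    for i, lung in enumerate(lungs, start=1):
        vt_oracle = steady_state_vt(branch_for_patient(lung, splitter, which=i), settings)
        row[f"vt{i}_oracle_ml"] = vt_oracle
        row[f"resid{i}_ml"] = row[f"vt{i}_ml"] - vt_oracle
    return row


def run_validation(settings: VentilatorSettings = DEFAULT_SETTINGS,
                   tune: bool = True) -> pd.DataFrame:
    """Matched pairs on the standard splitter at their calibrated PIPs.

    With ``tune=True`` each row also reports the PIP re-derived by
    bisection from a 490 ml target, and the tidal volume it achieves.
    """
    rows = []
    for l1, l2, pip in VALIDATION_CASES:
        s = replace(settings, pip=pip)
        spl = SplitterConfig(topology="standard")
        row = _row(f"{l1}-{l2}", "standard", s, spl, [lung_preset(l1), lung_preset(l2)])
        if tune:
            res = tune_pip((l1, l2), topology="standard", settings=settings)
            row["pip_recovered"] = res.pip
            row["vt1_recovered_ml"] = res.vt1
        rows.append(row)
    return pd.DataFrame(rows)


def run_standard_mismatch(settings: VentilatorSettings = DEFAULT_SETTINGS) -> pd.DataFrame:
    """Mismatched pairs on the standard splitter; PIP set for patient 1.

    Adds patient 2's shortfall relative to patient 1 in ml and percent.
    """
    rows = []
    for l1, l2, pip in MISMATCH_CASES:
        s = replace(settings, pip=pip)
        spl = SplitterConfig(topology="standard")
        row = _row(f"{l1}-{l2}", "standard", s, spl, [lung_preset(l1), lung_preset(l2)])
        row["shortfall_ml"] = row["vt1_ml"] - row["vt2_ml"]
        row["shortfall_pct"] = 100.0 * row["shortfall_ml"] / row["vt1_ml"]
        rows.append(row)
    return pd.DataFrame(rows)


def run_modified_equalize(settings: VentilatorSettings = DEFAULT_SETTINGS,
                          tune: bool = True) -> pd.DataFrame:
    """Mismatched pairs on the modified splitter at the published
    (PIP, R_V1) calibration points; optionally re-derives the calibration
    from scratch with :func:`ventsplit.tuning.tune_modified`."""
    rows = []
    for l1, l2, pip, r_v1 in EQUALIZE_CASES:
        s = replace(settings, pip=pip)
        spl = SplitterConfig(topology="modified", r_v1=r_v1, r_v2=0.0)
        row = _row(f"{l1}-{l2}", "modified", s, spl, [lung_preset(l1), lung_preset(l2)])
        if tune and l1 != l2:
            res = tune_modified((l1, l2), settings=settings)
            row.update(pip_tuned=res.pip, rv1_tuned=res.r_v1,
                       vt1_tuned_ml=res.vt1, vt2_tuned_ml=res.vt2,
                       tuned_converged=res.converged)
        rows.append(row)
    return pd.DataFrame(rows)


def run_independent_adjust(settings: VentilatorSettings = DEFAULT_SETTINGS,
                           tune: bool = True) -> pd.DataFrame:
    """C-C pair on the modified splitter: baseline, -30% and +30% rows at
    the published settings; optionally re-derives each adjustment with
    :func:`ventsplit.tuning.adjust_patient2`."""
    rows = []
    lungs = [lung_preset("C"), lung_preset("C")]
    baseline_pip = INDEPENDENT_CASES[0][3]
    for label, r_v1, r_v2, pip in INDEPENDENT_CASES:
        s = replace(settings, pip=pip)
        spl = SplitterConfig(topology="modified", r_v1=r_v1, r_v2=r_v2)
        row = _row(label, "modified", s, spl, lungs)
        if tune and label != "C-C":
            delta = -0.30 if "(-)" in label else 0.30
            res = adjust_patient2(("C", "C"), delta, pip=baseline_pip, settings=settings)
            row.update(delta_target=delta, pip_tuned=res.pip,
                       rv1_tuned=res.r_v1, rv2_tuned=res.r_v2,
                       vt1_tuned_ml=res.vt1, vt2_tuned_ml=res.vt2,
                       tuned_converged=res.converged)
        rows.append(row)
    return pd.DataFrame(rows)
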