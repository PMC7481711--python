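"""Parameter registry, unit conversions and lung presets.

All internal computation uses the units clinicians read off the ventilator:
pressure in cmH2O, volume in litres, time in seconds.  Resistance is then
cmH2O/L/s and compliance L/cmH2O.  Because the network model is linear,
units only rescale the solution, so the S.I. conversions here are an I/O
convenience rather than something the solver needs.

The conversion constant is fixed at 1 cmH2O = 98.0665 Pa (standard
gravity), which reproduces every published clinical-to-S.I. conversion of
the reference parameter set to better than 0.1%.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import yaml

#: Pa per cmH2O at standard gravity.
CMH2O_TO_PA = 98.0665

#: m^3 per litre.
LITRE_TO_M3 = 1e-3

#: Reference (healthy) respiratory-system compliance, L/cmH2O.
REFERENCE_COMPLIANCE = 0.054

#: Fractional compliance reduction of each lung preset relative to healthy.
#: A is healthy; B, C, D represent mild, moderate and severe ARDS.
COMPLIANCE_REDUCTION = {"A": 0.0, "B": 0.2, "C": 0.3, "D": 0.4}

#: Default small-airway resistance, cmH2O/L/s.
DEFAULT_R_L = 2.0

#: Default endotracheal-tube resistance, cmH2O/L/s.
DEFAULT_R_ETT = 8.0

#: Default tubing resistance per splitter arm, cmH2O/L/s (Poiseuille
#: estimate for 1.8 m of 22 mm tubing, see :func:`poiseuille_resistance`).
DEFAULT_R_TUBE = 0.06


# ---------------------------------------------------------------------------
# Unit conversions
# ---------------------------------------------------------------------------

def cmh2o_to_pa(p: float) -> float:
    """Convert a pressure from cmH2O to Pa."""
    return p * CMH2O_TO_PA


def pa_to_cmh2o(p: float) -> float:
    """Convert a pressure from Pa to cmH2O (inverse of :func:`cmh2o_to_pa`)."""
    return p / CMH2O_TO_PA


def resistance_clinical_to_si(r: float) -> float:
    """Convert a pneumatic resistance from cmH2O/L/s to Pa·s/m^3.

    Parameters
    ----------
    r : float
        Resistance in clinical units; must be non-negative.
    """
    if r < 0:
        raise ValueError(f"resistance must be non-negative, got {r}")
    return r * CMH2O_TO_PA / LITRE_TO_M3


def resistance_si_to_clinical(r: float) -> float:
    """Convert a pneumatic resistance from Pa·s/m^3 to cmH2O/L/s."""
    if r < 0:
        raise ValueError(f"resistance must be non-negative, got {r}")
    return r * LITRE_TO_M3 / CMH2O_TO_PA


def compliance_clinical_to_si(c: float) -> float:
    """Convert a compliance from L/cmH2O to m^3/Pa."""
    if c < 0:
        raise ValueError(f"compliance must be non-negative, got {c}")
    return c * LITRE_TO_M3 / CMH2O_TO_PA


def compliance_si_to_clinical(c: float) -> float:
    """Convert a compliance from m^3/Pa to L/cmH2O."""
    if c < 0:
        raise ValueError(f"compliance must be non-negative, got {c}")
    return c * CMH2O_TO_PA / LITRE_TO_M3


def poiseuille_resistance(diameter: float, viscosity: float, length: float) -> float:
    """Laminar (Poiseuille) resistance of a straight circular tube.

    R = 128 * mu * L / (pi * D^4), everything in S.I. units (result in
    Pa·s/m^3).  For standard 22 mm ventilator tubing of length 1.8 m with
    air viscosity 18.13e-6 Pa·s this gives ~5.7e3 Pa·s/m^3, i.e. about
    0.06 cmH2O/L/s per arm.

    All three arguments must be strictly positive.
    """
    for name, v in (("diameter", diameter), ("viscosity", viscosity), ("length", length)):
        if not v > 0:
            raise ValueError(f"{name} must be positive, got {v}")
    return 128.0 * viscosity * length / (math.pi * diameter ** 4)


# ---------------------------------------------------------------------------
# S.I. registry
# ---------------------------------------------------------------------------

#: Rounded S.I. values as commonly tabulated for this parameter set.  The
#: exact conversions differ slightly (e.g. 8 cmH2O/L/s is 784532 Pa·s/m^3,
#: often rounded to 784000); the difference changes tidal volumes by well
#: under 0.1 ml.
_SI_ROUNDED = {
    "peep": 490.0,
    "pip": 1471.0,
    "r_i": 5670.0,
    "r_e": 5670.0,
    "r_l": 196133.0,
    "c_l": 5.5e-7,
    "r_ett": 784000.0,
}

_CLINICAL = {
    "peep": 5.0,
    "pip": 15.0,
    "r_i": DEFAULT_R_TUBE,
    "r_e": DEFAULT_R_TUBE,
    "r_l": DEFAULT_R_L,
    "c_l": REFERENCE_COMPLIANCE,
    "r_ett": DEFAULT_R_ETT,
}


def si_registry(rounded: bool = False) -> dict[str, float]:
    """Reference parameter set in S.I. units.

    With ``rounded=False`` (default) every value is the exact conversion of
    the clinical value; with ``rounded=True`` the conventional rounded
    figures are substituted verbatim, for byte-level comparison studies.
    """
    if rounded:
        return dict(_SI_ROUNDED)
    out = {}
    for key, val in _CLINICAL.items():
        if key in ("peep", "pip"):
            out[key] = cmh2o_to_pa(val)
        elif key == "c_l":
            out[key] = compliance_clinical_to_si(val)
        else:
            out[key] = resistance_clinical_to_si(val)
    return out


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VentilatorSettings:
    """Pressure-control ventilator settings defining the square-wave source.

    Attributes
    ----------
    pip : float
        Peak inspiratory pressure, cmH2O; the plateau applied during
        inspiration.
    peep : float
        Positive end-expiratory pressure, cmH2O; the baseline held during
        expiration.
    rr : float
        Respiratory rate, breaths per minute.
    ie_ratio : tuple of float
        Inspiration:expiration time parts, e.g. ``(1, 2)``.
    """

    pip: float
    peep: float = 5.0
    rr: float = 15.0
    ie_ratio: tuple[float, float] = (1.0, 2.0)

    def __post_init__(self) -> None:
        if not self.peep >= 0:
            raise ValueError(f"PEEP must be >= 0, got {self.peep}")
        if not self.pip >= self.peep:
            raise ValueError(f"PIP ({self.pip}) must be >= PEEP ({self.peep})")
        if not self.rr > 0:
            raise ValueError(f"RR must be positive, got {self.rr}")
        i, e = self.ie_ratio
        if not (i > 0 and e > 0):
            raise ValueError(f"both I:E parts must be positive, got {self.ie_ratio}")

    @property
    def delta_p(self) -> float:
        """Driving pressure PIP - PEEP, cmH2O."""
        return self.pip - self.peep


@dataclass(frozen=True)
class LungModel:
    """One patient's single-compartment respiratory mechanics.

    ``c_l`` is the lung + chest-wall compliance (L/cmH2O), ``r_l`` the
    airway resistance and ``r_ett`` the endotracheal-tube resistance
    (cmH2O/L/s).  ARDS severity is represented purely as reduced
    compliance.
    """

    c_l: float
    r_l: float = DEFAULT_R_L
    r_ett: float = DEFAULT_R_ETT
    label: str = "custom"

    def __post_init__(self) -> None:
        if not self.c_l > 0:
            raise ValueError(f"compliance must be positive, got {self.c_l}")
        if self.r_l < 0 or self.r_ett < 0:
            raise ValueError("resistances must be non-negative")


@dataclass(frozen=True)
class SplitterConfig:
    """Splitter topology and tubing resistances (cmH2O/L/s).

    ``r_v1``/``r_v2`` are the adjustable inspiratory flow restrictors and
    only take effect for the ``modified`` topology, which also places a
    one-way valve in each expiration arm.
    """

    topology: str = "standard"
    r_i: float = DEFAULT_R_TUBE
    r_e: float = DEFAULT_R_TUBE
    r_v1: float = 0.0
    r_v2: float = 0.0

    def __post_init__(self) -> None:
        if self.topology not in ("single", "standard", "modified"):
            raise ValueError(f"unknown topology {self.topology!r}")
        for name in ("r_i", "r_e", "r_v1", "r_v2"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def lung_preset(label: str) -> LungModel:
    """Return lung preset A, B, C or D.

    A is the healthy reference (compliance 0.054 L/cmH2O); B, C and D
    reduce compliance by 20, 30 and 40% to represent mild, moderate and
    severe ARDS.  Airway and tube resistances are identical across presets.
    """
    if label not in COMPLIANCE_REDUCTION:
        raise ValueError(f"unknown lung preset {label!r}; expected one of A, B, C, D")
    c = REFERENCE_COMPLIANCE * (1.0 - COMPLIANCE_REDUCTION[label])
    return LungModel(c_l=c, r_l=DEFAULT_R_L, r_ett=DEFAULT_R_ETT, label=label)


def as_lung(value: LungModel | str) -> LungModel:
    """Coerce a preset label or LungModel to a LungModel."""
    if isinstance(value, LungModel):
        return value
    return lung_preset(value)


#: Reference ventilator settings: PIP 15 / PEEP 5 cmH2O, RR 15, I:E 1:2.
DEFAULT_SETTINGS = VentilatorSettings(pip=15.0, peep=5.0, rr=15.0, ie_ratio=(1.0, 2.0))


# ---------------------------------------------------------------------------
# Configuration files
# ---------------------------------------------------------------------------

@dataclass
class SimulationConfig:
    """A fully specified simulation: ventilator, splitter and patients."""

    ventilator: VentilatorSettings
    splitter: SplitterConfig
    patients: list[LungModel] = field(default_factory=list)


def _parse_patient(entry) -> LungModel:
    if isinstance(entry, str):
        return lung_preset(entry)
    if isinstance(entry, dict):
        if "preset" in entry:
            return lung_preset(entry["preset"])
        return LungModel(
            c_l=float(entry["c_l"]),
            r_l=float(entry.get("r_l", DEFAULT_R_L)),
            r_ett=float(entry.get("r_ett", DEFAULT_R_ETT)),
            label=str(entry.get("label", "custom")),
        )
    raise ValueError(f"cannot interpret patient entry {entry!r}")


def load_config(source: str | Path | dict) -> SimulationConfig:
    """Load a simulation configuration from YAML/JSON or a dict.

    Schema (all values in clinical units)::

        ventilator: {pip, peep, rr, ie: [i, e]}
        splitter:   {topology, r_i, r_e, r_v1, r_v2}
        patients:   [A, {preset: D}, {c_l: 0.04, r_l: 2, r_ett: 8}, ...]
    """
    if isinstance(source, dict):
        raw = source
    else:
        path = Path(source)
        text = path.read_text()
        raw = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)

    vent = raw.get("ventilator", {})
    ie = tuple(vent.get("ie", (1.0, 2.0)))
    settings = VentilatorSettings(
        pip=float(vent.get("pip", DEFAULT_SETTINGS.pip)),
        peep=float(vent.get("peep", DEFAULT_SETTINGS.peep)),
        rr=float(vent.get("rr", DEFAULT_SETTINGS.rr)),
        ie_ratio=(float(ie[0]), float(ie[1])),
    )
    spl = raw.get("splitter", {})
    splitter = SplitterConfig(
        topology=spl.get("topology", "standard"),
        r_i=float(spl.get("r_i", DEFAULT_R_TUBE)),
        r_e=float(spl.get("r_e", DEFAULT_R_TUBE)),
        r_v1=float(spl.get("r_v1", 0.0)),
        r_v2=float(spl.get("r_v2", 0.0)),
    )
    patients = [_parse_patient(p) for p in raw.get("patients", [])]
    return SimulationConfig(ventilator=settings, splitter=splitter, patients=patients)
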