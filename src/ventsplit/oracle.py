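"""Closed-form periodic steady state of a single series-RC branch.

Under the square-wave source a lone patient branch is a first-order RC
circuit with (possibly different) charging and discharging resistances.
Writing dP = PIP - PEEP, tau_i = r_insp * C, tau_e = r_exp * C,
a = exp(-t_insp/tau_i) and b = exp(-t_exp/tau_e), the steady tidal volume
is

    VT = 1000 * C * dP * (1 - a) * (1 - b) / (1 - a*b)   [ml]

This is derived by matching the end-inspiratory and end-expiratory
compliance pressures of the periodic orbit, independently of the network
integrator, and serves as its cross-check.  It is exact for a single
patient and for symmetric two-patient splits (where symmetry forces zero
cross-flow); for asymmetric pairs it ignores the weak coupling through the
shared tubing and is approximate (the shared-arm resistances are two
orders of magnitude below the patient impedance, so the error is well
under a millilitre).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .params import LungModel, SplitterConfig, VentilatorSettings
from .waveform import schedule


@dataclass(frozen=True)
class BranchSpec:
    """One patient's lumped branch: compliance plus total path resistances.

    ``r_insp`` is the total resistance from the source to the compliance
    during inspiration (restrictor + tubing + tracheal tube + airway);
    ``r_exp`` the total during expiration.
    """

    c: float
    r_insp: float
    r_exp: float

    def __post_init__(self) -> None:
        if not self.c > 0:
            raise ValueError("compliance must be positive")
        if not (self.r_insp > 0 and self.r_exp > 0):
            raise ValueError("path resistances must be positive")

    @property
    def tau_insp(self) -> float:
        return self.r_insp * self.c

    @property
    def tau_exp(self) -> float:
        return self.r_exp * self.c


def steady_state_vt(branch: BranchSpec, settings: VentilatorSettings) -> float:
    """Steady-cycle tidal volume in ml for one isolated branch."""
    sched = schedule(settings)
    a = math.exp(-sched.t_insp / branch.tau_insp)
    b = math.exp(-sched.t_exp / branch.tau_exp)
    dp = settings.delta_p
    return 1000.0 * branch.c * dp * (1.0 - a) * (1.0 - b) / (1.0 - a * b)


def branch_for_patient(lung: LungModel, splitter: SplitterConfig,
                       which: int = 1) -> BranchSpec:
    """Total-path branch for patient 1 or 2 of a split configuration.

    Inspiratory path: R_V (modified topology only) + R_I + R_ETT + R_L;
    expiratory path: R_E + R_ETT + R_L.
    """
    r_v = 0.0
    if splitter.topology == "modified":
        r_v = splitter.r_v1 if which == 1 else splitter.r_v2
    r_insp = r_v + splitter.r_i + lung.r_ett + lung.r_l
    r_exp = splitter.r_e + lung.r_ett + lung.r_l
    return BranchSpec(c=lung.c_l, r_insp=r_insp, r_exp=r_exp)
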