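"""Square-wave pressure source and breath-phase timing.

The ventilator is modelled as an ideal pressure source that holds PIP
during inspiration and PEEP during expiration.  Cycle timing follows from
the respiratory rate (period = 60/RR seconds) and the I:E ratio, which
splits each period into inspiratory and expiratory parts.  t = 0 is the
rising edge of the first inspiration; the integrator restarts exactly at
every edge so the discontinuity is never stepped over.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

from .params import VentilatorSettings


class Phase(Enum):
    """Breath phase: inspiration (source at PIP) or expiration (PEEP)."""

    INSP = "insp"
    EXP = "exp"


@dataclass(frozen=True)
class PhaseSchedule:
    """Derived cycle timing: period = t_insp + t_exp, all in seconds."""

    period: float
    t_insp: float
    t_exp: float

    def phase_at(self, t: float) -> Phase:
        """Phase at time t >= 0 (edge instants belong to the new phase)."""
        tau = math.fmod(t, self.period)
        return Phase.INSP if tau < self.t_insp else Phase.EXP

    def segments(self, n_cycles: int):
        """Yield (cycle, phase, t_start, t_end) for n_cycles full breaths."""
        for k in range(n_cycles):
            t0 = k * self.period
            yield k, Phase.INSP, t0, t0 + self.t_insp
            yield k, Phase.EXP, t0 + self.t_insp, t0 + self.period


def schedule(settings: VentilatorSettings) -> PhaseSchedule:
    """Compute the breath-cycle timing for the given ventilator settings.

    period = 60/RR; t_insp = period * i / (i + e) for I:E ratio i:e.
    """
    period = 60.0 / settings.rr
    i, e = settings.ie_ratio
    t_insp = period * i / (i + e)
    return PhaseSchedule(period=period, t_insp=t_insp, t_exp=period - t_insp)


def source_pressure(settings: VentilatorSettings, t: float) -> tuple[float, Phase]:
    """Source pressure (cmH2O) and phase at time t.

    PIP during [0, t_insp) of each cycle, PEEP otherwise.
    """
    if t < 0:
        raise ValueError(f"t must be >= 0, got {t}")
    phase = schedule(settings).phase_at(t)
    return (settings.pip, phase) if phase is Phase.INSP else (settings.peep, phase)


def phase_pressure(settings: VentilatorSettings, phase: Phase) -> float:
    """Source pressure associated with a phase."""
    return settings.pip if phase is Phase.INSP else settings.peep
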