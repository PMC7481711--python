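"""Calibration procedures for split ventilation.

Three procedures are provided, mirroring how the system would be titrated
at the bedside:

* :func:`tune_pip` — raise PIP until patient 1 reaches a target tidal
  volume (used on matched pairs, where both patients track together).
* :func:`tune_modified` — for a mismatched pair on the modified splitter:
  first raise PIP until the LOW-compliance patient reaches the target,
  then raise the other patient's inspiratory restrictor R_V1 to bring that
  patient back down to the target.  The two stages couple only weakly, so
  at most a few outer refinement passes are needed.
* :func:`adjust_patient2` — change patient 2's tidal volume by a fraction
  while holding patient 1: a decrease only needs R_V2; an increase raises
  PIP and then restores patient 1 with R_V1.

All procedures target the steady-cycle tidal volume and use bracketing
root finding (Brent) on responses that are smooth and strictly monotone:
VT increases with PIP and decreases with the patient's own R_V.  Recovered
settings are reported to the resolution the response supports; the
contractual outcome is the achieved tidal-volume band, not a particular
PIP/R_V value (the optimum is flat).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from scipy.optimize import brentq

from .metrics import steady_state_summary
from .params import (DEFAULT_SETTINGS, LungModel, SplitterConfig,
                     VentilatorSettings, as_lung)
from .splitters import build

#: Root-finding tolerance on the achieved tidal volume, ml.
INNER_TOL_ML = 0.25

#: Default calibration target and clinical acceptance band, ml.
DEFAULT_TARGET_ML = 490.0
DEFAULT_TOL_ML = 10.0

#: PIP search bracket, cmH2O above PEEP at the low end.
PIP_MARGIN = 0.1
PIP_MAX = 60.0

#: R_V search bracket, cmH2O/L/s.
RV_MAX = 100.0


class UnreachableTargetError(RuntimeError):
    """The target tidal volume is outside the response range on the
    search bracket."""


@dataclass(frozen=True)
class TuneResult:
    """Outcome of a calibration run."""

    pip: float
    r_v1: float
    r_v2: float
    vt1: float
    vt2: float
    iterations: int
    converged: bool


class _Evaluator:
    """Steady tidal volumes as a function of (pip, r_v1, r_v2); counts
    simulator calls."""

    def __init__(self, lung1: LungModel, lung2: LungModel | None, topology: str,
                 base: VentilatorSettings, splitter: SplitterConfig | None = None):
        self.lung1 = lung1
        self.lung2 = lung2
        self.topology = topology
        self.base = base
        self.splitter = splitter or SplitterConfig(topology=topology)
        self.calls = 0

    def vts(self, pip: float, r_v1: float = 0.0, r_v2: float = 0.0) -> tuple[float, ...]:
        self.calls += 1
        settings = replace(self.base, pip=pip)
        spl = replace(self.splitter, topology=self.topology, r_v1=r_v1, r_v2=r_v2)
        lungs = [self.lung1] if self.lung2 is None else [self.lung1, self.lung2]
        summary = steady_state_summary(build(settings, spl, lungs), settings)
        return summary.tidal_volume_ml


def _bracketed_root(f, lo: float, hi: float, what: str) -> float:
    flo, fhi = f(lo), f(hi)
    if flo == 0.0:
        return lo
    if fhi == 0.0:
        return hi
    if flo * fhi > 0:
        raise UnreachableTargetError(
            f"target unreachable for {what}: f({lo:g})={flo:.2f} ml, "
            f"f({hi:g})={fhi:.2f} ml have the same sign")
    return brentq(f, lo, hi, xtol=1e-4)


def _pair(pair) -> tuple[LungModel, LungModel]:
    l1, l2 = pair
    return as_lung(l1), as_lung(l2)


def tune_pip(pair, topology: str = "standard", target_vt: float = DEFAULT_TARGET_ML,
             tol: float = DEFAULT_TOL_ML,
             settings: VentilatorSettings = DEFAULT_SETTINGS,
             splitter: SplitterConfig | None = None) -> TuneResult:
    """Find the PIP at which patient 1's steady tidal volume hits the target.

    Monotone bracketing on PIP in [PEEP + 0.1, 60] cmH2O; raises
    :class:`UnreachableTargetError` with the bracket values if the target
    lies outside the achievable range.
    """
    lung1, lung2 = _pair(pair)
    ev = _Evaluator(lung1, lung2, topology, settings, splitter)
    pip = _bracketed_root(lambda p: ev.vts(p)[0] - target_vt,
                          settings.peep + PIP_MARGIN, PIP_MAX, "PIP")
    vts = ev.vts(pip)
    converged = abs(vts[0] - target_vt) <= tol
    return TuneResult(pip=pip, r_v1=0.0, r_v2=0.0, vt1=vts[0], vt2=vts[-1],
                      iterations=ev.calls, converged=converged)


def tune_modified(pair, target_vt: float = DEFAULT_TARGET_ML,
                  tol: float = DEFAULT_TOL_ML,
                  settings: VentilatorSettings = DEFAULT_SETTINGS,
                  splitter: SplitterConfig | None = None,
                  max_outer: int = 3) -> TuneResult:
    """Equalize both patients of a mismatched pair at the target tidal volume.

    Patient 2 must be the lower-compliance patient (its restrictor R_V2
    stays at zero).  Stage 1 titrates PIP for patient 2; stage 2 titrates
    R_V1 for patient 1; stage 1 is repeated if stage 2 moved patient 2 off
    target, up to ``max_outer`` passes.
    """
    lung1, lung2 = _pair(pair)
    if lung2.c_l > lung1.c_l:
        raise ValueError("patient 2 must be the lower-compliance patient")
    ev = _Evaluator(lung1, lung2, "modified", settings, splitter)

    r_v1 = 0.0
    pip = settings.pip
    for _ in range(max_outer):
        pip = _bracketed_root(lambda p: ev.vts(p, r_v1=r_v1)[1] - target_vt,
                              settings.peep + PIP_MARGIN, PIP_MAX, "PIP (patient 2)")
        if ev.vts(pip)[0] <= target_vt + INNER_TOL_ML:
            r_v1 = 0.0  # patient 1 already at/below target with no restrictor
        else:
            r_v1 = _bracketed_root(lambda r: ev.vts(pip, r_v1=r)[0] - target_vt,
                                   0.0, RV_MAX, "R_V1 (patient 1)")
        vt1, vt2 = ev.vts(pip, r_v1=r_v1)
        if abs(vt2 - target_vt) <= INNER_TOL_ML:
            break
    converged = abs(vt1 - target_vt) <= tol and abs(vt2 - target_vt) <= tol
    return TuneResult(pip=pip, r_v1=r_v1, r_v2=0.0, vt1=vt1, vt2=vt2,
                      iterations=ev.calls, converged=converged)


def adjust_patient2(pair, delta_fraction: float, pip: float | None = None,
                    tol: float = 1.0,
                    settings: VentilatorSettings = DEFAULT_SETTINGS,
                    splitter: SplitterConfig | None = None) -> TuneResult:
    """Move patient 2's tidal volume by ``delta_fraction`` (e.g. -0.30 or
    +0.30) on the modified splitter while holding patient 1 at baseline.

    The baseline is the pair's steady state at ``pip`` with both
    restrictors at zero (``pip`` defaults to the value that equalizes the
    pair at 490 ml).  A decrease holds PIP and raises R_V2; an increase
    raises PIP until patient 2 reaches target and then raises R_V1 to
    restore patient 1.
    """
    if not abs(delta_fraction) < 1:
        raise ValueError("delta_fraction must satisfy |delta| < 1")
    lung1, lung2 = _pair(pair)
    ev = _Evaluator(lung1, lung2, "modified", settings, splitter)
    if pip is None:
        pip = tune_pip(pair, topology="modified", settings=settings,
                       splitter=splitter).pip

    vt1_base, vt2_base = ev.vts(pip)
    target2 = (1.0 + delta_fraction) * vt2_base

    if delta_fraction == 0.0:
        return TuneResult(pip=pip, r_v1=0.0, r_v2=0.0, vt1=vt1_base, vt2=vt2_base,
                          iterations=ev.calls, converged=True)

    if delta_fraction < 0:
        r_v2 = _bracketed_root(lambda r: ev.vts(pip, r_v2=r)[1] - target2,
                               0.0, 2 * RV_MAX, "R_V2 (patient 2)")
        vt1, vt2 = ev.vts(pip, r_v2=r_v2)
        converged = abs(vt2 - target2) <= tol and abs(vt1 - vt1_base) <= tol
        return TuneResult(pip=pip, r_v1=0.0, r_v2=r_v2, vt1=vt1, vt2=vt2,
                          iterations=ev.calls, converged=converged)

    new_pip = _bracketed_root(lambda p: ev.vts(p)[1] - target2,
                              settings.peep + PIP_MARGIN, PIP_MAX, "PIP (patient 2)")
    r_v1 = _bracketed_root(lambda r: ev.vts(new_pip, r_v1=r)[0] - vt1_base,
                           0.0, RV_MAX, "R_V1 (patient 1)")
    vt1, vt2 = ev.vts(new_pip, r_v1=r_v1)
    converged = abs(vt2 - target2) <= tol and abs(vt1 - vt1_base) <= tol
    return TuneResult(pip=new_pip, r_v1=r_v1, r_v2=0.0, vt1=vt1, vt2=vt2,
                      iterations=ev.calls, converged=converged)
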