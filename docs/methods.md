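# Methods

## Model

Each patient is a single-compartment linear respiratory system: one
compliance `C_L` (lungs + chest wall) charged through the series
resistance of endotracheal tube (`R_ETT`) and airways (`R_L`). The
ventilator circuit is an electrical-analogue network — volume ↔ charge,
flow ↔ current, pressure ↔ voltage — in which tubing segments are
resistors, the ventilator is an ideal square-wave pressure source (PIP
during inspiration, PEEP during expiration) and one-way valves are ideal
diodes. All pressures are gauge (atmosphere = ground = 0).

Three topologies are built:

* **single** — one patient, for validation against the closed form;
* **standard** — two patients joined by T-pieces: each wye connects to the
  inspiratory port through `R_I` and to the expiratory port through `R_E`;
* **modified** — as standard, plus an adjustable restrictor `R_V1`/`R_V2`
  in series with each inspiratory arm and a check valve in each
  expiratory arm that permits patient→ventilator flow only.

The source ports are phase-gated: an inspiration-phase valve connects the
source to the inspiratory tee and an expiration-phase valve connects the
expiratory tee back to the source, mirroring a ventilator's internal
inspiratory/expiratory valves. A consequence worth noting: on the
*standard* splitter during inspiration, the two expiration arms and the
closed expiratory port form a resistive path directly between the two
patients' wyes. That path is exactly what the modified splitter's check
valves remove. Its resistance (`R_E1 + R_E2 = 0.12 cmH2O/L/s`) is two
orders of magnitude below the patient impedance (~10 cmH2O/L/s), which is
why cross-coupling shifts tidal volumes by well under a millilitre and
patient 1 is insensitive to its partner's compliance.

## Parameters

All values in clinical units (cmH2O, L, s); SI conversions use
1 cmH2O = 98.0665 Pa and are I/O conveniences only (the network is linear,
so units merely rescale). Defaults:

| parameter | value | meaning |
|---|---|---|
| PIP | 15 cmH2O (reference) | inspiratory plateau; raised during calibration |
| PEEP | 5 cmH2O | expiratory baseline |
| RR | 15 /min | cycle period 4 s |
| I:E | 1:2 | t_insp 4/3 s, t_exp 8/3 s |
| R_I, R_E | 0.06 cmH2O/L/s | Poiseuille estimate for 1.8 m of 22 mm tubing (`128 µL/(π D⁴)` ≈ 5.7e3 Pa·s/m³) |
| R_L | 2 cmH2O/L/s | airway resistance, all presets |
| R_ETT | 8 cmH2O/L/s | endotracheal tube, all presets |
| C_L | 0.054 L/cmH2O × (1, 0.8, 0.7, 0.6) | presets A–D; ARDS modelled purely as compliance loss |
| R_V | 0 (adjustable) | inspiratory restrictor, modified splitter only |

The published SI table rounds some conversions (784000 vs exact 784532
Pa·s/m³ for `R_ETT`; the tubing row is rounded independently in each unit
system); `params.si_registry(rounded=True)` reproduces the rounded
figures verbatim for comparison studies. The difference is < 0.1 ml of
tidal volume.

## Numerics

* **State** is the vector of compliance pressures (not charges): stored
  volume is derived as `Q = C_L · P_alv`, so volume and pressure can never
  drift apart.
* **Instantaneous solves.** With compliance pressures given, the network
  is resistive; node pressures follow from nodal balance (LU-factored per
  conduction state and cached). Valves are piecewise-linear ideal:
  on-resistance 1e-4, blocking (leak) resistance 1e8 cmH2O/L/s — chosen to
  keep the nodal matrix well-conditioned while sitting ≥9 orders of
  magnitude away from every physical resistance. Zero-valued resistors
  (e.g. an `R_V = 0` arm) are clamped to the on-resistance for the same
  reason (< 0.01 ml effect).
* **Valve logic.** A conducting valve blocks when its flow falls below
  −1e-7 L/s; a blocked valve conducts when its forward bias exceeds
  1e-7 cmH2O. The asymmetric rule with a tolerance band matters: a valve
  pinned at zero current (e.g. an expiratory valve whose downstream port
  is closed) is consistent in either state at leak level, and a
  sign-of-pressure rule would chatter indefinitely. Conduction states are
  resolved by fixed-point iteration with exhaustive enumeration over the
  ≤ 2² assignments as a fallback.
* **Integration.** Adaptive explicit Runge–Kutta (RK45), rtol 1e-8,
  atol 1e-12, restarted exactly at every phase edge and at every valve
  switching event (located by event detection on the offset switching
  functions above, so the solver never steps across a discontinuity).
  These tolerances target the exact ODE solution; they are deliberately
  much tighter than a typical block-diagram default (rtol 1e-3), and
  tightening rtol a further 10× moves tidal volumes by < 0.1 ml.
* **Steady state.** Simulations start from the all-zero state. A cycle is
  steady when consecutive cycles' tidal volumes agree to < 0.05 ml per
  patient; with every time constant (≤ 0.55 s) well below the phase times
  this happens by the second breath (end-expiratory residual factor
  `exp(−t_exp/τ_e) < 0.01` for every configuration of interest), so the
  default run of 4 cycles is ample and reported summaries always come
  from a steady cycle.
* **Metrics.** Tidal volume = max − min stored volume within a cycle
  (immune to cross-flow artifacts); achieved PEEP = minimum airway
  pressure at the patient side of `R_ETT`; peak airway pressure likewise.

## Calibration procedures

All procedures target steady-cycle tidal volumes and use bracketing root
finding (Brent, inner tolerance 0.25 ml) on responses that are smooth and
strictly monotone — VT rises with PIP and compliance, falls with the
patient's own restrictor (property-tested):

* `tune_pip` — bisect PIP ∈ [PEEP + 0.1, 60] until patient 1 hits the
  target (default 490 ± 10 ml).
* `tune_modified` — stage 1: bisect PIP until the *low-compliance* patient
  (patient 2 by convention, `R_V2 = 0`) hits target; stage 2: bisect
  `R_V1 ∈ [0, 100]` until patient 1 hits target; repeat stage 1 if stage 2
  moved patient 2 (coupling is weak; ≤ 3 outer passes suffice).
* `adjust_patient2` — decrease: hold PIP, raise `R_V2`; increase: raise
  PIP until patient 2 hits target, then raise `R_V1` to restore patient 1.

The tuning landscape is flat near the optimum: distinct (PIP, R_V)
combinations within ~1 cmH2O / ~1 cmH2O/L/s achieve tidal volumes within
the clinical band, so recovered settings are not unique — the contractual
outcome is the achieved-volume band, not a particular setting.

## Design choices made where the design was open

* The internal wiring of the ventilator's control porting is not uniquely
  determined by a circuit sketch with two gated ports; the gated
  inspiratory/expiratory port topology above was chosen because it both
  matches how real ventilators sequence flow and produces the
  inter-patient short-circuit path that the modified splitter's check
  valves are explicitly there to remove.
* Expiration arms join at the patient wye (splitter side of `R_ETT`),
  mirroring the inspiration arms, so the splitter is a self-contained
  block attached to the patient limb.
* `R_V` sits between the inspiratory tee and `R_I`; series resistances
  commute, so this ordering is cosmetic.
* Check-valve orientation permits expiratory (patient → ventilator) flow
  and blocks ventilator → patient flow through the expiration arm.

## What the model does and does not capture

The simulator reproduces the behaviour of an idealized linear circuit: it
demonstrates the *mechanism* of compliance-mismatch volume starvation and
the *controllability* added by restrictors and check valves. It does not
emulate several features of real shared-ventilation hardware, so passing
tests bound the model, not the hardware:

* resistances are linear (laminar); real ribbed tubing becomes turbulent
  at high flow, and ARDS raises expiratory (flow-direction-dependent)
  airway resistance — both are outside scope here;
* no inertance, humidifiers, filters, leaks or gas compressibility;
* real one-way valves have cracking pressures and finite forward drops;
  the ideal-diode model is the stated intent of the design, and the
  residual ~1–2% disagreement with one published calibration table on
  exactly the restrictor-bearing cells is consistent with unstated
  component defaults in the original block-library implementation;
* both patients necessarily share RR, I:E and PEEP; per-patient PEEP
  control (expiratory restrictors + inspiratory check valves) is a
  hypothesis not simulated here;
* the model says nothing about monitoring, infection control, or the
  clinical ethics of ventilator sharing — it is a circuit study only.

## Problem sizes

Every simulation is a two-state (one per patient) switched linear ODE over
4–12 breath cycles (16–48 s of simulated time), solved in ~0.1–0.3 s.
Calibrations run 10–40 such simulations; the full test suite and the
acceptance script each complete in a few minutes on one CPU.
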