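# ventsplit

Lumped-parameter simulation of **one pressure-control ventilator shared by
two patients** through a T-piece splitter, for quantifying the risks of
emergency ventilator splitting and for prototyping splitter modifications
that make per-patient tidal-volume control possible.

Sharing a ventilator is strongly advised against in normal circumstances:
with a plain splitter both patients receive the same pressure waveform, so
any mismatch in respiratory compliance (e.g. one healthy patient paired
with an ARDS patient) starves the stiffer patient of tidal volume, and
nothing on the ventilator can correct it for one patient without harming
the other. This package quantifies that effect and simulates a modified
splitter — an adjustable flow restrictor in each inspiratory limb and a
one-way valve in each expiratory limb — under which the two tidal volumes
become independently controllable.

## Model

The pneumatic circuit maps onto an electrical analogue: volume ↔ charge,
flow ↔ current, pressure ↔ voltage, tubing ↔ resistance, lung + chest wall
↔ capacitance, one-way valve ↔ diode. Each patient is a single RC
compartment: compliance `C_L` behind airway and endotracheal-tube
resistances `R_L + R_ETT`, fed through tubing resistance `R_I` (plus the
restrictor `R_V` on the modified splitter). The ventilator is an ideal
square-wave pressure source: PIP during inspiration, PEEP during
expiration, timing set by the respiratory rate and I:E ratio.

For an isolated branch the periodic steady state is closed-form. With
`ΔP = PIP − PEEP`, `τ_i = R_insp·C_L`, `τ_e = R_exp·C_L`,
`a = exp(−t_insp/τ_i)`, `b = exp(−t_exp/τ_e)`:

```
VT = 1000 · C_L · ΔP · (1 − a)(1 − b) / (1 − a·b)   [ml]
```

The full network (shared tubing, valves, both patients) is solved as a
switched linear circuit: nodal balance at every instant conditioned on
each valve's conduction state, adaptive Runge–Kutta integration of the
compliance pressures, with hard restarts at phase edges and valve
switching events. The closed form above is kept as an independent
cross-check of the simulator (they agree to well under 0.5 ml wherever the
closed form is exact).

Patient severity presets follow reduced compliance: A healthy
(0.054 L/cmH2O), B/C/D at 20/30/40% reduction (mild/moderate/severe ARDS);
all use `R_L` = 2 and `R_ETT` = 8 cmH2O/L/s.

## Worked example

Ventilate mismatched pairs through the *standard* (unregulated) splitter
at the PIP calibrated for patient 1, and measure both tidal volumes:

```python
from ventsplit.experiments import run_standard_mismatch
df = run_standard_mismatch()
print(df[["pair", "pip_cmH2O", "vt1_ml", "vt2_ml", "shortfall_ml",
          "shortfall_pct"]].to_string(index=False, float_format=lambda x: f"{x:.1f}"))
```

```
pair  pip_cmH2O  vt1_ml  vt2_ml  shortfall_ml  shortfall_pct
 A-A       15.0   490.3   490.3           0.0            0.0
 A-B       15.0   490.3   411.0          79.3           16.2
 A-C       15.0   490.3   366.3         124.1           25.3
 A-D       15.0   490.4   318.4         171.9           35.1
 B-C       17.0   493.3   439.6          53.7           10.9
 B-D       17.0   493.3   382.2         111.2           22.5
 C-D       18.5   494.6   429.9          64.6           13.1
```

Patient 1 always receives its target (~490 ml) because the shared tubing
is a weak coupling, but the lower-compliance patient 2 is progressively
starved — down 35% in the extreme healthy/severe pairing. The modified
splitter repairs this; calibrating it from scratch:

```python
from ventsplit.tuning import tune_modified
r = tune_modified(("A", "D"))
print(f"PIP={r.pip:.2f} R_V1={r.r_v1:.2f} VT1={r.vt1:.1f} VT2={r.vt2:.1f}")
```

```
PIP=20.39 R_V1=17.45 VT1=490.0 VT2=490.0
```

i.e. raise PIP until the stiff patient reaches 490 ml, then restrict the
healthy patient's inspiratory limb (≈17 cmH2O/L/s) to bring it back down
to 490 ml. `ventsplit.tuning.adjust_patient2` similarly retargets one
patient by ±30% while holding the other.

The same is available from the shell:

```
ventsplit reproduce standard-mismatch --out mismatch.csv
ventsplit tune-modified --pair A,D
ventsplit simulate --config examples/pair_ad.yaml --cycles 6 --out trace.csv
```

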