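# Healthy patient (A) paired with severe ARDS (D) on the unregulated
# standard splitter at the reference ventilator settings.
# All values in clinical units: cmH2O, L, s.
ventilator:
  pip: 15
  peep: 5
  rr: 15
  ie: [1, 2]
splitter:
  topology: standard
  r_i: 0.06
  r_e: 0.06
patients:
  - A
  - D
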