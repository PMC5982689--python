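# Scenario with a gripped PC-3 cell (reference mean modulus).
extends: paper_default

cell:
  E_c: 1401 Pa
  v: 0.5
  R: 10 um
  label: PC-3
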