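kind: panel
indicators:
- V1
- V2
- V3
- V4
factors:
  V1:
  - V1
  V2:
  - V2
  V3:
  - V3
  V4:
  - V4
identification: loadings
observed: true
n_waves: 3
between_residual_fixed_zero:
- V1
- V2
- V3
- V4
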