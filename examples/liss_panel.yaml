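kind: panel
indicators:
- SE1
- SE2
- SE3
- Pes1
- Pes2
- Pes3
- Opt1
- Opt2
- Opt3
- LS1
- LS2
- LS3
- LS4
- LS5
- PA1
- PA2
- PA3
- PA4
- NA1
- NA2
- NA3
- NA4
factors:
  SE:
  - SE1
  - SE2
  - SE3
  Pes:
  - Pes1
  - Pes2
  - Pes3
  Opt:
  - Opt1
  - Opt2
  - Opt3
  LS:
  - LS1
  - LS2
  - LS3
  - LS4
  - LS5
  PA:
  - PA1
  - PA2
  - PA3
  - PA4
  NA:
  - NA1
  - NA2
  - NA3
  - NA4
identification: loadings
observed: false
n_waves: 3
between_residual_fixed_zero:
- SE2
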