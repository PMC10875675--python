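basis_mode: ecp
elements:
  H:
    effective_Z: 1.0
    shells:
    - weight: 0.030102996285349324
      exponent: 7.820855731667337
    - weight: 0.3592027005876373
      exponent: 1.4199200327563382
    - weight: 0.6106943031270133
      exponent: 0.37861496203778827
  O:
    effective_Z: 6.0
    shells:
    - weight: -0.1820035647683573
      exponent: 11.667603991591463
    - weight: 4.183611082819121
      exponent: 1.4385471932811362
    - weight: 1.9983924819492365
      exponent: 0.6877342622638778
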