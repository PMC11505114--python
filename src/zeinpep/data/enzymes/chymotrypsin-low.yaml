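name: chymotrypsin (low specificity)
ec: 3.4.21.1
subrules:
- p1:
  - F
  - H
  - L
  - M
  - N
  - W
  - Y
  p1prime_blocked: []
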