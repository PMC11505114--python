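name: subtilisin
ec: 3.4.21.62
subrules:
- p1:
  - A
  - F
  - I
  - L
  - M
  - V
  - W
  - Y
  p1prime_blocked: []
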