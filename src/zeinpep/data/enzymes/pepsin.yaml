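name: pepsin (pH 1.3)
ec: 3.4.23.1
subrules:
- p1:
  - F
  - L
  p1prime_blocked: []
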