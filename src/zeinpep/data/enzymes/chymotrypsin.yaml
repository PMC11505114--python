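name: chymotrypsin A
ec: 3.4.21.1
subrules:
- p1:
  - F
  - W
  - Y
  p1prime_blocked:
  - P
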