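accession	name	length
Q94IM1	22 kDa alpha-zein 14	266
P04698	22 kDa alpha-zein 14	267
P06679	22 kDa alpha-zein 8b	261
P04700	22 kDa alpha-zein 16	263
P06678	Zein-alpha 19D1	240
P04704	Zein-alpha ZG99	235
P06676	Zein-alpha 19C1	240
P04703	Zein-alpha A20	240
P06674	Zein-alpha 19A2	230
P06675	Zein-alpha 19B1	234
P04702	Zein-alpha M6	240
P02859	Zein-alpha A30	234
P04705	Zein-alpha PZ19.1	186
Q548E6	19kD alpha zein B3	240
Q548E7	19kD alpha zein B2	267
B6SIF7	Zein-alpha PMS1	234
B6SHV3	Zein-alpha 19B1	234
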