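accession_a	accession_b	identity_pct
Q94IM1	P04698	98.9
Q94IM1	P06679	88.9
Q94IM1	P04700	86.2
Q94IM1	P06678	49.1
Q94IM1	P04704	44.2
Q94IM1	P06676	46.7
Q94IM1	P04703	46.7
Q94IM1	P06674	43.6
Q94IM1	P06675	46.0
Q94IM1	P04702	46.7
Q94IM1	P02859	46.4
Q94IM1	P04705	41.9
Q94IM1	Q548E6	46.4
Q94IM1	Q548E7	45.5
Q94IM1	B6SIF7	43.8
Q94IM1	B6SHV3	44.0
P04698	P06679	89.3
P04698	P04700	87.3
P04698	P06678	49.1
P04698	P04704	44.4
P04698	P06676	46.7
P04698	P04703	46.7
P04698	P06674	43.8
P04698	P06675	43.5
P04698	P04702	46.7
P04698	P02859	43.9
P04698	P04705	41.7
P04698	Q548E6	46.4
P04698	Q548E7	45.3
P04698	B6SIF7	43.7
P04698	B6SHV3	43.9
P06679	P04700	90.1
P06679	P06678	49.1
P06679	P04704	43.5
P06679	P06676	42.4
P06679	P04703	46.0
P06679	P06674	42.9
P06679	P06675	42.8
P06679	P04702	46.8
P06679	P02859	43.1
P06679	P04705	43.2
P06679	Q548E6	40.6
P06679	Q548E7	45.4
P06679	B6SIF7	43.1
P06679	B6SHV3	43.1
P04700	P06678	48.9
P04700	P04704	44.0
P04700	P06676	46.7
P04700	P04703	46.7
P04700	P06674	40.7
P04700	P06675	42.8
P04700	P04702	47.1
P04700	P02859	43.5
P04700	P04705	42.3
P04700	Q548E6	46.7
P04700	Q548E7	43.1
P04700	B6SIF7	42.5
P04700	B6SHV3	42.8
P06678	P04704	56.0
P06678	P06676	58.5
P06678	P04703	58.5
P06678	P06674	56.3
P06678	P06675	56.0
P06678	P04702	58.1
P06678	P02859	56.5
P06678	P04705	48.7
P06678	Q548E6	58.1
P06678	Q548E7	52.2
P06678	B6SIF7	56.5
P06678	B6SHV3	56.5
P04704	P06676	71.8
P04704	P04703	71.8
P04704	P06674	91.4
P04704	P06675	91.1
P04704	P04702	69.8
P04704	P02859	92.3
P04704	P04705	87.2
P04704	Q548E6	71.0
P04704	Q548E7	87.3
P04704	B6SIF7	91.9
P04704	B6SHV3	91.5
P06676	P04703	99.6
P06676	P06674	70.5
P06676	P06675	72.5
P06676	P04702	96.7
P06676	P02859	72.1
P06676	P04705	61.4
P06676	Q548E6	99.9
P06676	Q548E7	65.4
P06676	B6SIF7	72.1
P06676	B6SHV3	72.1
P04703	P06674	70.5
P04703	P06675	72.5
P04703	P04702	96.3
P04703	P02859	72.1
P04703	P04705	61.4
P04703	Q548E6	98.3
P04703	Q548E7	62.8
P04703	B6SIF7	72.1
P04703	B6SHV3	72.1
P06674	P06675	90.5
P06674	P04702	68.5
P06674	P02859	92.2
P06674	P04705	79.3
P06674	Q548E6	69.7
P06674	Q548E7	68.7
P06674	B6SIF7	91.8
P06674	B6SHV3	90.9
P06675	P04702	70.5
P06675	P02859	97.4
P06675	P04705	81.8
P06675	Q548E6	71.7
P06675	Q548E7	80.1
P06675	B6SIF7	96.6
P06675	B6SHV3	99.6
P04702	P02859	70.1
P04702	P04705	57.9
P04702	Q548E6	97.9
P04702	Q548E7	63.9
P04702	B6SIF7	70.1
P04702	B6SHV3	70.1
P02859	P04705	82.4
P02859	Q548E6	71.3
P02859	Q548E7	80.5
P02859	B6SIF7	98.3
P02859	B6SHV3	97.9
P04705	Q548E6	60.4
P04705	Q548E7	87.8
P04705	B6SIF7	81.3
P04705	B6SHV3	82.4
Q548E6	Q548E7	97.0
Q548E6	B6SIF7	71.3
Q548E6	B6SHV3	80.5
Q548E7	B6SIF7	80.1
Q548E7	B6SHV3	97.0
B6SIF7	B6SHV3	97.0
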