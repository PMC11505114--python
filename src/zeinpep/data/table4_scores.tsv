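sequence	score	activities
FCF	0.9978	ACE inhibitor
CF	0.9964	ACE inhibitor
GF	0.9947	ACE inhibitor; Renin inhibitor; Dipeptidyl peptidase III inhibitor; Dipeptidyl peptidase IV inhibitor
FP	0.9939	ACE inhibitor; Dipeptidyl peptidase IV inhibitor
PF	0.9934	ACE inhibitor; Dipeptidyl peptidase IV inhibitor
LF	0.9869	ACE inhibitor
RF	0.9865	ACE inhibitor; Dipeptidyl peptidase III inhibitor; Dipeptidyl peptidase IV inhibitor
FY	0.9824	ACE inhibitor; Alpha-amylase inhibitor; Hypotensive; Antioxidative
LPF	0.9749	ACE inhibitor; Anti-inflammatory; Dipeptidyl peptidase IV inhibitor
AF	0.9732	ACE inhibitor; Inhibitor of tripeptidyl peptidase II; Dipeptidyl peptidase IV inhibitor
IF	0.9491	ACE inhibitor; Dipeptidyl peptidase IV inhibitor
SF	0.9487	ACE inhibitor; Renin inhibitor; Dipeptidyl peptidase IV inhibitor
MG	0.9439	ACE inhibitor; Dipeptidyl peptidase IV inhibitor
LLF	0.9389	ACE inhibitor
ARF	0.9298	ACE inhibitor
AFL	0.9285	ACE inhibitor
FQ	0.9160	ACE inhibitor; Dipeptidyl peptidase IV inhibitor
FAL	0.8902	ACE inhibitor
AFLL	0.8892	ACE inhibitor
GG	0.8873	ACE inhibitor; Dipeptidyl peptidase IV inhibitor
PP	0.8869	ACE inhibitor; Alpha-glucosidase inhibitor; Dipeptidyl peptidase IV inhibitor
LSW	0.8282	ACE inhibitor; Anti-inflammatory; Antioxidative
LPP	0.8280	ACE inhibitor; Dipeptidyl peptidase IV inhibitor
PL	0.8111	ACE inhibitor; Dipeptidyl peptidase IV inhibitor
GL	0.8087	ACE inhibitor; Xaa-Pro inhibitor; Lactocepin inhibitor; Dipeptidyl peptidase IV inhibitor
PLG	0.8013	ACE inhibitor; Dipeptidyl peptidase IV inhibitor
GFL	0.9802	Regulating (phosphoglycerate kinase activity); Dipeptidyl peptidase III inhibitor
FC	0.9960	Antioxidative
LLPF	0.9464	Antioxidative; Anti-inflammatory
PF	0.9934	Dipeptidyl peptidase IV inhibitor; Dipeptidyl peptidase III inhibitor
FL	0.9896	Dipeptidyl peptidase IV inhibitor; Dipeptidyl peptidase III inhibitor
FA	0.9558	Dipeptidyl peptidase IV inhibitor; Dipeptidyl peptidase III inhibitor
FN	0.9512	Dipeptidyl peptidase IV inhibitor
QF	0.9461	Dipeptidyl peptidase IV inhibitor; Renin inhibitor
SW	0.9339	Dipeptidyl peptidase IV inhibitor; Pancreatic lipase inhibitor
AFL	0.9285	Dipeptidyl peptidase IV inhibitor
ML	0.8945	Dipeptidyl peptidase IV inhibitor
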