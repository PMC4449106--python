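family	kind	pattern	requires_amidation	min_len	max_len	cys_count	priority
myosuppressin	regex	^QDLDHVFLRF$	1	10	10		10
CCAP	regex	^PFCNAFTGC$	1	9	9		20
OT/VP-like	regex	^CFITNCPPG$	1	9	9		30
sulfakinin	regex	GH[ML]RF$	1	6	40		40
sNPF	regex	RLR[FY]$	1	6	40		50
FLRFamide	regex	[FY][LIM]RF$	1	5	40		60
NPF	regex	R.RF$	1	25	90		70
SIFamide	regex	SIF$	1	8	30		80
tachykinin-related	regex	F.GMR$	1	6	30		90
allatostatin-A	regex	[YF].FGL$	1	5	20		100
allatostatin-B	regex	W.{6}W$	1	8	20		110
RPCH	regex	NFSPGW$	1	8	12		120
corazonin	regex	RGWTN$	1	8	15		130
PDH	regex	^NS..INS.LG.P	1	18	18		140
orcokinin	regex	^NFDEIDRS	0	8	20		150
CLDH	regex	GP$	1	28	34		160
DH45	regex	.	1	40	50		170
EH	cys		0	50	62	6	180
CHH-superfamily	cys		0	66	80	6	190
neuroparsin	cys		0	70	80	12	200
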