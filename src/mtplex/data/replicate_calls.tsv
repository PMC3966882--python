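individual	period	method	call_1	call_2	printed_consensus
EI 1	EI	snp26	B2	B2	B2
EI 1	EI	hvr1	?	?	B2
EI 2	EI	snp26	D1?	M	D1
EI 2	EI	hvr1	D1	D1	D1
EI 3	EI	snp26	C1b	C1b	C1b
EI 3	EI	hvr1	C1	C1	C1b
EI 4	EI	snp26	B2	B2	B2
EI 4	EI	hvr1	B4	B4	B2
EI 5	EI	snp26	C1b	C1b	C1b
EI 5	EI	hvr1	C1	?	C1b
EI 6	EI	snp26	B2	B2	B2
EI 6	EI	hvr1	B4	B4	B2
EI 7	EI	snp26	B2	B2	B2
EI 7	EI	hvr1	?	?	B2
EI 8	EI	snp26	B2b	B2b	B2b
EI 8	EI	hvr1	B4	?	B2b
EI 9	EI	snp26	A2	A2	A2
EI 9	EI	hvr1	A2	A2	A2
EI 10	EI	snp26	B2	B2	B2
EI 10	EI	hvr1	B4	B4	B2
EI 11	EI	snp26	B2b	B2	B2
EI 11	EI	hvr1	B4	?	B2
EI 12	EI	snp26	B2b	B2	B2
EI 12	EI	hvr1	B4	B4	B2
MH 1	MH	snp26	C1b	C1b	C1b
MH 1	MH	hvr1	?	?	C1b
MH 2	MH	snp26	B2	B2	B2
MH 2	MH	hvr1	?	?	B2
MH 3	MH	snp26	B2	B2	B2
MH 3	MH	hvr1	?	?	B2
MH 4	MH	snp26	B2	B2	B2
MH 4	MH	hvr1	?	B4?	B2
MH 5	MH	snp26	C1b	C1b	C1b
MH 5	MH	hvr1	-	-	C1b
MH 6	MH	snp26	C1b	C1b	C1b
MH 6	MH	hvr1	C1	?	C1b
MH 7	MH	snp26	A2	A2	A2
MH 7	MH	hvr1	?	-	A2
MH 8	MH	snp26	A2	A2	A2
MH 8	MH	hvr1	D?	-	A2
LI 1	LI	snp26	M	C1b	C1
LI 1	LI	hvr1	C1	C1	C1
LI 2	LI	snp26	B2	B2	B2
LI 2	LI	hvr1	B4	B4	B2
LI 3	LI	snp26	B2	B2	B2
LI 3	LI	hvr1	?	-	B2
LI 4	LI	snp26	M	M	M
LI 4	LI	hvr1	C1	?	M
LI 5	LI	snp26	B2	B2b	B2
LI 5	LI	hvr1	B4	B4	B2
LI 6	LI	snp26	C1b	C1b	C1b
LI 6	LI	hvr1	C1	C1	C1b
LI 7	LI	snp26	B2b	B2	B2
LI 7	LI	hvr1	?	?	B2
LI 8	LI	snp26	B2	B2	B2
LI 8	LI	hvr1	B4	B4	B2
LI 9	LI	snp26	B2	B2b	B2
LI 9	LI	hvr1	B4	B4	B2
LI 10	LI	snp26	C1b	C1b	C1b
LI 10	LI	hvr1	C1	C1	C1b
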