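family	subfamily	P_pacificus	C_elegans
HAT	CBP/P300	12	7
HAT	GNAT	15	11
HAT	MYST	7	4
HAT	Other	2	1
HDAC	Class I	4	3
HDAC	Class II	4	5
HDAC	Class III	5	4
HDAC	Class IV	1	1
HMT	PRMT	12	3
HMT	SET	45	31
HMT	DOT1	6	6
HMT	Other	1	1
HDMT	JMJ	20	12
HDMT	LSD	2	3
HISTONE	H1	5	9
HISTONE	H2A	13	19
HISTONE	H2B	12	17
HISTONE	H3	19	24
HISTONE	H4	12	16
DNA_METH	DNA methyltransferase	1	0
DNA_METH	ALKB	5	5
DNA_METH	DAMT-1	1	1
NCRNA	Dicer	1	1
NCRNA	RdRP	5	4
NCRNA	Helicases	7	4
NCRNA	Argonautes	23	20
NCRNA	Drosha	1	1
NCRNA	Microprocessor complex	2	1
REMODELER	SWI/SNF	2	2
REMODELER	ISWI	2	1
REMODELER	INO80	1	1
REMODELER	CHD	3	4
OTHER	Histone kinase	17	22
OTHER	Histone phosphatase	5	6
OTHER	Histone ubiquitin transferase	9	7
OTHER	Histone deubiquitinase	6	6
OTHER	Misc.	3	2
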