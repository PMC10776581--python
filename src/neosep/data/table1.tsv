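baby_id	birth_ga_weeks	sex	n_samples	day_first	day_last	n_mcs	organisms	onset_type	n_clinsep	n_nsc	n_stable	n_nec	flow_cohort
A1	25	F	10	1	48	3	CoNS	LOS	1	1	5	0	1
A10	25	F	14	2	76	2	E. coli	EOS	4	2	6	0	1
A11	29	F	7	4	53	2	E. cloacae	LOS	0	0	5	0	1
A12	24	M	9	5	61	2	E. cloacae	LOS	2	0	5	0	1
A13	26	F	14	4	75	2	CoNS	LOS	2	3	7	0	1
A14	24	F	5	4	30	2	CoNS	LOS	1	0	2	0	1
A15	24	F	13	6	76	0	-	-	2	5	6	0	1
A16	26	M	9	8	71	0	-	-	1	1	7	0	1
A17	23	M	11	7	74	2	E. faecalis	LOS	4	1	4	0	1
A18	24	F	10	5	69	2	CoNS	LOS	2	2	4	0	1
A19	28	M	8	8	56	0	-	-	2	0	6	0	1
A2	24	F	12	3	79	2	CoNS	LOS	0	3	7	0	1
A20	24	F	3	7	21	0	-	-	3	0	0	0	1
A21	28	M	7	3	44	0	-	-	2	1	4	0	1
A3	24	M	10	4	58	2	CoNS	LOS	1	0	7	0	1
A4	24	F	3	2	8	1	CoNS	LOS	0	1	1	0	1
A5	28	F	6	4	31	1	CoNS	LOS	0	0	4	1	1
A6	23	M	5	8	35	1	CoNS	LOS	0	1	3	0	1
A7	26	M	12	2	73	4	GBS/CoNS	LOS	0	3	4	1	1
A8	24	M	2	1	4	1	E. coli	EOS	0	1	0	0	1
A9	24	M	14	2	84	2	E. coli	EOS	1	2	9	0	1
B10	29	M	8	3	51	0	-	-	0	0	8	0	0
B11	27	F	9	3	55	0	-	-	0	0	9	0	0
B12	28	M	7	6	48	0	-	-	0	0	7	0	0
B13	29	M	7	5	46	0	-	-	0	0	7	0	0
B14	25	M	8	5	47	0	-	-	0	0	8	0	0
B6	24	M	7	6	45	0	-	-	2	0	1	4	1
B7	26	M	4	5	39	1	S. anginosus	EOS	0	1	2	0	0
B8	29	F	4	7	35	0	-	-	0	0	4	0	0
B9	30	M	4	4	26	0	-	-	0	0	4	0	0
C12	26	M	10	4	74	0	-	-	7	1	2	0	0
C13	26	M	9	3	43	0	-	-	6	0	3	0	0
C17	27	M	6	4	60	0	-	-	3	1	2	0	0
C2	26	F	9	4	87	0	-	-	1	1	7	0	0
C3	29	M	10	4	73	3	CoNS	LOS	4	1	2	0	0
C4	25	F	11	4	88	0	-	-	7	1	3	0	0
C5	25	F	11	4	88	2	CoNS	LOS	4	0	5	0	0
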