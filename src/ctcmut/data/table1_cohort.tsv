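case_id	t_stage	lvi	vein_invasion	vim_pos_ck_neg	vim_neg_ck_pos	vim_pos_ck_pos	total_ctc
TCC14	T4a	Pos	Neg	1	17	0	18
TCC16	T1	Neg	Neg	1	7	1	9
TCC17	T3a	Pos	Neg	1	5	2	8
TCC18	T3a	Neg	Neg	0	17	1	18
TCC20	T2b	Pos	Pos	6	1	21	28
TCC21	T3a	Pos	Pos	0	0	15	15
TCC27	T3a	Neg	Neg	0	11	0	11
TCC28	T2b	Pos	Neg	0	12	5	17
TCC31	T2a	Pos	Pos	9	1	4	14
TCC32	T3a	Pos	Pos	3	11	18	32
TCC37	Ta	Neg	Neg	1	1	0	2
TCC38	T3a	Neg	Neg	1	12	17	30
TCC39	T1	Neg	Neg	0	4	4	8
TCC40	Ta	Neg	Neg	2	1	4	7
TCC41	Ta	Neg	Neg	0	1	2	3
TCC43	T1	Neg	Neg	1	2	7	10
TCC44	T1	Neg	Neg	1	2	5	8
TCC45	T3a	Pos	Pos	0	19	8	27
TCC46	T2a	Neg	Neg	4	2	4	10
TCC47	T2a	Neg	Neg	2	1	7	10
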