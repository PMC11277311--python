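pair	P_SUM	P_O	P_LO	P_VUS	R_SUM	R_O	R_LO	R_VUS	S_SUM	S_O	S_LO	S_VUS
1	29	3	3	23	27	0	2	25	9	2	1	6
2	12	0	3	9	26	1	0	25	4	2	0	2
3	13	0	5	8	55	3	5	47	3	0	1	2
4	12	1	0	11	24	3	4	17	2	0	0	2
5	61	1	5	55	61	5	2	54	5	1	0	4
6	13	1	1	11	35	3	4	28	7	1	2	4
7	36	2	5	29	17	0	0	17	1	0	0	1
8	34	3	2	29	34	2	8	24	6	3	0	3
9	10	0	1	9	14	1	0	13	4	1	1	2
10	16	1	1	14	41	3	2	36	6	1	1	4
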