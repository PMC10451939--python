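subject_chromosome	8:top	8:total	8:solo	41:top	41:total	41:solo	22:top	22:total	22:solo
1	2	12	0	5	13	2	68	109	19
2	8	29	1	7	26	1	2	14	1
3	0	12	0	1	8	0	0	8	0
4	59	96	4	61	92	10	8	16	0
5	14	48	1	20	48	5	4	14	0
6	3	10	0	1	3	0	11	25	3
7	2	11	0	2	6	2	3	11	0
8	2	18	1	5	12	0	6	15	2
9	4	10	2	4	12	0	61	98	14
10	75	117	12	36	72	9	17	32	5
11	0	9	0	1	9	0	1	5	0
12	1	8	0	2	7	0	2	13	0
13	0	2	0	2	4	0	1	2	0
14	0	3	0	1	4	0	0	6	0
15	0	1	0	1	5	0	1	6	1
16	0	8	0	0	5	0	2	10	1
17	0	6	0	3	8	2	1	13	1
18	0	0	0	0	0	0	2	4	0
19	1	7	0	2	13	0	12	37	4
20	6	10	2	3	6	1	1	5	1
21	1	4	0	0	2	0	0	1	0
22	0	2	0	0	1	0	0	2	0
X	2	8	0	0	2	0	1	5	0
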