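participant_id	age	sex	bmi	serum_d0	serum_d1
1	40	F	22.6	26.9	32.3
2	45	F	23.1	19.3	28.6
3	34	F	20.2	16.1	23.7
4	41	F	19.8	38.3	47.3
5	49	F	21.2	29.5	38.0
6	48	F	20.2	24.7	35.2
7	40	F	24.7	21.8	30.4
8	38	F	20.4	19.9	23.6
9	37	F	21.2	26.6	30.0
10	48	F	25.0	18.8	30.0
11	43	F	19.7	21.5	27.8
12	43	F	21.2	34.3	39.9
13	40	F	21.6	47.0	57.5
14	50	F	20.4	35.3	40.1
15	23	F	24.2	30.0	39.3
16	40	F	22.5	31.2	38.7
17	41	F	22.1	27.7	33.4
18	24	F	23.1	16.8	22.2
19	43	F	24.6	28.1	35.5
20	35	F	21.5	20.9	25.0
21	53	F	19.3	54.8	62.6
22	47	F	24.2	14.0	18.6
23	47	F	23.3	21.4	26.0
24	47	M	25.3	41.6	48.7
25	35	M	23.6	12.7	22.1
26	53	M	29.3	30.0	34.7
27	64	M	27.1	41.2	42.7
28	25	M	21.1	24.5	36.4
29	49	M	27.9	23.1	29.1
30	31	M	28.7	15.9	24.2
31	27	M	28.6	14.3	20.6
32	47	M	29.6	16.3	21.0
33	40	M	24.0	55.9	57.8
34	37	M	23.4	33.7	41.9
35	24	M	21.2	25.7	31.4
36	25	M	20.3	25.6	30.5
37	37	M	19.3	15.3	20.7
38	39	M	27.6	32.4	34.7
39	34	M	27.5	41.7	45.1
40	47	M	29.5	26.6	32.7
41	25	M	20.6	24.9	29.7
42	31	M	24.9	9.0	15,2
43	38	M	27.2	17.4	22.5
44	38	M	28.9	11.4	19.9
45	42	M	28.3	28.6	32.1
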