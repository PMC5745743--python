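k	frequency	frequency_pct
58	1	0.70
57	10	7.04
55	1	0.70
54	1	0.70
53	15	10.56
49	24	16.90
48	3	2.11
42	1	0.70
28	13	9.15
27	3	2.11
26	3	2.11
24	4	2.82
23	2	1.41
21	1	0.70
20	1	0.70
19	3	2.11
17	1	0.70
16	2	1.41
15	2	1.41
14	6	4.23
13	2	1.41
12	3	2.11
11	9	6.34
10	12	8.45
9	2	1.41
8	4	2.82
7	5	3.52
4	1	0.70
3	1	0.70
2	5	3.52
1	1	0.70
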