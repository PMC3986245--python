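chromosome	length_mbp	n_snps_evaluated
1	158.31	42331
2	137.01	36802
3	121.39	32464
4	120.63	32187
5	121.18	31541
6	119.42	32799
7	112.60	30247
8	113.35	30611
9	105.67	28856
10	104.28	28134
11	107.27	29252
12	91.12	23880
13	84.21	21206
14	84.03	22441
15	85.23	22408
16	81.69	22284
17	75.15	20390
18	65.98	17803
19	63.96	17246
20	71.95	19697
21	71.57	19360
22	61.29	16807
23	52.46	13848
24	62.54	17182
25	42.82	11795
26	51.64	13957
27	45.40	11938
28	46.24	12032
29	51.18	13280
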