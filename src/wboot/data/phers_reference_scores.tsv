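branch	std	sb	ls	nsb	nls	std_noisy	sb_noisy	ls_noisy	nsb_noisy	nls_noisy
1	35.7	35.7	35.4	35.7	35.2	33.0	33.0	32.6	32.8	32.4
2	100.0	100.0	100.0	100.0	100.0	99.7	99.7	99.7	99.7	99.7
3	54.1	54.3	53.7	55.3	53.4	43.4	43.6	43.0	44.9	42.8
4	100.0	100.0	100.0	100.0	100.0	99.9	99.9	99.9	100.0	99.9
5	91.7	91.9	91.8	92.8	91.7	78.6	79.2	78.7	81.7	78.7
6	47.2	47.4	47.6	48.7	47.9	34.2	34.6	34.6	36.6	34.8
7	54.4	54.7	54.4	56.3	54.5	43.8	44.2	43.8	45.9	43.8
8	22.8	22.7	22.7	22.5	22.7	20.5	20.5	20.4	20.8	20.3
9	100.0	100.0	100.0	100.0	100.0	100.0	100.0	100.0	100.0	100.0
10	100.0	100.0	100.0	100.0	100.0	99.8	99.8	99.8	99.8	99.8
11	98.9	98.9	99.0	99.0	99.0	95.3	95.4	95.5	96.0	95.6
12	99.9	99.9	99.9	99.9	99.9	97.1	97.2	97.0	97.5	97.0
13	68.2	68.3	68.8	69.1	69.2	56.6	56.9	57.6	58.4	58.3
14	99.8	99.8	99.8	99.9	99.9	98.6	98.7	98.7	98.9	98.7
15	23.6	23.9	23.5	25.4	23.5	15.7	16.0	15.8	17.3	16.0
16	45.3	45.6	45.5	47.0	45.6	32.1	32.4	32.4	33.7	32.4
17	5.1	5.1	5.0	5.2	5.0	2.4	2.5	2.5	2.8	2.5
18	66.3	66.8	67.0	68.9	67.4	50.5	51.2	51.0	54.6	51.4
19	63.2	63.2	63.5	63.3	63.7	54.7	54.9	55.0	55.5	55.3
20	5.5	5.5	5.6	5.6	5.7	2.7	2.7	2.7	2.8	2.7
21	26.1	26.2	26.1	26.9	26.2	19.9	20.1	20.0	21.0	20.0
22	2.2	2.2	2.2	2.2	2.3	1.2	1.2	1.2	1.3	1.3
23	33.2	33.5	32.9	34.7	32.7	21.5	21.8	21.2	23.2	21.1
24	21.4	21.5	21.2	22.2	21.2	10.7	10.8	10.6	11.6	10.7
25	100.0	100.0	100.0	100.0	100.0	99.8	99.8	99.7	99.8	99.7
26	69.0	69.2	69.4	70.0	69.5	50.2	50.5	50.4	51.9	50.6
27	77.0	77.3	76.9	78.9	77.0	64.5	64.9	64.5	66.9	64.6
28	31.1	31.1	31.0	31.1	30.9	17.8	17.9	17.8	18.6	17.9
29	49.1	49.1	49.3	49.0	49.3	33.4	33.5	33.5	34.1	33.6
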