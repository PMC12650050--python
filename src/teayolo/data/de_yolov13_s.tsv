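# DE-YOLOv13-S layer specification: id, from, expected params, module, arguments
0	-1	464	Conv	[3, 16, 3, 2]
1	-1	2368	Conv	[16, 32, 3, 2, 1, 2]
2	-1	15940	DynamicConv-C3k2	[32, 64, 1, False, 0.25]
3	-1	9344	Conv	[64, 64, 3, 2, 1, 4]
4	-1	63108	DynamicConv-C3k2	[64, 128, 1, False, 0.25]
5	-1	590596	DynamicConv	[128, 128, 3, 2]
6	-1	174720	A2C2f	[128, 128, 2, True, 4]
7	-1	1180676	DynamicConv	[128, 256, 3, 2]
8	-1	677120	A2C2f	[256, 256, 2, True, 1]
9	[4, 6, 8]	273536	HyperACE	[128, 128, 1, 4, True, True, 0.5, 1, 'both']
10	-1	0	Upsample	[None, 2, 'nearest']
11	9	33280	DownsampleConv	[128]
12	[6, 9]	1	FullPAD_Tunnel	[]
13	[4, 10]	1	FullPAD_Tunnel	[]
14	[8, 11]	1	FullPAD_Tunnel	[]
15	-1	0	Upsample	[None, 2, 'nearest']
16	[-1, 12]	0	Concat	[1]
17	-1	175368	DynamicConv-C3k2	[384, 128, 1, True]
18	[-1, 9]	1	FullPAD_Tunnel	[]
19	17	0	Upsample	[None, 2, 'nearest']
20	[-1, 13]	0	Concat	[1]
21	-1	48264	DynamicConv-C3k2	[256, 64, 1, True]
22	10	8320	Conv	[128, 64, 1, 1]
23	[21, 22]	1	FullPAD_Tunnel	[]
24	-1	36992	Conv	[64, 64, 3, 2]
25	[-1, 18]	0	Concat	[1]
26	-1	150792	DynamicConv-C3k2	[192, 128, 1, True]
27	[-1, 9]	1	FullPAD_Tunnel	[]
28	26	147712	Conv	[128, 128, 3, 2]
29	[-1, 14]	0	Concat	[1]
30	-1	600584	DynamicConv-C3k2	[384, 256, 1, True]
31	[-1, 11]	1	FullPAD_Tunnel	[]
32	23	4	EMCA	[64]
33	27	4	EMCA	[128]
34	31	4	EMCA	[256]
35	[32, 33, 34]	431257	Detect	[3, [64, 128, 256]]
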