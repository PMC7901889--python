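nr	label	hemisphere
1	OP2-3	left
2	24dd	right
3	a24pr	left
4	TE2p	right
5	SFL	right
6	STV	right
7	a47r	left
8	TA2	right
9	a9-46v	left
10	7Pm	right
11	47m	right
12	V3CD	left
13	13l	left
14	A1	right
15	V3A	left
16	PGp	right
17	PeEc	right
18	a9-46v	right
19	TPOJ2	left
20	8C	right
21	p9-46v	right
22	9a	right
23	TE1a	left
24	TE1m	right
25	1	right
26	POS2	left
27	V6A	right
28	PFt	left
29	A4	left
30	V4t	right
31	TGd	right
32	7AL	left
33	MIP	left
34	PoI1	left
35	i6-8	right
36	4	right
37	RSC	right
38	p32	left
39	25	left
40	IFJp	left
41	31a	left
42	VMV2	left
43	A4	right
44	8Ad	left
45	IP2	left
46	TGd	left
47	PFop	right
48	6r	right
49	6a	left
50	TE1a	right
51	H	right
52	POS1	left
53	TE2p	left
54	PeEc	left
55	10d	right
56	STGa	left
57	8BL	right
58	PGs	left
59	PFm	right
60	OFC	right
61	V1	left
62	6ma	left
63	7AL	right
64	MI	left
65	TE2a	right
66	45	left
67	6v	left
68	VMV1	right
69	LIPd	right
70	V8	left
71	p32	right
72	V8	right
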