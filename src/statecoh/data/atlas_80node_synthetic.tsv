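node_id	name	hemisphere	x_mm	y_mm	z_mm
1	Cortical Placeholder 01	Left	-20	68	15
2	Cortical Placeholder 02	Right	25	66	24
3	Cortical Placeholder 03	Left	-25	64	33
4	Cortical Placeholder 04	Right	30	62	42
5	Cortical Placeholder 05	Left	-30	60	51
6	Cortical Placeholder 06	Right	35	58	6
7	Cortical Placeholder 07	Left	-35	56	15
8	Cortical Placeholder 08	Right	40	54	24
9	Cortical Placeholder 09	Left	-40	52	33
10	Cortical Placeholder 10	Right	45	50	42
11	Cortical Placeholder 11	Left	-45	48	51
12	Cortical Placeholder 12	Right	20	46	6
13	Cortical Placeholder 13	Left	-20	44	15
14	Cortical Placeholder 14	Right	25	42	24
15	Cortical Placeholder 15	Left	-25	40	33
16	Cortical Placeholder 16	Right	30	38	42
17	Cortical Placeholder 17	Left	-30	36	51
18	Cortical Placeholder 18	Right	35	34	6
19	Cortical Placeholder 19	Left	-35	32	15
20	Cortical Placeholder 20	Right	40	30	24
21	Cortical Placeholder 21	Left	-40	28	33
22	Cortical Placeholder 22	Right	45	26	42
23	Cortical Placeholder 23	Left	-45	24	51
24	Cortical Placeholder 24	Right	20	22	6
25	Cortical Placeholder 25	Left	-20	20	15
26	Cortical Placeholder 26	Right	25	18	24
27	Cortical Placeholder 27	Left	-25	16	33
28	Cortical Placeholder 28	Right	30	14	42
29	Cortical Placeholder 29	Left	-30	12	51
30	Cortical Placeholder 30	Right	35	10	6
31	Cortical Placeholder 31	Left	-35	8	15
32	Cortical Placeholder 32	Right	40	6	24
33	Cortical Placeholder 33	Left	-40	4	33
34	Cortical Placeholder 34	Right	45	2	42
35	Cortical Placeholder 35	Left	-45	0	51
36	Cortical Placeholder 36	Right	20	-2	6
37	Cortical Placeholder 37	Left	-20	-4	15
38	Cortical Placeholder 38	Right	25	-6	24
39	Cortical Placeholder 39	Left	-25	-8	33
40	Cortical Placeholder 40	Right	30	-10	42
41	Cortical Placeholder 41	Left	-30	-12	51
42	Cortical Placeholder 42	Right	35	-14	6
43	Cortical Placeholder 43	Left	-35	-16	15
44	Cortical Placeholder 44	Right	40	-18	24
45	Cortical Placeholder 45	Left	-40	-20	33
46	Cortical Placeholder 46	Right	45	-22	42
47	Cortical Placeholder 47	Left	-45	-24	51
48	Cortical Placeholder 48	Right	20	-26	6
49	Cortical Placeholder 49	Left	-20	-28	15
50	Cortical Placeholder 50	Right	25	-30	24
51	Cortical Placeholder 51	Left	-25	-32	33
52	Cortical Placeholder 52	Right	30	-34	42
53	Cortical Placeholder 53	Left	-30	-36	51
54	Cortical Placeholder 54	Right	35	-38	6
55	Cortical Placeholder 55	Left	-35	-40	15
56	Cortical Placeholder 56	Right	40	-42	24
57	Cortical Placeholder 57	Left	-40	-44	33
58	Cortical Placeholder 58	Right	45	-46	42
59	Cortical Placeholder 59	Left	-45	-48	51
60	Cortical Placeholder 60	Right	20	-50	6
61	Cortical Placeholder 61	Left	-20	-52	15
62	Cortical Placeholder 62	Right	25	-54	24
63	Cortical Placeholder 63	Left	-25	-56	33
64	Cortical Placeholder 64	Right	30	-58	42
65	Cortical Placeholder 65	Left	-30	-60	51
66	Cortical Placeholder 66	Right	35	-62	6
67	Cortical Placeholder 67	Left	-35	-64	15
68	Cortical Placeholder 68	Right	40	-66	24
69	Cortical Placeholder 69	Left	-40	-68	33
70	Cortical Placeholder 70	Right	45	-70	42
71	Cortical Placeholder 71	Left	-45	-72	51
72	Cortical Placeholder 72	Right	20	-74	6
73	Dentate Nucleus	Left	-12	-52	-24
74	Posterior Lobe	Left	-30	-55	-49
75	Cruseus I	Left	-36	-46	-26
76	Cruseus II	Left	-45	-45	-32
77	Dentate Nucleus	Right	12	-52	-24
78	Posterior Lobe	Right	30	-55	-49
79	Cruseus I	Right	36	-46	-26
80	Cruseus II	Right	45	-45	-32
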