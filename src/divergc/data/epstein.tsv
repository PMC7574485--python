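# Epstein-style coefficient of difference (construction after Epstein 1967, Nature 215:355).
# Generated by scripts/derive_matrices.py; rows = from-residue, columns = to-residue.
aa	A	C	D	E	F	G	H	I	K	L	M	N	P	Q	R	S	T	V	W	Y
A	0	36.34	71.34	73.76	42.71	6.01	75.78	32.93	78.34	32.93	31.33	36.95	10.16	42.33	79.24	35.36	37.21	21.67	68.52	56.66
C	35.6	0	35.37	37.54	49.27	36.8	40.07	43.04	43.5	43.04	42.14	2.36	35.4	14.88	44.71	4.11	3.2	37.77	50.3	35.88
D	70.87	35.36	0	11.51	78.13	71.52	17.75	74.5	24.24	74.5	74.01	35.38	70.71	37.95	26.27	35.66	35.42	71.75	60.59	49.6
E	71.49	35.91	5.76	0	73.97	72.61	6.24	71.71	12.73	71.71	71.46	35.72	70.92	35.43	14.76	36.86	35.67	70.71	51.68	42.33
F	21.36	39.3	72.64	71.54	0	27.37	71.13	4.89	70.85	4.89	5.69	38.8	16.28	36.67	70.8	41.26	38.63	10.52	38.8	35.39
G	12.02	40.82	73.91	78.04	54.73	0	80.88	44.95	84.22	44.95	43.35	42.05	22.18	49.96	85.34	37.4	42.52	33.69	79.06	66.47
H	72.01	36.59	8.88	3.12	72.38	73.38	0	70.94	6.49	70.94	70.83	36.3	71.22	35.41	8.52	37.86	36.21	70.77	47.32	39.25
I	16.47	37.42	71.68	70.96	9.78	22.47	70.77	0	70.72	1	1	37.05	11.38	35.68	70.77	38.97	36.93	5.63	43.75	37.13
K	72.69	37.56	12.12	6.37	71.28	74.32	3.25	70.71	0	70.71	70.72	37.18	71.69	35.74	2.02	39.14	37.05	70.97	43.28	36.89
L	16.47	37.42	71.68	70.96	9.78	22.47	70.77	1	70.72	0	1	37.05	11.38	35.68	70.77	38.97	36.93	5.63	43.75	37.13
M	15.66	37.17	71.55	70.9	11.38	21.67	70.74	1.6	70.75	1.6	0	36.82	10.58	35.58	70.85	38.64	36.71	4.83	44.71	37.65
N	35.76	1.18	35.36	36.81	47.66	37.14	39.01	41.74	42.17	41.74	40.91	0	35.36	12.52	43.3	5.29	1	37	47.94	33.52
P	5.08	35.37	70.71	71.54	32.55	11.09	72.74	22.77	74.54	22.77	21.17	35.36	0	37.71	75.2	35.71	35.38	11.51	60.04	49.13
Q	37.22	7.44	36.02	35.37	40.35	39.51	35.58	36.65	36.87	36.65	36.26	6.26	35.96	0	37.49	11.55	5.84	35.36	35.42	21
R	72.94	37.91	13.13	7.38	71.05	74.64	4.26	70.72	1.01	70.72	70.75	37.5	71.86	35.9	0	39.58	37.36	71.06	42.14	36.37
S	35.36	8.22	36.56	41.03	55.32	35.88	44.53	48.2	48.75	48.2	47.13	10.58	36.74	23.11	50.16	0	11.43	41.38	58.52	44.1
T	35.83	1.6	35.37	36.58	47.1	37.27	38.66	41.29	41.71	41.29	40.49	1	35.36	11.68	42.82	5.71	0	36.76	47.1	32.68
V	10.84	35.97	70.97	70.71	21.04	16.84	70.93	11.26	71.73	11.26	9.66	35.77	5.76	35.39	72.1	36.95	35.71	0	51.19	41.96
W	45.95	25.15	43.07	40.07	36.25	50	38.7	37.63	37.49	37.63	37.91	23.97	42.88	17.71	37.17	29.26	23.55	39.91	0	7.21
Y	41.71	17.94	39.4	37.22	35.36	45.19	36.37	35.81	35.75	35.81	35.94	16.76	39.25	10.5	35.61	22.05	16.34	37.12	14.42	0
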