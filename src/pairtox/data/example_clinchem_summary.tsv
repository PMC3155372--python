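analyte	group	mean	se	n
ALT	V	73.75	3.12	12
ALT	E1	69.17	1.86	12
ALT	E2	72.17	3.14	12
ALT	E3	76.25	3.98	12
ALT	T1	70.08	2.60	12
ALT	T2	69.75	2.01	12
ALT	T3	87.67	7.90	12
ALP	V	290.75	22.68	12
ALP	E1	342.75	23.98	12
ALP	E2	317.75	22.19	12
ALP	E3	319.50	21.83	12
ALP	T1	297.25	15.88	12
ALP	T2	309.83	13.38	12
ALP	T3	335.33	25.56	12
TBA	V	15.95	4.39	12
TBA	E1	14.65	4.07	12
TBA	E2	8.09	1.31	12
TBA	E3	13.05	3.37	12
TBA	T1	9.60	3.72	12
TBA	T2	7.81	1.84	12
TBA	T3	9.37	1.82	12
CREA	V	0.65	0.03	12
CREA	E1	0.73	0.07	12
CREA	E2	0.68	0.02	12
CREA	E3	0.71	0.03	12
CREA	T1	0.68	0.03	12
CREA	T2	0.71	0.02	12
CREA	T3	0.67	0.03	12
BUN	V	14.93	0.35	12
BUN	E1	16.68	0.54	12
BUN	E2	17.65	0.88	12
BUN	E3	19.03	1.67	12
BUN	T1	16.61	0.43	12
BUN	T2	16.97	0.53	12
BUN	T3	17.53	0.47	12
AST	V	110.08	8.28	12
AST	E1	95.25	5.14	12
AST	E2	98.33	4.27	12
AST	E3	97.33	3.77	12
AST	T1	100.75	4.70	12
AST	T2	106.75	6.40	12
AST	T3	122.42	9.12	12
SDH	V	41.85	5.34	12
SDH	E1	46.98	2.51	12
SDH	E2	48.79	3.69	12
SDH	E3	49.44	3.67	12
SDH	T1	47.96	4.66	12
SDH	T2	51.61	4.60	12
SDH	T3	52.53	5.06	12
ALB	V	4.58	0.06	12
ALB	E1	4.54	0.10	12
ALB	E2	4.83	0.07	12
ALB	E3	4.63	0.11	12
ALB	T1	4.57	0.10	12
ALB	T2	4.60	0.09	12
ALB	T3	4.66	0.12	12
TP	V	6.13	0.07	12
TP	E1	6.18	0.08	12
TP	E2	6.21	0.07	12
TP	E3	6.22	0.10	12
TP	T1	6.12	0.05	12
TP	T2	6.19	0.08	12
TP	T3	6.28	0.06	12
TBIL	V	0.14	0.01	12
TBIL	E1	0.25	0.06	12
TBIL	E2	0.14	0.01	12
TBIL	E3	0.15	0.02	12
TBIL	T1	0.13	0.01	12
TBIL	T2	0.15	0.02	12
TBIL	T3	0.18	0.03	12
LDH	V	381.83	36.74	12
LDH	E1	370.75	33.14	12
LDH	E2	368.00	32.52	12
LDH	E3	377.67	33.05	12
LDH	T1	341.50	28.25	12
LDH	T2	462.83	45.11	12
LDH	T3	491.50	53.18	12
5NT	V	32.93	1.78	12
5NT	E1	38.79	2.17	12
5NT	E2	33.17	1.52	12
5NT	E3	32.76	2.04	12
5NT	T1	31.71	2.18	12
5NT	T2	31.48	1.20	12
5NT	T3	33.96	2.74	12
GLDH	V	11.37	1.55	12
GLDH	E1	12.27	2.41	12
GLDH	E2	12.15	2.67	12
GLDH	E3	11.56	1.65	12
GLDH	T1	11.91	1.81	12
GLDH	T2	15.67	2.66	12
GLDH	T3	15.49	2.82	12
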