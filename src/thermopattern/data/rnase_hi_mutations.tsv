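pattern	positions	mutation	delta_t_c	p_value	ave_the	ave_mes
ER	61 E, H 62	H62R	1.3	0.0032	1.782	1.474
LR	74 V, R 75	V74L	3.7	0.0106	1.773	1.492
LE	134 D, E 135	D134L	5.5	0.0007	1.918	1.437
NK	95 K, K 96	K95N	3.2	0.00841	1.951	1.43
SI	52 A, I 53	A52S	-5.8	0.04146	1.579	1.21
SG	10 D, G 11	D10S	9.2	0.0083	1.836	1.63
KI	52 A, I 53	A52K	19.5	0.0398	2.385	1.69
EG	10 D, G 11	D10E	3.8	0.012	1.74	1.376
F1E	8 F, D 10	D10E	3.8	0.0199	1.463	1.242
F1S	8 F, D 10	D10S	9.2	0.0186	1.767	1.284
C2N	41 R, N 44	R41C	1.6	0.0002	1.282	1.052
A2Y	70 D, Y 73	D70A	3.8	0.004	1.647	1.304
E2Y	70 D, Y 73	D70E	1.8	0.0331	1.583	1.12
E2C	10 D, C 13	D10E	3.8	0.008	1.409	1
L2N	49 L, A 52	A52N	-5.9	0.0323	1.617	1.301
L2N	67 L, D 70	D70N	5.5	0.0323	1.617	1.301
V2K	119 E, K 122	E119V	2.7	0.0379	1.635	1.264
N3I	130 N, D 134	D134I	4.6	0.0281	1.667	1.246
N3N	130 N, D 134	D134N	6.4	0.0004	1.658	1.265
N3E	130 N, D 134	D134E	3.1	0.0353	1.757	1.557
N3V	130 N, D 134	D134V	4.1	0.0031	1.541	1.299
N3V	70 D, V 74	D70N	5.5	0.0031	1.541	1.299
R3V	91 K, K 95	K91R	0.5	0.0005	1.554	1.26
V3Y	24 A, Y 28	A24V	3.2	0.0419	1.638	1.136
E3V	48 E, A 52	A52V	7.8	0.0133	2.023	1.852
E3V	64 E, S 68	S68V	1.9	0.0133	2.023	1.852
E3V	70 D, V 74	D70E	1.8	0.0133	2.023	1.852
E3V	94 D, V 98	D94E	-1.2	0.0133	2.023	1.852
Y3L	52 A, L 56	A52Y	-7.6	0.0146	1.636	1.082
C4E	52 A, E 57	A52C	2.5	0.0175	1.4	1
V4Y	68 S, Y 73	S68V	1.9	0.0162	1.528	1.079
N4R	70 D, R 75	D70N	5.5	7.34E-09	1.587	1.155
N4K	130 N, E 135	E135K	-0.8	6.92E-05	2.329	1.678
N4E	52 A, E 57	A52N	-5.9	0.0127	1.664	1.317
Q5N	4 Q, D 10	D10N	6.8	0.0361	1.696	1.16
E5N	64 E, D 70	D70N	5.5	0.00257	1.615	1.36
E5V	10 D, N 16	D10E	3.8	0.0025	1.615	1.3
E5N	94 D, N 100	D94E	-1.2	0.0025	1.615	1.36
R5P	46 R, A 52	A52P	-5.4	0.0499	1.37	1.217
R5P	91 K, P 97	K91R	0.5	0.0499	1.37	1.217
R5I	46 R, A 52	A52I	6.2	0.0299	1.429	1.206
R5Y	46 R, A 52	A52Y	-7.6	0.0176	1.483	1.116
L5P	56 L, H 62	H62P	4.1	0.0009	1.59	1.316
L5P	107 L, Q 113	Q113P	-0.6	0.0009	1.59	1.316
L5L	80 Q, K 86	Q80L	1	0.0001	2.102	1.618
K6E	3 K, D 10	D10E	3.8	0.027	2.111	1.712
K6E	87 K, D 94	D94E	-1.2	0.027	2.111	1.712
N6I	45 N, A 52	A52I	6.2	0.007	1.554	1.2
L6L	67 L, V 74	V74L	3.7	0.0002	2.008	1.684
L6L	52 A, L 59	A52L	4.3	0.0002	2.008	1.684
L6K	80 Q, K 87	Q80L	1	0.0017	1.884	1.47
N6T	45 N, A 52	A52T	-2.7	0.01419	1.491	1.261
I7I	66 I, V 74	V74I	2.4	0.0043	1.618	1.241
I7I	74 V, I 82	V74I	2.4	0.0043	1.618	1.241
L7K	52 A, K 60	A52L	4.3	0.0395	1.67	1.355
L7I	74 V, I 82	V74L	3.7	0.0018	1.704	1.346
K7E	86 K, D 94	D94E	-1.2	0.0045	1.971	1.573
K7K	52 A, K 60	A52K	-19.5	0.0003	2.059	1.632
G7N	126 G, D 134	D134N	6.4	3.92E-07	1.934	1.473
Y7K	52 A, K 60	A52Y	-7.6	0.0202	1.705	1.262
N7T	44 N, A 52	A52T	-2.7	0.0001	1.767	1.215
N7V	16 N, A 24	A24V	3.2	0.0005	1.632	1.311
N7V	44 N, A 52	A52V	7.8	0.0005	1.632	1.311
F7K	52 A, K 60	A52F	-1.5	0.0211	1.636	1.237
R7K	91 K, K 99	K91R	0.5	0.0111	1.446	1.2
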