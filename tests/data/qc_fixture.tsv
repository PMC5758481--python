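# hand-classified QC fixture: 40 kept, 12 undetermined, 8 low_r2
plate	well	gene_id	group	replicate	ct	efficiency	r_squared
1	K00	TF0001	IR64_C	1	20.00	1.85	0.9950
1	K01	TF0002	IR64_S	2	20.37	1.85	0.9950
1	K02	TF0003	IR64Sub1_C	3	20.74	1.85	0.9953
1	K03	TF0004	IR64Sub1_S	1	21.11	1.85	0.9954
1	K04	TF0005	IR64_C	2	21.48	1.85	0.9955
1	K05	TF0006	IR64_S	3	21.85	1.85	0.9956
1	K06	TF0007	IR64Sub1_C	1	22.22	1.85	0.9957
1	K07	TF0008	IR64Sub1_S	2	22.59	1.85	0.9958
1	K08	TF0009	IR64_C	3	22.96	1.85	0.9959
1	K09	TF0010	IR64_S	1	23.33	1.85	0.9960
1	K10	TF0001	IR64Sub1_C	2	23.70	1.85	0.9961
1	K11	TF0002	IR64Sub1_S	3	24.07	1.85	0.9962
1	K12	TF0003	IR64_C	1	24.44	1.85	0.9963
1	K13	TF0004	IR64_S	2	24.81	1.85	0.9964
1	K14	TF0005	IR64Sub1_C	3	25.18	1.85	0.9965
1	K15	TF0006	IR64Sub1_S	1	25.55	1.85	0.9966
1	K16	TF0007	IR64_C	2	25.92	1.85	0.9967
1	K17	TF0008	IR64_S	3	26.29	1.85	0.9968
1	K18	TF0009	IR64Sub1_C	1	26.66	1.85	0.9969
1	K19	TF0010	IR64Sub1_S	2	27.03	1.85	0.9970
1	K20	TF0001	IR64_C	3	27.40	1.85	0.9971
1	K21	TF0002	IR64_S	1	27.77	1.85	0.9972
1	K22	TF0003	IR64Sub1_C	2	28.14	1.85	0.9973
1	K23	TF0004	IR64Sub1_S	3	28.51	1.85	0.9974
1	K24	TF0005	IR64_C	1	28.88	1.85	0.9975
1	K25	TF0006	IR64_S	2	29.25	1.85	0.9976
1	K26	TF0007	IR64Sub1_C	3	29.62	1.85	0.9977
1	K27	TF0008	IR64Sub1_S	1	29.99	1.85	0.9978
1	K28	TF0009	IR64_C	2	30.36	1.85	0.9979
1	K29	TF0010	IR64_S	3	30.73	1.85	0.9980
1	K30	TF0001	IR64Sub1_C	1	31.10	1.85	0.9981
1	K31	TF0002	IR64Sub1_S	2	31.47	1.85	0.9982
1	K32	TF0003	IR64_C	3	31.84	1.85	0.9983
1	K33	TF0004	IR64_S	1	32.21	1.85	0.9984
1	K34	TF0005	IR64Sub1_C	2	32.58	1.85	0.9985
1	K35	TF0006	IR64Sub1_S	3	32.95	1.85	0.9986
1	K36	TF0007	IR64_C	1	33.32	1.85	0.9987
1	K37	TF0008	IR64_S	2	33.69	1.85	0.9988
1	K38	TF0009	IR64Sub1_C	3	34.06	1.85	0.9989
1	K39	TF0010	IR64Sub1_S	1	34.43	1.85	0.9990
1	W00	WATER	IR64_C	1			
1	W01	WATER	IR64_S	1			
1	W02	WATER	IR64Sub1_C	1			
1	W03	WATER	IR64Sub1_S	1			
1	U00	TF0011	IR64_C	1	Undetermined	1.80	0.9800
1	U01	TF0012	IR64_S	1	Undetermined	1.80	0.9990
1	U02	TF0013	IR64Sub1_C	1	Undetermined	1.80	0.9990
1	U03	TF0014	IR64Sub1_S	1	Undetermined	1.80	0.9990
1	U04	TF0015	IR64_C	1	Undetermined	1.80	0.9990
1	C00	TF0016	IR64_C	1	40.00	1.78	0.9900
1	C01	TF0017	IR64_S	1	40.85	1.78	0.9980
1	C02	TF0018	IR64Sub1_C	1	43.20	1.78	0.9980
1	L00	TF0019	IR64_C	1	24.00	1.90	0.9949
1	L01	TF0020	IR64_S	2	25.00	1.90	0.9810
1	L02	TF0021	IR64Sub1_C	3	26.00	1.90	0.9820
1	L03	TF0022	IR64Sub1_S	1	27.00	1.90	0.9830
1	L04	TF0023	IR64_C	2	28.00	1.90	0.9840
1	L05	TF0024	IR64_S	3	29.00	1.90	0.9850
1	L06	TF0025	IR64Sub1_C	1	30.00	1.90	0.9860
1	L07	TF0026	IR64Sub1_S	2	31.00	1.90	0.9870
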