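# Observed vs model-predicted PK parameters, healthy adults, IV infusion.
# Study codes H1-H5 index the source clinical studies (H1: n=12 1000 mg;
# H2: n=24 multidose; H3: n=16 2000 mg short infusions; H4: n=6 2000 mg;
# H5: n=3/48 multidose). anomaly_flag 'duplicated_cl' marks the printed
# 1000 mg cmax block that repeats the CL column values; rows are preserved
# as printed so the published summary statistics reproduce.
study	population	parameter	unit	dose	observed	predicted	printed_ratio	anomaly_flag
H4	healthy	auc_0_inf	ug/mL.h	2000	253.2	224.0	1.13
H5	healthy	auc_0_inf	ug/mL.h	2000	250.0	218.8	1.14
H2	healthy	auc_0_inf	ug/mL.h	2000	271.3	203.4	1.33
H3	healthy	auc_0_inf	ug/mL.h	2000	221.5	236.1	0.93
H3	healthy	auc_0_inf	ug/mL.h	2000	264.7	236.1	1.12
H3	healthy	auc_0_inf	ug/mL.h	2000	219.6	236.0	0.93
H3	healthy	auc_0_inf	ug/mL.h	2000	248.0	236.1	1.05
H2	healthy	auc_0_inf	ug/mL.h	1000	140.2	109.6	1.27
H5	healthy	auc_0_inf	ug/mL.h	1000	150.6	123.0	1.22
H2	healthy	auc_0_inf	ug/mL.h	1000	147.0	103.6	1.41
H1	healthy	auc_0_inf	ug/mL.h	1000	128.6	113.6	1.13
H5	healthy	auc_0_inf	ug/mL.h	1000	173.8	123.0	1.41
H5	healthy	auc_0_inf	ug/mL.h	500	58.6	54.1	1.08
H2	healthy	auc_0_inf	ug/mL.h	500	66.5	51.8	1.28
H5	healthy	auc_0_inf	ug/mL.h	250	34.5	27.3	1.26
H2	healthy	auc_0_inf	ug/mL.h	250	36.4	25.9	1.40
H2	healthy	auc_0_inf	ug/mL.h	125	17.9	13.0	1.37
H2	healthy	auc_0_inf	ug/mL.h	62.5	7.3	6.3	1.15
H4	healthy	cmax	ug/mL	2000	126.3	111.3	1.13
H5	healthy	cmax	ug/mL	2000	118.1	122.3	0.96
H2	healthy	cmax	ug/mL	2000	129.4	85.2	1.51
H3	healthy	cmax	ug/mL	2000	150.6	161.8	0.93
H3	healthy	cmax	ug/mL	2000	173.1	158.6	1.09
H3	healthy	cmax	ug/mL	2000	99.1	154.7	0.64
H3	healthy	cmax	ug/mL	2000	128.4	145.0	0.88
H2	healthy	cmax	ug/mL	1000	7.1	9.1	0.78	duplicated_cl
H5	healthy	cmax	ug/mL	1000	6.6	8.1	0.81	duplicated_cl
H2	healthy	cmax	ug/mL	1000	6.8	9.6	0.70	duplicated_cl
H1	healthy	cmax	ug/mL	1000	7.8	8.8	0.88	duplicated_cl
H5	healthy	cmax	ug/mL	1000	5.8	8.1	0.71	duplicated_cl
H5	healthy	cmax	ug/mL	500	32.0	30.6	1.06
H2	healthy	cmax	ug/mL	500	31.7	22.4	1.41
H5	healthy	cmax	ug/mL	250	16.8	15.3	1.09
H2	healthy	cmax	ug/mL	250	15.8	11.2	1.41
H2	healthy	cmax	ug/mL	125	9.3	5.6	1.66
H2	healthy	cmax	ug/mL	62.5	3.5	3.0	1.16
H4	healthy	cl	L/h	2000	7.9	8.9	0.88
H5	healthy	cl	L/h	2000	8.0	9.1	0.87
H2	healthy	cl	L/h	2000	7.4	9.8	0.75
H3	healthy	cl	L/h	2000	9.0	8.5	1.05
H3	healthy	cl	L/h	2000	8.1	8.5	0.95
H3	healthy	cl	L/h	2000	9.1	8.5	1.07
H3	healthy	cl	L/h	2000	7.6	8.5	0.89
H2	healthy	cl	L/h	1000	7.1	9.1	0.78
H5	healthy	cl	L/h	1000	6.6	8.1	0.81
H2	healthy	cl	L/h	1000	6.8	9.6	0.70
H1	healthy	cl	L/h	1000	7.8	8.8	0.88
H5	healthy	cl	L/h	1000	5.8	8.1	0.71
H5	healthy	cl	L/h	500	8.5	9.2	0.92
H2	healthy	cl	L/h	500	7.5	9.6	0.78
H5	healthy	cl	L/h	250	7.2	9.1	0.79
H2	healthy	cl	L/h	250	6.9	9.6	0.71
H2	healthy	cl	L/h	125	7.0	9.6	0.72
H2	healthy	cl	L/h	62.5	8.6	9.9	0.86
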