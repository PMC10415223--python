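# Observed vs model-predicted PK parameters, chronic kidney disease
# cohorts (1000 mg IV infusion).
study	population	parameter	unit	dose	observed	predicted	printed_ratio	anomaly_flag
R1	severe_ckd	cmax	ug/mL	1000	62.55	68.14	0.91
R1	severe_ckd	cl	L/h	1000	1.46	2.4	0.6
R1	severe_ckd	auc_0_inf	ug/mL.h	1000	684.56	415.32	1.64
R2	moderate_ckd	cmax	ug/mL	1000	69.1	67.3	1.02
R2	moderate_ckd	cl	L/h	1000	3.44	6.57	0.52
R2	moderate_ckd	auc_0_inf	ug/mL.h	1000	290.109	152.14	1.9
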