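# Observed vs model-predicted PK parameters, obese cohort (2000 mg IV).
study	population	parameter	unit	dose	observed	predicted	printed_ratio	anomaly_flag
O1	obese	cl	L/h	2000	8.21	9.16	0.89
O1	obese	cmax	ug/mL	2000	75.98	94.80	0.80
O1	obese	auc_0_inf	ug/mL.h	2000	244.69	220.39	1.10
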