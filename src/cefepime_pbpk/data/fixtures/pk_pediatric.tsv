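# Observed vs model-predicted PK parameters, pediatric cohort (50 mg/kg IV).
# Clearance is weight-normalized (L/h/kg) in the source table.
study	population	parameter	unit	dose	observed	predicted	printed_ratio	anomaly_flag
P1	pediatric	cl	L/h/kg	50/kg	0.18	0.20	0.9
P1	pediatric	cmax	ug/mL	50/kg	164.45	182.78	0.89
P1	pediatric	auc_0_inf	ug/mL.h	50/kg	259.49	255.56	1.01
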