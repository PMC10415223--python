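# Published summary statistics that recompute exactly from the packaged
# observed/predicted tables (tolerance 0.01 on ratio statistics; some
# printed cells are truncated rather than rounded). Summaries that do not
# recompute from their own source table are intentionally absent.
check	statistic	parameter	populations	printed_value
healthy_cl_mean_ratio	mean_ratio	cl	healthy	0.84
healthy_cmax_mean_ratio	mean_ratio	cmax	healthy	1.04
healthy_auc_afe	afe	auc_0_inf	healthy	1.20
healthy_cmax_mean_observed	mean_observed	cmax	healthy	59.34
healthy_cmax_mean_predicted	mean_predicted	cmax	healthy	59.48
healthy_auc_mean_observed	mean_observed	auc_0_inf	healthy	149.42
pediatric_cl_ratio	mean_ratio	cl	pediatric	0.90
severe_ckd_cl_ratio	mean_ratio	cl	severe_ckd	0.60
moderate_ckd_cl_ratio	mean_ratio	cl	moderate_ckd	0.52
moderate_ckd_auc_ratio	mean_ratio	auc_0_inf	moderate_ckd	1.90
renal_cl_afe	afe	cl	severe_ckd+moderate_ckd	0.56
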