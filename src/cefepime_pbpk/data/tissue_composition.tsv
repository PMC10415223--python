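# Fractional tissue composition for partition-coefficient prediction.
# f_ew/f_iw: extracellular/intracellular water; f_nl/f_np: neutral lipid /
# neutral phospholipid (volume fractions); ra_albumin: tissue:plasma albumin
# ratio; ph: intracellular pH. Values compiled from Rodgers & Rowland
# (J Pharm Sci 2006, 95:1238) and Poulin & Theil tissue tables.
tissue	f_ew	f_iw	f_nl	f_np	ra_albumin	ph
adipose	0.135	0.017	0.790	0.0016	0.049	7.0
bone	0.100	0.346	0.017	0.0017	0.100	7.0
brain	0.162	0.620	0.039	0.0015	0.048	7.0
gut	0.282	0.475	0.038	0.0125	0.158	7.0
heart	0.320	0.456	0.014	0.0111	0.157	7.0
kidney	0.273	0.483	0.012	0.0242	0.130	7.0
liver	0.161	0.573	0.014	0.0240	0.086	7.0
lung	0.336	0.446	0.022	0.0128	0.212	7.0
muscle	0.118	0.630	0.010	0.0072	0.064	7.0
pancreas	0.120	0.664	0.041	0.0093	0.060	7.0
skin	0.382	0.291	0.060	0.0044	0.277	7.0
spleen	0.207	0.579	0.0077	0.0113	0.097	7.0
gonads	0.323	0.446	0.0	0.0	0.100	7.0
rest	0.300	0.450	0.050	0.0050	0.100	7.0
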