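# Reference DLVO parameters for the colloid-probe AFM pair series analyzed by
# this package: sulfated cellulose nanocrystals (CNC), sodium polyacrylate
# (PAAS) and CNC/chitosan-oligosaccharide composites (CNC/COS_j, j = wt%
# loading), each measured as probe-sample vs substrate-sample in water.
# Columns: zeta potentials of probe and substrate samples (mV), Debye
# parameter kappa (1/nm), interaction constant Z (nN), and the mean +/- sd
# limit distance (nm) of the measured series.
pair_label	zeta_probe_mV	zeta_substrate_mV	kappa_per_nm	z_nN	limit_distance_nm	limit_distance_sd_nm
PAAS-CNC	-56.6	-38.5	0.03966	11.17e-3	97.23	5.78
CNC-CNC	-37.7	-37.7	0.04125	9.305e-3	94.43	7.56
CNC/COS_1.0-CNC/COS_1.0	-34.6	-34.6	0.03823	8.594e-3	91.59	3.79
CNC/COS_1.5-CNC/COS_1.5	-31.8	-31.8	0.03980	8.402e-3	89.96	7.92
CNC/COS_2.0-CNC/COS_2.0	-29.2	-29.2	0.04416	7.527e-3	83.31	5.17
CNC/COS_2.5-CNC/COS_2.5	-28.0	-28.0	0.05182	6.504e-3	78.48	5.79
CNC/COS_3.0-CNC/COS_3.0	-26.5	-26.5	0.05844	6.277e-3	68.91	6.97
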