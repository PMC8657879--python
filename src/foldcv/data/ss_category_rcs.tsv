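algorithm	category	phi_mean	phi_sd	psi_mean	psi_sd	rcs_mean	rcs_sd	count
dssp4	H	-64.70	11.84	-39.56	11.39	7.273	0.421	412071
dssp4	G	-66.05	34.16	-15.55	29.33	7.523	0.840	51822
dssp4	I	-79.15	25.74	-41.63	20.41	6.516	0.999	7086
dssp4	E	-110.89	42.62	122.38	58.10	2.730	0.966	282196
dssp4	B	-96.98	49.29	122.90	67.45	2.976	0.898	15416
dssp4	T	-39.33	70.25	6.23	51.49	6.923	1.223	151631
dssp4	S	-69.26	73.32	44.16	97.63	4.850	2.166	113536
dssp4	P	-72.33	13.05	144.79	13.85	3.660	0.498	24764
dssp4	C	-82.97	55.81	97.00	83.52	3.835	1.574	218948
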