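feature	p_African	p_EastAsian	p_Hispanic	p_SouthAsian	sign_African	sign_EastAsian	sign_Hispanic	sign_SouthAsian
rs1558902	8.50E-07	2.00E-03	1.20E-08	2.95E-13	1	1	1	1
rs1421085	7.00E-07	2.00E-03	9.50E-09	7.50E-13	1	1	1	1
rs7903146	2.60E-04	0.59	1.95E-06	2.80E-08	1	1	1	1
rs489693	3.05E-02	9.00E-04	4.10E-02	2.30E-09	1	1	1	1
rs2206277	1.15E-06	0.83	3.00E-04	3.35E-03	1	1	1	1
rs12243326	0.71	0.39	2.80E-06	6.50E-06	1	1	1	1
rs987237	3.35E-04	0.95	3.55E-04	1.85E-03	1	1	1	1
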