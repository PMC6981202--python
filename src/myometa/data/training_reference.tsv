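gene	aerobic_healthy_logfc	aerobic_healthy_fdr	aerobic_impaired_logfc	aerobic_impaired_fdr	resistance_healthy_logfc	resistance_healthy_fdr	resistance_impaired_logfc	resistance_impaired_fdr
GUCY1B1	0.26	7.8E-03	0.09	9.7E-01	0.11	2.0E-01	0.02	1.0E+00
KANSL3	-0.09	7.8E-03	-0.04	1.0E+00	0.03	6.9E-01	0.01	1.0E+00
ARNT	-0.10	7.8E-03	-0.02	1.0E+00	0.01	9.3E-01	-0.05	1.0E+00
TOP2B	-0.20	7.1E-03	-0.04	1.0E+00	-0.09	5.5E-02	0.00	1.0E+00
IGIP	-0.19	7.1E-03	-0.03	1.0E+00	-0.10	1.6E-01	-0.03	1.0E+00
COL6A6	0.24	7.9E-02	0.04	8.1E-01	0.36	6.2E-04	-0.03	1.0E+00
APLNR	0.22	3.9E-01	0.18	7.8E-01	0.36	6.5E-03	-0.01	1.0E+00
COL4A2	0.53	2.8E-01	0.33	1.3E-01	0.53	9.7E-04	0.19	1.0E+00
PTGDS	0.09	8.2E-01	0.07	1.0E+00	0.37	5.7E-04	0.03	1.0E+00
ABCG1	-0.07	8.2E-01	-0.03	1.0E+00	0.29	2.5E-03	-0.02	1.0E+00
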