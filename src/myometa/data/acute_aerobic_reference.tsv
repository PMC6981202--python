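gene	mu	fdr
NR4A3	2.99	2.0E-07
EGR1	2.47	3.8E-08
FOS	2.20	5.7E-06
MAFF	2.03	3.0E-05
CYR61	1.84	9.0E-05
GADD45G	-0.70	2.7E-03
CA4	-0.59	4.3E-03
MSTN	-0.42	6.3E-03
ADH1C	-0.39	2.4E-05
LGALSL	-0.39	2.7E-04
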