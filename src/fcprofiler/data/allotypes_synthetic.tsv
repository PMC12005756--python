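name	subclass	backbone_mass_avg	n_glyc_sites	openSS_truncation_delta
IGHG1*01	IgG1	23788.0	1	-2453.6
IGHG1*03	IgG1	23816.1	1	-2453.6
IGHG2*01	IgG2	23756.3	1	-2481.8
IGHG2*02	IgG2	23727.9	1	-2481.8
IGHG3*01	IgG3	24178.2	1	-2512.3
IGHG3*11	IgG3	24206.5	2	-2512.3
IGHG4*01	IgG4	23680.4	1	-2437.9
IGHG4*03	IgG4	23708.6	1	-2437.9
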