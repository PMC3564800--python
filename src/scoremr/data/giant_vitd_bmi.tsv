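rsid	gene	score	beta	ci_low	ci_high	n	weight
rs12785878	DHCR7	synthesis	0.001	-0.01	0.009	123864	1
rs10741657	CYP2R1	synthesis	-0.005	-0.004	0.01	123864	1
rs2282679	GC	metabolism	0.001	-0.011	0.010	123864	1
rs6013897	CYP24A1	metabolism	0.003	-0.008	0.014	123864	1
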