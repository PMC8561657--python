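component	mass_fraction_percent	sd_percent
carbohydrate	32.4	1.6
protein	43.7	1.2
lipid	4.9	0.2
dna	0.2	0.1
rna	0.6	0.1
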