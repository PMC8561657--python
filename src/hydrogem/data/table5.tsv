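metabolite	mean	sd	lower_bound	upper_bound
succinate	0.03	0.01	0.02	0.05
lactate	0.87	0.14	0.72	1.09
ethanol	0.66	0.20	0.47	1.01
formate	1.40	0.30	1.09	1.79
acetate	0.56	0.12	0.42	0.71
h2	0.10	0.06	0.05	0.19
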