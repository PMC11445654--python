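# Density of aqueous sulfuric acid vs. mass fraction, 20 C handbook
# (specific gravity) values as republished in standard chemical
# engineering references. Replaceable via RunConfig.density_table.
mass_fraction_percent,density_g_per_ml
80,1.7272
81,1.7383
82,1.7491
83,1.7594
84,1.7693
85,1.7786
86,1.7872
87,1.7951
88,1.8022
89,1.8087
90,1.8144
91,1.8195
92,1.8240
93,1.8279
94,1.8312
95,1.8337
96,1.8355
97,1.8364
98,1.8361
99,1.8342
100,1.8305
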