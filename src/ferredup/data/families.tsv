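ccs	name	nd	venn_group
c.37.1.10	nitrogenase iron protein-like	0.036	ABEV
c.67.1.4	GABA aminotransferase-like	0.052	ABEV
d.15.4.2	2Fe-2S ferredoxin	0.193	ABE
d.58.1.5	ferredoxin domain of multidomain proteins	0.197	ABEV
d.58.1.1	short-chain ferredoxin	0.287	ABEV
a.127.1.2	HAL/PAL-like	0.321	
a.6.1.7	excisionase-like	0.438	
d.58.1.4	single 4Fe-4S cluster ferredoxin	0.463	
b.163.1.1	Mtd domain-like	0.481	
d.58.1.2	7Fe ferredoxin	0.494	
c.92.2.3	nitrogenase molybdenum-iron protein	0.515	ABE
c.96.1.1	Fe-only hydrogenase	0.527	
d.58.1.3	archaeal ferredoxin	0.554	
d.161.1.1	ADC synthase	0.279	
d.122.1.2	N-terminal domain of DNA gyrase/MutL	0.214	
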