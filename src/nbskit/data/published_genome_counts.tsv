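species	family	estimated_gene_number	nbs_genes
Cucumber_V1	Cucurbitaceae	26682	59
Cucumber_V2	Cucurbitaceae	25600	62
Cucumber_VW	Cucurbitaceae	26548	71
Melon	Cucurbitaceae	27427	80
Watermelon	Cucurbitaceae	23440	45
Peach	Rosaceae	28524	437
Mei	Rosaceae	31390	475
Strawberry	Rosaceae	34809	346
Pear	Rosaceae	42812	617
Apple	Rosaceae	57386	1303
Cannabis	Cannabaceae	30000	234
Poplar	Salicaceae	45654	402
Grape	Vitaceae	30434	341
Soybean	Leguminosae	46430	392
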