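species	klass	subtype	count
Cucumber_V1	TIR	XN	1
Cucumber_V1	TIR	XNL	9
Cucumber_V1	TIR	TN	5
Cucumber_V1	TIR	TNL	12
Cucumber_V1	nonTIR	CN	4
Cucumber_V1	nonTIR	CNL	12
Cucumber_V1	nonTIR	XN	6
Cucumber_V1	nonTIR	XNL	10
Cucumber_V2	TIR	XN	0
Cucumber_V2	TIR	XNL	8
Cucumber_V2	TIR	TN	3
Cucumber_V2	TIR	TNL	15
Cucumber_V2	nonTIR	CN	1
Cucumber_V2	nonTIR	CNL	16
Cucumber_V2	nonTIR	XN	3
Cucumber_V2	nonTIR	XNL	16
Cucumber_VW	TIR	XN	4
Cucumber_VW	TIR	XNL	6
Cucumber_VW	TIR	TN	2
Cucumber_VW	TIR	TNL	21
Cucumber_VW	nonTIR	CN	2
Cucumber_VW	nonTIR	CNL	17
Cucumber_VW	nonTIR	XN	7
Cucumber_VW	nonTIR	XNL	12
Melon	TIR	XN	2
Melon	TIR	XNL	8
Melon	TIR	TN	4
Melon	TIR	TNL	21
Melon	nonTIR	CN	5
Melon	nonTIR	CNL	14
Melon	nonTIR	XN	12
Melon	nonTIR	XNL	14
Watermelon	TIR	XN	0
Watermelon	TIR	XNL	5
Watermelon	TIR	TN	3
Watermelon	TIR	TNL	12
Watermelon	nonTIR	CN	0
Watermelon	nonTIR	CNL	8
Watermelon	nonTIR	XN	7
Watermelon	nonTIR	XNL	10
Peach	TIR	XN	10
Peach	TIR	XNL	23
Peach	TIR	TN	15
Peach	TIR	TNL	133
Peach	nonTIR	CN	9
Peach	nonTIR	CNL	112
Peach	nonTIR	XN	27
Peach	nonTIR	XNL	101
Mei	TIR	XN	10
Mei	TIR	XNL	27
Mei	TIR	TN	32
Mei	TIR	TNL	155
Mei	nonTIR	CN	22
Mei	nonTIR	CNL	104
Mei	nonTIR	XN	28
Mei	nonTIR	XNL	93
Strawberry	TIR	XN	6
Strawberry	TIR	XNL	15
Strawberry	TIR	TN	15
Strawberry	TIR	TNL	117
Strawberry	nonTIR	CN	9
Strawberry	nonTIR	CNL	94
Strawberry	nonTIR	XN	19
Strawberry	nonTIR	XNL	71
Pear	TIR	XN	22
Pear	TIR	XNL	54
Pear	TIR	TN	25
Pear	TIR	TNL	241
Pear	nonTIR	CN	23
Pear	nonTIR	CNL	152
Pear	nonTIR	XN	24
Pear	nonTIR	XNL	76
Apple	TIR	XN	88
Apple	TIR	XNL	184
Apple	TIR	TN	91
Apple	TIR	TNL	301
Apple	nonTIR	CN	83
Apple	nonTIR	CNL	270
Apple	nonTIR	XN	81
Apple	nonTIR	XNL	205
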