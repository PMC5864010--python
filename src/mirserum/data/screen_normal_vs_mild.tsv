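MicroRNA Name	dCt	FC	p value	sampling p
hsa-miR-589-3p	5.236	0.027	0.0021	0.0006
hsa-miR-542-5p	4.701	0.038	0.0022	0.0014
hsa-miR-886-5p	4.305	0.051	0.00446	0.0020
hsa-miR-550-5p	3.896	0.067	0.0055	0.0030
hsa-miR-143-3p	-4.725	26.454	0.0070	0.0033
hsa-miR-520d-5p	3.311	0.101	0.0105	0.0051
hsa-miR-329-3p	3.416	0.094	0.0121	0.0057
hsa-miR-654-5p	3.101	0.117	0.0136	0.0088
hsa-miR-509-3p	3.310	0.101	0.0152	0.0104
hsa-miR-185-3p	3.425	0.093	0.0182	0.0130
hsa-miR-510-5p	2.961	0.128	0.0180	0.0137
hsa-miR-301b-3p	2.770	0.147	0.0250	0.0188
hsa-miR-99a-5p	-2.949	7.722	0.0366	0.0335
hsa-miR-202-3p	2.466	0.181	0.0393	0.0358
hsa-miR-184	2.431	0.185	0.0430	0.0384
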