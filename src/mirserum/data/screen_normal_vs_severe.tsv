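MicroRNA Name	dCt	FC	p value	sampling p
hsa-miR-589-3p	5.236	0.027	0.0034	0.0007
hsa-miR-185-3p	4.449	0.046	0.0021	0.0008
hsa-miR-526b-5p	4.165	0.056	0.0046	0.0017
hsa-miR-30b*-3p	4.380	0.048	0.0042	0.0017
hsa-miR-9-5p	3.705	0.077	0.0051	0.0018
hsa-miR-200a-3p	-3.585	11.999	0.0052	0.0019
hsa-miR-886-5p	4.305	0.051	0.0051	0.0024
hsa-miR-520d-5p	3.311	0.1011	0.0072	0.0031
hsa-miR-654-5p	3.101	0.117	0.0087	0.0038
hsa-miR-493-3p	3.086	0.118	0.0098	0.0043
hsa-miR-933	-3.849	14.414	0.0101	0.0047
hsa-miR-663a	-4.294	19.621	0.0088	0.0051
hsa-miR-873-5p	-2.886	7.392	0.0113	0.0053
hsa-miR-377-3p	2.875	0.136	0.0117	0.0064
hsa-miR-510-5p	2.961	0.128	0.0123	0.0075
hsa-miR-95-3p	2.7001	0.154	0.0179	0.0119
hsa-miR-143-3p	-4.115	17.333	0.0190	0.0124
hsa-miR-708-5p	3.310	0.101	0.0231	0.0136
hsa-miR-365a-3p	-4.525	23.020	0.0218	0.0150
hsa-miR-202-3p	2.465	0.181	0.0272	0.0232
hsa-miR-452-5p	2.680	0.156	0.0319	0.0248
hsa-miR-490-3p	2.880	0.136	0.0374	0.0299
hsa-miR-760	3.536	0.086	0.0356	0.0336
hsa-miR-376b-3p	2.385	0.191	0.0450	0.0367
hsa-miR-184	2.201	0.218	0.0448	0.0389
hsa-miR-27b-3p	-1.916	3.774	0.0486	0.0414
hsa-miR-362-5p	-2.235	4.708	0.0498	0.0438
hsa-miR-382-5p	1.9611	0.257	0.0489	0.0448
hsa-miR-502-5p	3.755	0.074	0.0496	0.0494
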