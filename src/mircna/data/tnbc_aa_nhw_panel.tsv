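mirna	cytoband	start	stop	cna	expression	log2fc	p_value
hsa-miR-205-5p	1q32.2	209432133	209432242	gain	up	2.925	7.82E-05
hsa-miR-216a-5p	2p16.1	55988950	55989059	gain	up	1.059	7.65E-07
hsa-miR-4431	2p16.2	52702522	52702615	gain	up	1.220	2.42E-04
hsa-miR-548ad-3p	2p25.1	35471405	35471486	gain	up	0.690	8.22E-04
hsa-miR-15b-5p	3q25.33	160404588	160404685	gain	up	2.202	2.97E-04
hsa-miR-1263	3q26.1	164171471	164171556	gain	up	1.375	2.69E-04
hsa-miR-28-5p	3q28	188688781	188688866	gain	up	1.655	2.28E-05
hsa-miR-580-3p	5p13.2	36147892	36147988	gain	up	1.526	7.47E-07
hsa-miR-4458	5p15.31	8460925	8460999	gain	up	2.224	4.79E-07
hsa-miR-3934-5p	6p21.31	33698128	33698234	gain	up	0.754	2.99E-04
hsa-miR-4284	7q11.23	73711317	73711397	gain	up	1.981	4.65E-06
hsa-miR-93-5p	7q22.1	100093768	100093847	gain	up	2.230	1.88E-04
hsa-miR-182-5p	7q32.2	129770383	129770492	gain	up	2.026	7.77E-05
hsa-miR-183-5p	7q32.2	129774905	129775014	gain	up	1.717	7.54E-05
hsa-miR-599	8q22.2	99536636	99536730	gain	up	1.755	7.81E-06
hsa-miR-661	8q24.3	143945191	143945279	gain	up	1.307	7.37E-04
hsa-miR-614	12p13.1	12915829	12915918	gain	up	1.021	4.31E-04
hsa-miR-200c-3p	12p13.31	6963699	6963766	gain	up	2.465	6.10E-04
hsa-miR-17-5p	13q31.3	91350605	91350688	gain	up	1.990	3.21E-04
hsa-miR-18a-5p	13q31.3	91350751	91350821	gain	up	1.160	3.60E-05
hsa-miR-940	16p13.3	2271747	2271840	loss	down	-1.118	2.05E-04
hsa-miR-1225-3p	16p13.3	2090195	2090284	loss	down	-1.953	1.29E-07
hsa-miR-23a-3p	19p13.12	13836587	13836659	gain	up	2.334	9.01E-05
hsa-miR-769-5p	19q13.32	46018932	46019049	gain	up	1.355	2.46E-06
hsa-miR-150-5p	19q13.33	49500762	49500873	gain	up	2.730	6.20E-04
hsa-miR-532-5p	Xp11.23	50003148	50003238	loss	down	-1.875	9.57E-08
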