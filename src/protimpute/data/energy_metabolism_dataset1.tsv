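gene_id	predicted_LL	rna_LL	protein_LL	predicted_LS	rna_LS	protein_LS	predicted_FL	rna_FL	protein_FL	description
DVU0918	10.08	2315.20	x	2.46	416.75	x	5.71	1668.90	x	ATP synthase F0, A subunit (atpB)
DVU0779	6.55	2505.40	x	3.30	497.75	x	5.08	1397.10	x	ATP synthase F0, B subunit
DVU0780	6.62	3156.20	x	3.88	1050.10	x	5.81	2352.70	x	ATP synthase F0, B subunit
DVU0917	7.60	6086.50	x	3.85	1234.90	x	10.85	5944.40	x	ATP synthase F0, C subunit (atpE)
DVU0920	3.80	1590.50	x	3.59	947.88	x	5.75	1198.20	x	ATP synthase protein I (atpI)
DVU0777	39.24	2535.00	20.00	8.40	369.95	8.00	17.76	735.68	17.33	ATP synthase, F1 alpha subunit (atpA)
DVU0775	50.11	2228.60	49.33	23.76	711.53	30.33	39.80	1198.40	38.33	ATP synthase, F1 beta subunit (atpD)
DVU0778	4.25	1974.50	x	2.71	374.22	x	3.21	714.57	x	ATP synthase, F1 delta subunit (atpH)
DVU0774	4.85	2043.70	x	2.32	336.55	x	4.14	1113.40	x	ATP synthase, F1 epsilon subunit (atpC)
DVU0702	2.62	288.72	x	2.20	372.82	x	2.05	417.68	1.00	Cytochrome c family protein
DVU0922	1.69	66.60	x	1.85	149.38	x	1.49	149.52	x	Cytochrome c family protein
DVU1288	3.44	1172.20	x	2.06	298.10	x	3.12	826.90	x	Cytochrome c family protein
DVU2483	10.24	456.23	x	3.24	284.22	x	7.36	490.33	x	Cytochrome c family protein
DVU2484	5.06	575.50	x	2.39	277.35	x	4.63	665.95	x	Cytochrome c family protein
DVU2791	4.77	683.65	x	2.61	530.00	x	3.32	667.05	x	Cytochrome c family protein
DVU3107	15.10	1009.30	2.33	2.98	177.15	1.67	13.04	1026.30	3.00	Cytochrome c family protein
DVU3144	5.58	297.85	x	3.58	142.45	x	8.24	342.52	x	Cytochrome c family protein
DVU0625	30.20	1822.80	x	14.80	764.85	x	16.61	2467.50	x	Cytochrome c nitrite reductase, catalytic subunit NfrA
DVU1815	4.91	439.87	x	2.98	324.93	x	7.12	833.88	x	Cytochrome c oxidase, subunit I
DVU1812	4.42	304.57	x	2.72	215.70	x	4.63	335.70	x	Cytochrome c oxidase, subunit II
DVU1814	2.53	397.35	x	2.31	283.90	x	3.80	898.67	x	Cytochrome c oxidase, subunit III
DVU2809	3.11	447.42	x	2.32	395.15	x	2.10	601.50	x	Cytochrome c3
DVU3171	13.24	3937.00	3.33	5.24	966.25	x	11.82	5719.20	1.00	Cytochrome c3
DVU2524	1.77	114.95	x	2.08	135.07	x	1.61	170.70	x	Cytochrome c3,
DVU3041	3.03	894.60	x	2.62	713.10	x	2.73	684.27	x	Cytochrome c553
DVU1817	6.34	2280.00	11.67	7.26	1858.20	3.33	9.61	5400.20	12.00	Cytochrome c-553 (cyf)
DVU1048	2.31	255.07	x	2.14	243.58	x	1.53	185.47	x	Cytochrome c-type biogenesis protein CcmB (ccmB)
DVU1047	2.87	435.45	x	2.06	284.87	x	2.23	259.25	x	Cytochrome c-type biogenesis protein CcmC (ccmC)
DVU1051	3.30	915.92	x	3.59	769.45	x	4.19	732.07	x	Cytochrome c-type biogenesis protein CcmE (ccmE)
DVU1050	7.42	581.02	x	4.03	408.20	x	6.27	463.25	x	Cytochrome c-type biogenesis protein CcmF (ccmF)
DVU3271	35.79	8217.80	x	12.15	2295.10	x	11.38	6954.00	x	Cytochrome d ubiquinol oxidase, subunit I (cydA)
DVU3270	18.09	3877.70	x	5.50	1145.70	x	13.90	3897.10	x	Cytochrome d ubiquinol oxidase, subunit II (cydB)
DVU0434	1.28	177.22	x	2.79	168.72	x	5.13	468.00	x	Ech hydrogenase, subunit EchA
DVU0433	2.10	217.82	x	2.34	166.95	x	2.84	422.28	x	Ech hydrogenase, subunit EchB
DVU0432	2.11	222.90	x	2.24	133.13	x	3.12	595.60	x	Ech hydrogenase, subunit EchC
DVU0431	2.20	303.27	x	2.03	215.73	x	3.30	778.70	x	Ech hydrogenase, subunit EchD
DVU0430	2.68	259.00	x	2.52	199.20	x	4.61	685.78	x	Ech hydrogenase, subunit EchE
DVU0429	2.24	239.03	x	2.07	201.57	x	2.05	405.30	x	Ech hydrogenase, subunit EchF
DVU2824	0.90	124.20	x	3.54	106.78	x	9.30	102.10	x	Formate acetyltransferase
DVU2272	1.05	97.08	x	3.69	113.33	1.00	16.21	160.88	x	Formate acetyltransferase
DVU0578	2.11	154.12	x	2.23	217.48	x	2.03	247.52	x	Formate dehydrogenase accessory protein FdhD
DVU0577	2.56	237.93	x	2.29	148.02	x	1.97	513.40	x	Formate dehydrogenase formation protein FdhE
DVU2810	3.39	423.00	x	2.27	312.02	x	2.47	510.12	x	Formate dehydrogenase formation protein FdhE
DVU0588	0.92	35.70	x	2.65	35.25	x	1.26	79.03	x	Formate dehydrogenase, beta subunit
DVU2481	2.39	227.43	x	2.37	304.92	x	2.35	399.82	x	Formate dehydrogenase, beta subunit
DVU2811	3.22	335.33	x	2.52	181.45	x	3.13	435.95	x	Formate dehydrogenase, beta subunit
DVU2288	2.68	781.45	x	2.24	412.85	x	1.39	139.17	x	Hydrogenase, CooL subunit
DVU2286	16.67	308.33	x	3.29	138.72	x	6.08	81.55	x	Hydrogenase, CooM subunit
DVU2290	2.84	703.22	3.00	2.10	316.45	3.00	NA	NA	x	Hydrogenase, CooU subunit
DVU2289	3.92	823.18	x	2.14	553.33	x	2.36	319.80	x	Hydrogenase, CooX subunit
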