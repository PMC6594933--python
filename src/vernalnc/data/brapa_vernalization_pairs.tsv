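lnc_id	lnc_category	lnc_direction	lnc_fpkm_nv	lnc_fpkm_v	lnc_log2_fc	mrna_gene_id	mrna_fpkm_nv	mrna_fpkm_v	mrna_log2_fc	mrna_direction
MSTRG.2161	NAT	up	0.49	4.04	3.05	Bra021594	18.91	69.48	1.88	up
MSTRG.10467	NAT	up	0.88	6.04	2.77	Bra004446	0.89	2.93	1.71	up
MSTRG.4795	NAT	up	1.83	12.20	2.74	Bra029292	1.35	58.72	5.44	up
MSTRG.23036	NAT	up	1.05	4.86	2.21	Bra007504	4.02	10.18	1.34	up
MSTRG.3577	NAT	up	0.93	3.94	2.09	Bra039752	7.26	11.98	0.72	up
MSTRG.5770	NAT	up	0.45	1.64	1.87	Bra006862	1.08	2.25	1.05	up
MSTRG.20836	NAT	up	0.88	3.03	1.78	Bra037845	2.57	26.69	3.38	up
MSTRG.8355	NAT	up	1.45	4.71	1.70	Bra024126	43.12	197.36	2.19	up
MSTRG.15105	NAT	up	2.80	7.26	1.37	Bra025323	7.79	19.67	1.34	up
MSTRG.7460	NAT	up	5.92	16.90	1.51	Bra001846	31.46	6.81	-2.21	down
MSTRG.21908	NAT	up	8.75	24.69	1.50	Bra029572	7.07	0.93	-2.92	down
MSTRG.2598	NAT	down	7.53	4.08	-0.88	Bra028893	14.69	1.71	-3.10	down
MSTRG.17623	NAT	down	9.66	3.21	-1.59	Bra016256	41.96	10.07	-2.06	down
MSTRG.7151	NAT	down	9.17	1.94	-2.24	Bra001390	44.61	7.40	-2.59	down
MSTRG.25903	NAT	down	4.79	0.86	-2.48	Bra009516	9.37	3.51	-1.42	down
MSTRG.17356	NAT	down	8.32	1.39	-2.58	Bra004009	34.78	9.35	-1.89	down
MSTRG.17011	NAT	down	2.65	0.29	-3.19	Bra003511	4.48	0.31	-3.85	down
MSTRG.5884	NAT	down	16.78	1.66	-3.34	Bra029099	11.87	5.02	-1.24	down
MSTRG.14559	incRNA	up	119.61	251.26	1.07	Bra024395	1.54	17.65	3.52	up
MSTRG.1863	incRNA	down	10.94	3.29	-1.73	Bra023842	4.73	0.38	-3.65	down
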