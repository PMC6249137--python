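snp_id	gene	effect_allele	eaf	or_overall	or_sun_sensitive	or_not_sensitive	is_mc1r	pathways
D84E	MC1R	var	0.01	2.2	1.7	3.0	true	pigmentation
V60L	MC1R	var	0.12	1.4	1.2	1.7	true	pigmentation
V92M	MC1R	var	0.09	1.3	1.15	1.55	true	pigmentation
I155T	MC1R	var	0.01	2.4	1.8	3.2	true	pigmentation
R151C	MC1R	var	0.07	2.6	1.9	3.5	true	pigmentation
R160W	MC1R	var	0.06	1.9	1.5	2.5	true	pigmentation
R163Q	MC1R	var	0.04	1.2	1.1	1.4	true	pigmentation
D294H	MC1R	var	0.02	2.3	1.75	3.1	true	pigmentation
rs7412746	ARNT	T	0.45	1.12	NA	NA	false	pigmentation
rs62211989	ASIP	G	0.1	1.65	NA	NA	false	pigmentation
rs7274597	ASIP	A	0.08	1.35	NA	NA	false	pigmentation
rs1393350	TYR	A	0.28	1.25	NA	NA	false	pigmentation
syn_TYR_1	TYR	C	0.2	1.1	NA	NA	false	pigmentation
rs12527588	CDKAL1	T	0.06	1.3	NA	NA	false	pigmentation
rs7776158	CDKAL1	C	0.35	1.2	NA	NA	false	pigmentation
rs16953002	FTO	A	0.18	1.2	NA	NA	false	pigmentation
rs700635	CASP8	C	0.32	1.15	NA	NA	false	pigmentation
rs3219090	PARP1	G	0.3	1.25	NA	NA	false	pigmentation
syn_SLC45A2_1	SLC45A2	G	0.03	1.4	NA	NA	false	pigmentation
syn_SLC45A2_2	SLC45A2	T	0.05	1.2	NA	NA	false	pigmentation
syn_SLC45A2_3	SLC45A2	A	0.1	1.1	NA	NA	false	pigmentation
syn_OCA2_1	OCA2	C	0.15	1.15	NA	NA	false	pigmentation
syn_OCA2_2	OCA2	G	0.22	1.1	NA	NA	false	pigmentation
syn_IRF4_1	IRF4	T	0.17	1.2	NA	NA	false	pigmentation
syn_IRF4_2	IRF4	C	0.3	1.1	NA	NA	false	pigmentation
rs6949072	AGR3	A	0.4	1.15	NA	NA	false	pigmentation,nevus
rs34585474	AGR3	G	0.35	1.18	NA	NA	false	pigmentation,nevus
rs7781130	AGR3	T	0.12	1.25	NA	NA	false	pigmentation,nevus
rs132985	PLA2G6	C	0.4	1.15	NA	NA	false	pigmentation,nevus
syn_PLA2G6_1	PLA2G6	T	0.25	1.1	NA	NA	false	pigmentation,nevus
rs149617956	MITF	A	0.008	2.2	NA	NA	false	pigmentation,nevus
rs76699054	CCND1	T	0.05	1.35	NA	NA	false	nevus
syn_CCND1_1	CCND1	G	0.2	1.12	NA	NA	false	nevus
rs113908778	RAD23B	A	0.02	1.45	NA	NA	false	nevus
rs4436178	RAD23B	C	0.06	1.3	NA	NA	false	nevus
syn_RAD23B_1	RAD23B	T	0.25	1.1	NA	NA	false	nevus
rs3731217	CDKN2A	T	0.12	1.25	NA	NA	false	nevus,telomere_senescence_other
rs1801516	ATM	A	0.13	1.2	NA	NA	false	nevus,telomere_senescence_other
rs2736100	TERT	C	0.49	1.2	NA	NA	false	telomere_senescence_other
syn_TERT_1	TERT	G	0.3	1.1	NA	NA	false	telomere_senescence_other
rs2487999	OBFC1	T	0.11	1.3	NA	NA	false	telomere_senescence_other
syn_OBFC1_1	OBFC1	C	0.2	1.12	NA	NA	false	telomere_senescence_other
rs45430	MX2	G	0.4	1.2	NA	NA	false	telomere_senescence_other
rs6517661	MX2	A	0.35	1.12	NA	NA	false	telomere_senescence_other
syn_MX2_1	MX2	T	0.15	1.1	NA	NA	false	telomere_senescence_other
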