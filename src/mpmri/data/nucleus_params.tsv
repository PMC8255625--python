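abbrev	full_name	group	qsm_mean	qsm_sd	na_mean	na_sd	mtr_mean	mtr_sd	t1_mean	t1_sd
NC	Nucleus caudatus	extrapyramidal	0.0289	0.0230	53.1	4.2	19.4	2.6	1709	44
RN	Red nucleus	extrapyramidal	0.0651	0.0153	38.9	1.2	26.1	0.6	1167	25
Pal	Globus pallidus	extrapyramidal	0.0851	0.0095	38.8	2.0	23.0	1.7	1237	15
Put	Putamen	extrapyramidal	0.0255	0.0086	47.1	2.9	18.5	0.8	1614	40
NAC	Nucleus accumbens	limbic	-0.0148	0.0144	48.5	2.7	22.3	1.9	1602	31
LC	Locus coeruleus	aras	0.0163	0.0056	80.3	7.3	20.2	2.1	1725	79
BNST	Bed nucleus of stria terminalis	limbic	-0.0319	0.0177	47.5	4.8	21.0	1.9	1702	54
SN	Substantia nigra	extrapyramidal	0.0901	0.0174	37.2	2.8	23.3	0.6	1292	16
STN	Subthalamic nucleus	extrapyramidal	0.0747	0.0188	35.2	2.5	25.4	1.3	1141	27
VTA	Ventral tegmental area	aras	0.0228	0.0120	43.0	2.8	24.5	0.8	1308	40
CP	Cerebral peduncle	fiber_tract	-0.0374	0.0116	40.0	3.7	25.2	1.0	1153	38
DRN	Dorsal raphe nucleus	aras	-0.0110	0.0076	53.7	3.6	22.0	1.4	1589	63
LGB	Lateral geniculate body	epi_thalamic	0.0077	0.0069	45.8	3.7	19.2	1.5	1397	48
MB	Mammillary body	limbic	0.0341	0.0097	64.6	7.3	21.3	2.0	1477	44
MGB	Medial geniculate body	epi_thalamic	0.0337	0.0190	57.2	5.5	21.3	1.1	1513	44
PPN	Pedunculopontine nucleus	aras	0.0021	0.0097	46.4	4.5	24.1	1.2	1370	21
Pul	Pulvinar	epi_thalamic	0.0456	0.0094	49.8	4.7	20.6	1.4	1510	44
VP	Ventral pallidum	limbic	0.0943	0.0151	40.9	2.2	24.3	3.0	1270	34
HB	Habenula	epi_thalamic	0.0244	0.0210	92.9	6.8	24.0	1.4	1397	53
ML	Medial lemniscus	fiber_tract	-0.0208	0.0056	46.4	3.4	22.6	1.5	1312	30
NBM	Nucleus basalis Meynert	limbic	-0.0180	0.0184	46.7	4.5	20.5	3.3	1487	95
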