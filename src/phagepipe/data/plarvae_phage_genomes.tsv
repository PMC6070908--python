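phage	genome_length_bp	packaging_strategy	dtr_len	gc_percent	n_genes	genes_per_kbp	coding_fraction_pct	cluster
Pagassa	40035	cos3	0	42.0	66	1.65	91.2	Fern
Honeybear	40054	cos3	0	41.9	66	1.65	91.2	Fern
Toothless	38832	cos3	0	42.0	64	1.65	91.0	Fern
Tadhana	37880	cos3	0	42.1	61	1.61	91.2	Fern
Fern	37995	cos3	0	41.9	65	1.71	91.5	Fern
Willow	37994	cos3	0	41.9	65	1.71	91.5	Fern
Lucielle	37947	cos3	0	41.8	65	1.71	91.3	Fern
Saudage	37962	cos3	0	41.9	65	1.71	91.6	Fern
BN12	39485	cos3	0	42.6	69	1.75	92.4	Fern
Kawika	40769	cos3	0	41.6	71	1.74	89.8	Fern
Kiel007	37985	cos3	0	41.8	62	1.63	91.7	Fern
Redbud	37971	cos3	0	41.8	62	1.63	91.4	Fern
Rani	37990	cos3	0	41.8	62	1.63	91.8	Fern
Eltigre	38675	cos3	0	41.4	67	1.73	92.1	Fern
HB10c2	35644	cos3	0	41.8	58	1.63	91.2	Fern
Arcticfreeze	38518	cos3	0	41.5	66	1.71	90.6	Fern
DevRi	38520	cos3	0	41.5	66	1.71	90.6	Fern
Bloom	38519	cos3	0	41.5	66	1.71	90.6	Fern
Jacopo	38526	cos3	0	41.6	66	1.71	90.6	Fern
Genki	38540	cos3	0	40.5	66	1.71	90.6	Fern
Gryphonian	38541	cos3	0	40.5	66	1.71	90.6	Fern
Likha	39778	cos3	0	41.3	64	1.61	92.2	Fern
phiIBB_Pl23	41294	cos3	0	48.1	65	1.57	89.5	Fern
Yerffej	43126	cos3	0	40.6	69	1.60	90.4	Fern
Sitara	43724	cos3	0	41.6	75	1.72	89.6	Fern
Diva	37246	cos3	0	42.1	64	1.72	89.6	Fern
Shelly	41152	cos3	0	41.5	71	1.73	89.7	Fern
Xenia	41149	cos3	0	41.5	71	1.73	89.9	Fern
Leyra	42276	cos3	0	41.4	69	1.63	90.9	Fern
PBL1c	40611	cos3	0	41.2	74	1.82	90.5	Fern
Harrison	44247	cos3	0	40.2	78	1.76	91.6	Harrison
Paisley	44172	cos3	0	40.0	78	1.77	91.4	Harrison
Diane	45653	cos3	0	43.7	84	1.84	94.5	Vegas
Vadim	45653	cos3	0	43.7	84	1.84	94.5	Vegas
Vegas	45653	cos3	0	43.7	84	1.84	94.5	Vegas
Hayley	44256	cos3	0	43.5	82	1.85	94.2	Vegas
Dragolir	41131	cos3	0	44.0	65	1.58	92.3	Vegas
LincolnB	40437	cos3	0	42.3	72	1.78	93.2	Vegas
Wanderer	40448	cos3	0	42.4	72	1.78	93.2	Vegas
Lily	44952	cos5	0	42.7	75	1.67	90.0	Lily
Ash	56468	dtr	377	48.0	88	1.56	90.9	Halcyone
Ley	56465	dtr	377	48.0	88	1.56	90.9	Halcyone
C7Cdelta	55774	dtr	377	48.0	87	1.56	90.9	Halcyone
Halcyone	55560	dtr	377	48.6	90	1.62	91.8	Halcyone
Heath	55560	dtr	377	48.6	90	1.62	91.8	Halcyone
Scottie	55990	dtr	377	48.6	91	1.63	91.2	Halcyone
Unity	50316	dtr	378	49.1	78	1.55	92.5	Halcyone
Tripp	54439	dtr	378	48.3	90	1.65	89.6	Halcyone
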