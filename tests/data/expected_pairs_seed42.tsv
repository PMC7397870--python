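transcript_id	gene_id	saug_pos	fdaug_pos	frame	spacer_nt	saug_context	fd_context	saug_tie	fd_tie	fd_stop_nt	fd_terminated
T00000	G00000	53	268	2	215	AAGACAAUGGU	CUCCACAUGGC	81.6	60.0	75	True
T00001	G00001	61	226	0	165	AGUUGUAUGAA	UGUAUCAUGCA	17.3502	35.942400000000006	171	True
T00002	G00002	79	126	2	47	GCCGCCAUGCC	UUCGCGAUGUC	97.5	72.0	81	True
T00003	G00003	53	183	1	130	CAAAACAUGGC	AAUAUCAUGCG	96.0	44.92800000000001	147	True
T00004	G00004	63	103	1	40	GAGUGUAUGUG	UACCAGAUGUU	14.871599999999997	24.479999999999997	57	True
T00005	G00005	56	183	1	127	CUCAACAUGGG	UUUCGAAUGCC	108.0	26.52	138	True
T00006	G00006	71	158	0	87	CAACUUAUGCA	AUUAUCAUGCU	16.848000000000003	53.040000000000006	234	True
T00007	G00007	76	85	0	9	CAAACAAUGGU	GUCAUAAUGUC	81.6	72.0	171	True
T00008	G00008	78	88	1	10	UCUUUUAUGCA	AGUCGGAUGUG	15.163200000000003	22.031999999999996	24	True
T00009	G00009	52	76	0	24	CUUCUAAUGUG	AAAAUAAUGGC	20.736000000000004	96.0	162	True
T00010	G00010	54	112	1	58	UCUUGUAUGAG	AACCAAAUGUU	17.3502	30.599999999999998	27	True
T00011	G00011	61	95	1	34	CUAAAUAUGGA	GACGCUAUGAA	81.0	56.699999999999996	192	True
T00012	G00012	55	295	0	240	CUUUAUAUGCA	AUUCGCAUGUU	18.954000000000004	26.009999999999998	177	True
T00013	G00013	63	81	0	18	UGACCUAUGCA	UCGCCUAUGAC	21.060000000000002	25.2	228	True
T00014	G00014	51	66	0	15	GAGUGUAUGAG	UCUACAAUGCG	17.3502	56.160000000000004	237	True
T00015	G00015	53	146	0	93	AAUAGGAUGGC	CGGCUUAUGUU	81.6	11.750400000000003	270	True
T00016	G00016	76	96	2	20	UGUUGGAUGUG	AGGGUCAUGGA	15.863040000000005	69.12000000000002	33	True
T00017	G00017	54	211	1	157	UUGGCCAUGGC	GUGAUAAUGAU	96.0	57.11999999999999	15	True
T00018	G00018	81	114	0	33	UCAAAGAUGGU	CUCGUAAUGAU	102.0	57.11999999999999	180	True
T00019	G00019	56	131	0	75	CAGCCUAUGAU	CGGCUCAUGUA	17.136	16.588800000000003	168	True
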