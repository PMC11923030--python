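circrna_ids	chrom	start	end	donor_site	acceptor_site	similarity
circ-BCL2L12-1;circ-BCL2L12-15;circ-BCL2L12-16	chr19	49666059	49670223	CG	CC	GGCCYCGGACC
circ-BCL2L12-2b;circ-BCL2L12-21;circ-BCL2L12-22	chr19	49666695	49670375	GC	UG	UGGC
circ-BCL2L12-3	chr19	49665813	49667047	UU	AC	YAACAGACYY
circ-BCL2L12-4	chr19	49665848	49667134	AU	CC
circ-BCL2L12-5	chr19	49665958	49667158	CC	GA	RRCCYGGY
circ-BCL2L12-6	chr19	49665971	49667639	UA	GC	AGUGC
circ-BCL2L12-8	chr19	49665997	49673877	AA	UA	AAUAAA
circ-BCL2L12-9;circ-BCL2L12-55	chr19	49665997	49673917	AA	UA
circ-BCL2L12-10b	chr19	49666022	49670233	CC	GA
circ-BCL2L12-11;circ-BCL2L12-13	chr19	49666047	49669095	GC	CG	UGGAGGAGG
circ-BCL2L12-12	chr19	49666050	49673803	GU	CG
circ-BCL2L12-14	chr19	49666059	49670335	CG	CC	GCCCCGGRCC
circ-BCL2L12-17b	chr19	49666059	49670369	CG	CC	CCCG
circ-BCL2L12-18	chr19	49666445	49666935	CA	CU	UCCUC
circ-BCL2L12-19	chr19	49666684	49668879	GG	AG
circ-BCL2L12-23	chr19	49666695	49669091	GG	UG
circ-BCL2L12-24	chr19	49666702	49666899	CU	CU	GGCUCUR
circ-BCL2L12-25	chr19	49666702	49670365	GG	CU
circ-BCL2L12-26	chr19	49666776	49670304	AU	GG	GCCGGG
circ-BCL2L12-27a	chr19	49666878	49667289	UC	UC	UCCUCUCYYY
circ-BCL2L12-28	chr19	49666959	49669676	AC	GG
circ-BCL2L12-29	chr19	49667021	49673788	CC	AG	CCCUGCCC
circ-BCL2L12-30	chr19	49667021	49669116	GU	AG	CCAGAAG
circ-BCL2L12-31	chr19	49667021	49670232	CC	AG	GCCCUGC
circ-BCL2L12-32	chr19	49667141	49673764	CU	CC	CUGCUAYRR
circ-BCL2L12-33	chr19	49668064	49670874	CC	AG	AGCCA
circ-BCL2L12-34	chr19	49668545	49669278	GU	CU	GCUCACGCCUGUAAUCCYAGCACUUUGGGAGGCYGAG
circ-BCL2L12-35a	chr19	49668620	49669367	CU	AU	CAACAYGGUGAAACCCCAUYUCUACUAAAA
circ-BCL2L12-36	chr19	49668697	49669215	GU	AG	CAGG
circ-BCL2L12-37	chr19	49668850	49670489	GU	AG	CYRGGY
circ-BCL2L12-38	chr19	49668850	49669116	GU	AG	AGGY
circ-BCL2L12-39	chr19	49668850	49669165	GU	AG
circ-BCL2L12-40	chr19	49668898	49669233	AA	AC	GGCUGGRACAR
circ-BCL2L12-41	chr19	49668922	49670849	CU	AU	AUCUCYRC
circ-BCL2L12-42	chr19	49669063	49673838	GU	CU	RCUGYGGRG
circ-BCL2L12-43	chr19	49669098	49673761	AA	AG	CAGAAGYYRYUA
circ-BCL2L12-44	chr19	49670232	49673854	CC	GC	YYGCCCURC
circ-BCL2L12-46	chr19	49673118	49673785	UG	CG	CACCUCR
circ-BCL2L12-47b	chr19	49666003	49670358	AG	UU
circ-BCL2L12-92	chr19	49673501	49673813	AA	CC	RCYUUUCC
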