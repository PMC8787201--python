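human_gene_id	gene	bovine_gene_id	sites_text	dG_text	ratio_text
90416	CCDC32	506935	861–903 (22)	−115÷−119	90–93
959	CD40LG	282387	1550–1578 (15)	−119	93
2033	EP300	112446776	8556–8587 (16)	−115÷−119	90–93
1112	FOXN3	505469	2419–2445 (14)	−115÷−119	90–93
2674	GFRA1	534801	8452–8480 (15)	−119	93
2736	GLI2	510255	6118–6147 (15)	−115÷−119	90–93
2742	GLRA2	537660	2525–2567 (20)	−115÷−119	90–93
22801	ITGA11	523755	4599–4635 (22)	−115÷−119	90–93
84056	KATNAL1	537739	4197–4238 (20)	−115÷−119	90–93
56479	KCNQ5	613605	5367–5413 (24)	−115÷−119	90–93
653319	KIAA0895L	512420	2878–2927 (25)	−115÷−119	90–93
11155	LDB3	536781	4420–450 (15)	−115÷−119	90–93
10186	LHFP	532944	1396–1425 (14)	−115÷−119	90–93
108927	NCDN	505994	3556–3586 (16)	−115÷−119	90–93
7101	NR2E1	528156	2954–2980 (14)	−119	93
5579	PRKCB	282325	7060–7088 (15)	−115÷−121	90–95
862	RUNX1T1	538628	3268–3300 (17)	−115÷−119	90–93
388228	SBK1	614815	2320–2361 (20)	−117÷−121	92–95
23157	SEPT6	540783	4494–4522 (15)	−115÷−119	90–93
9342	SNAP29	532261	1360–1386 (14)	−115÷−119	90–93
54558	SPATA6	534169	3206–3232 (14)	−115÷−119	90–93
727837	SSX2B	534692	1276–1307 (16)	−115÷−121	90–95
10214	SSX3	6757	1085–1130 (18)	−115÷−121	90–95
11346	SYNPO	533531	3598–3624 (14)	−115÷−119	90–93
202500	TCTE1	523600	2239–2267 (15)	−115÷−119	90–93
84951	TNS4	532898	3472–3512 (21)	−115÷−119	90–93
79865	TREML2	515548	2346–2379 (17)	−115÷−119	90–93
134510	UBLCP1	508163	1544–1573 (15)	−115÷−119	90–93
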