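gene	chromosome	width_kb	n_samples	n_insertions	gkc_p	other_genes	inferred_moa	mc_support	cohort
Nfia	4	28.6	20	27	<1E-14	-	Loss	Y	medulloblastoma
Atxn2	5	25	6	6	<1E-14	-	?	Y	medulloblastoma
Tead1	7	19.1	6	7	3.9E-14	-	Gain	Y	medulloblastoma
Tgif2	2	0.8	3	4	0.0006	-	Gain	Y	medulloblastoma
Crebbp	16	37.1	5	5	0.0009	-	Loss	Y	medulloblastoma
Dscr3	16	18.3	5	6	0.0009	-	Loss	Y	medulloblastoma
CIS13:72336914	13	44.3	5	6	0.0042	n/a	n/a	Y	medulloblastoma
Pten	19	50.2	4	5	0.0046	-	Loss	Y	medulloblastoma
Itgbl1	14	43.4	5	5	0.0062	Fgf14	?	Y	medulloblastoma
Nfib	4	24.7	7	9	0.0071	-	Gain	Y	medulloblastoma
Myt1l	12	67.2	8	10	0.0089	Pxdn,Tpo,Sntg2	Loss	N	medulloblastoma
Ankrd5	2	1071.3	8	15	0.0092	Plcb4,Pak7,Snap25	?	N	medulloblastoma
Slit3	11	494.3	8	12	0.012	-	Loss	N	medulloblastoma
Tmem45b	9	58.4	4	5	0.019	-	?	Y	medulloblastoma
Sfi1	11	51	5	6	0.021	-	Loss	Y	medulloblastoma
CIS15:70979306	15	20.3	4	4	0.028	n/a	n/a	Y	medulloblastoma
Fgf13	X	23.5	3	4	0.026	-	Gain	N	medulloblastoma
CIS3:147532546	3	140.5	4	7	0.043	n/a	n/a	N	medulloblastoma
L3mbtl4	17	221.6	7	7	0.043	Tmem200c	Loss	N	medulloblastoma
Adcy5	16	127.1	4	6	0.044	Ptblb	Loss	N	medulloblastoma
Faf1	4	41.7	4	4	0.01	-	?	Y	cerebellum_control
l7Rn6	7	10	3	3	0.018	Ccdc81	?	Y	cerebellum_control
CIS6:31346217_240k	6	844	6	8	0.045	n/a	n/a	N	cerebellum_control
Ric3	7	99	4	4	0.035	Tub	?	N	cerebellum_control
CIS9:68415409_240k	9	1738	9	11	0.016	n/a	n/a	Y	cerebellum_control
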