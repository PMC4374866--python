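rat_id	genotype	sex	age_weeks	diagnosis	loh	loh_type	chromothripsis	ct_chroms	bfb	bfb_chroms	amplified_oncogenes
196	-/-	male	21	fibrosarcoma	no	-	no	-	no	-	-
198	-/-	male	13	fibrosarcoma	no	-	no	-	no	-	-
164	-/-	male	13	hemangiosarcoma	no	-	no	-	no	-	-
174	-/-	male	18	hemangiosarcoma	no	-	no	-	no	-	-
199	-/-	male	14	hemangiosarcoma	no	-	no	-	no	-	-
223	-/-	female	15	hemangiosarcoma	no	-	no	-	no	-	-
261	-/-	male	12	hemangiosarcoma	no	-	no	-	no	-	-
225	-/-	male	10	hemangiosarcoma	no	-	no	-	no	-	-
247	-/-	male	8	hemangiosarcoma	no	-	no	-	no	-	-
201	-/-	male	20	leiomyosarcoma	no	-	no	-	no	-	-
103	+/-	male	54	fibrosarcoma	yes	deletion	yes	6	no	-	-
170	+/-	male	45	fibrosarcoma	yes	deletion	yes	1	yes	7	Myc
153	+/-	male	49	leiomyosarcoma	yes	affected by chromothripsis	yes	10,13	yes	9	Vegfa
20	+/-	female	45	osteosarcoma	yes	gene conversion or copy-neutral SV	no	-	no	-	-
82	+/-	male	45	osteosarcoma	yes	gene conversion	yes	7	no	-	-
97	+/-	male	47	osteosarcoma	yes	affected by chromothripsis	yes	3,8,10	no	-	-
100	+/-	female	45	osteosarcoma	yes	gene conversion or copy-neutral SV	no	-	no	-	-
112	+/-	female	71	osteosarcoma	yes	affected by chromothripsis	yes	3,10	yes	6,10	Mycn,Alk
118	+/-	male	41	osteosarcoma	yes	gene conversion	no	-	no	-	-
142	+/-	male	54	osteosarcoma	yes	deletion	yes	5	yes	9	Vegfa
144	+/-	male	68	osteosarcoma	yes	deletion	no	-	yes	5,7	Myc
160	+/-	female	52	osteosarcoma	yes	deletion	no	-	no	-	-
202	+/-	male	34	osteosarcoma	yes	deletion	yes	10,17	yes	14	-
9	+/-	female	36	rhabdomyosarcoma	yes	gene conversion or copy-neutral SV	yes	6	no	-	-
125	+/-	female	46	transitional cell carcinoma	yes	gene conversion or copy-neutral SV	no	-	no	-	-
95	+/-	male	54	ND	yes	deletion	no	-	no	-	-
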