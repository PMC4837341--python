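id	name	formula	herb_class	structure
S14	14-Acetyltalatizamine	C26H41NO6	S
J54	6-Gingerol	C17H26O4	J	CCCCC[C@H](O)CC(=O)CCc1ccc(O)c(OC)c1
H60	Daidzein	C15H10O4	H	O=c1c(-c2ccc(O)cc2)coc2cc(O)ccc12
H34	Formononetin	C16H12O4	H	COc1ccc(-c2coc3cc(O)ccc3c2=O)cc1
S9	Fuziline	C24H39NO7	S
H41	Gancaonin L	C20H18O6	H
H54	Glycycoumarin	C21H20O6	H
Z16	Glycyrrhizin	C42H62O16	Z
S42	Hetisine	C20H27NO3	S
S8	Hypaconine	C24H39NO8	S
S26	Hypaconitine	C33H45NO10	S
H29	Isoliquiritigenin	C15H12O4	H	O=C(/C=C/c1ccc(O)cc1)c1ccc(O)cc1O
H58	Licochalcone D	C21H22O5	H
H59	Licoisoflavone	C20H18O6	H
H20	Liquiritigenin	C15H12O4	H	O=C1C[C@@H](c2ccc(O)cc2)Oc2cc(O)ccc21
S3	Mesaconine	C24H39NO9	S
S10	Neoline	C24H39NO6	S
S12	Talatisamine	C24H39NO5	S
Z29	Glycyrrhetic acid	C30H46O4	Z
S25	Aconitine	C34H47NO11	S
S21	Mesaconitine	C33H45NO11	S
H56	Davidigenin	C15H14O4	H	O=C(CCc1ccc(O)cc1)c1ccc(O)cc1O
J32	4-Shogaol	C15H20O3	J	CCC/C=C/C(=O)CCc1ccc(O)c(OC)c1
J56	8-Gingerol	C19H30O4	J	CCCCCCC[C@H](O)CC(=O)CCc1ccc(O)c(OC)c1
J24	8-Paradol	C19H30O3	J	CCCCCCCCCC(=O)CCc1ccc(O)c(OC)c1
J37	8-Shogaol	C19H28O3	J	CCCCCCC/C=C/C(=O)CCc1ccc(O)c(OC)c1
J58	10-Gingerol	C21H34O4	J	CCCCCCCCC[C@H](O)CC(=O)CCc1ccc(O)c(OC)c1
J39	10-Shogaol	C21H32O3	J	CCCCCCCCC/C=C/C(=O)CCc1ccc(O)c(OC)c1
J15	1-Dehydro-10-gingerdione	C21H30O4	J
J13	1-Dehydro-6-gingerdione	C18H26O3	J
J22	6-Paradol	C17H26O3	J	CCCCCCCC(=O)CCc1ccc(O)c(OC)c1
J35	6-Shogaol	C17H24O3	J	CCCCC/C=C/C(=O)CCc1ccc(O)c(OC)c1
S43	Beiwutinine	C23H37NO10	S
S32	Coryneine	C11H18NO2	S
H28	Echinatin	C16H14O4	H	COc1cc(/C=C/C(=O)c2ccc(O)cc2)ccc1O
S40	Fuzinoside	C15H28O13	S
H47	Glabridin	C20H20O4	H
Z1	Glycyrrhizic acid	C42H62O16	Z
S39	Higenamine	C16H17NO3	S	Oc1ccc(CC2NCCc3cc(O)c(O)cc32)cc1
H26	Licochalcone A	C21H22O4	H	COc1cc(/C=C/C(=O)c2ccc(O)cc2)c(C(C)(C)C=C)cc1O
H27	Licochalcone B	C16H14O5	H
H57	Licochalcone C	C21H22O4	H
S41	Neolinine	C23H37NO6	S
H19	Pinocembrin	C15H12O4	H	O=C1C[C@@H](c2ccccc2)Oc2cc(O)cc(O)c21
H11	Quercetin	C15H10O7	H	O=c1c(O)c(-c2ccc(O)c(O)c2)oc2cc(O)cc(O)c12
H10	Rutin	C27H30O16	H	C[C@@H]1O[C@@H](OC[C@H]2O[C@@H](Oc3c(-c4ccc(O)c(O)c4)oc4cc(O)cc(O)c4c3=O)[C@H](O)[C@@H](O)[C@@H]2O)[C@H](O)[C@H](O)[C@H]1O
S31	Salsolinol	C10H13NO2	S	CC1NCCc2cc(O)c(O)cc21
S38	Songoramine	C22H29NO3	S
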