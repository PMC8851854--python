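profile_id	database	cutoff_score	score_type	cutoff_kind	function_ids	motif_rule_id
ArrA_custom	custom	71	full	nc	O-F-05	
Cyc2_custom	custom	120	full	nc	O-F-03	
FeFe_GroupA	custom	147	full	nc	C-F-07	
Fe_hydrogenase	custom	252	full	nc	C-F-16	
K00001	kofam	248	full	suggested	C-F-05	
K00134	kofam	201	full	suggested	C-F-01	
K00198	kofam	225	full	suggested	C-F-03	
K00362	kofam	210	full	suggested	N-F-12	
K00363	kofam	269	full	suggested	N-F-12	
K00368	kofam	284	full	suggested	N-F-07	
K00370	kofam	94	full	suggested	N-F-04;N-F-05	
K00371	kofam	147	full	suggested	N-F-04;N-F-05	
K00376	kofam	187	full	suggested	N-F-10	
K00394	kofam	241	full	suggested	S-F-08	
K00395	kofam	128	full	suggested	S-F-08	
K00399	kofam	118	domain	suggested	C-F-10;C-F-11;C-F-12	
K00401	kofam	116	full	suggested	C-F-11	
K00537	kofam	122	full	suggested	O-F-04	
K00656	kofam	294	full	suggested	C-F-09	
K00925	kofam	258	full	suggested	C-F-10	
K00958	kofam	69	full	suggested	S-F-07	
K01601	kofam	208	domain	suggested	C-F-02	
K01895	kofam	244	full	suggested	C-F-06	
K02305	kofam	59	full	suggested	N-F-09	
K02567	kofam	118	full	suggested	N-F-06	
K02568	kofam	225	full	suggested	N-F-06	
K02586	kofam	113	full	suggested	N-F-01	
K02588	kofam	214	full	suggested	N-F-01	
K02591	kofam	171	full	suggested	N-F-01	
K03385	kofam	253	full	suggested	N-F-11	
K03520	kofam	161	full	suggested	C-F-17	
K04480	kofam	155	full	suggested	C-F-12	
K04561	kofam	88	full	suggested	N-F-09	
K05301	kofam	117	full	suggested	S-F-06	
K08352	kofam	279	full	suggested	S-F-13	
K10535	kofam	286	full	suggested	N-F-03	
K10944	kofam	188	domain	suggested	C-F-13;N-F-02	
K10945	kofam	89	full	suggested	N-F-02	
K11179	kofam	208	full	suggested	S-F-10	DsrC
K11180	kofam	203	domain	suggested	S-F-09	
K11181	kofam	101	full	suggested	S-F-09	
K12527	kofam		full	evalue_fallback	O-F-06	
K14138	kofam	226	full	suggested	C-F-03	
K15230	kofam	51	full	suggested	C-F-04	
K15231	kofam	186	full	suggested	C-F-04	
K15864	kofam	114	full	suggested	N-F-08	
K15876	kofam	111	full	suggested	N-F-11	
K16157	kofam	266	full	suggested	C-F-14	
K16950	kofam	276	full	suggested	S-F-11	
K16951	kofam	258	full	suggested	S-F-11	
K17218	kofam	138	full	suggested	S-F-01	
K17222	kofam	94	full	suggested	S-F-04	
K17224	kofam	264	full	suggested	S-F-04;S-F-12	
K17229	kofam	223	full	suggested	S-F-02	
K17725	kofam	182	full	suggested	S-F-05	
K20932	kofam	105	full	suggested	N-F-13	
K20935	kofam	238	full	suggested	N-F-14	
MtrB_custom	custom	137	full	nc	O-F-01	
NiFe_Group1	custom	158	full	nc	C-F-15	
NiFe_Group4	custom	76	full	nc	C-F-08	
OmcS_custom	custom		full	evalue_fallback	O-F-02	
SrdA_custom	custom	257	full	nc	O-F-07	
Sre_custom	custom	54	full	nc	S-F-03	
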