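function_id	name	category	step_id	profile_ids
C-F-01	Organic carbon oxidation	Carbon	C-S-01	K00134
C-F-02	CBB cycle (RuBisCO)	Carbon	C-S-02	K01601
C-F-03	Wood-Ljungdahl pathway	Carbon	C-S-02	K14138;K00198
C-F-04	rTCA cycle	Carbon	C-S-02	K15230;K15231
C-F-05	Ethanol oxidation	Carbon	C-S-03	K00001
C-F-06	Acetate oxidation	Carbon	C-S-04	K01895
C-F-07	FeFe hydrogenase H2 evolution	Carbon	C-S-05	FeFe_GroupA
C-F-08	NiFe Group 4 H2 evolution	Carbon	C-S-05	NiFe_Group4
C-F-09	Fermentation (pyruvate-formate lyase)	Carbon	C-S-06	K00656
C-F-10	Acetoclastic methanogenesis	Carbon	C-S-07	K00925;K00399
C-F-11	Hydrogenotrophic methanogenesis	Carbon	C-S-07	K00399;K00401
C-F-12	Methylotrophic methanogenesis	Carbon	C-S-07	K04480;K00399
C-F-13	Particulate methane monooxygenase	Carbon	C-S-08	K10944
C-F-14	Soluble methane monooxygenase	Carbon	C-S-08	K16157
C-F-15	NiFe Group 1 H2 uptake	Carbon	C-S-09	NiFe_Group1
C-F-16	Fe hydrogenase H2 uptake	Carbon	C-S-09	Fe_hydrogenase
C-F-17	CO oxidation (coxL)	Carbon	C-S-10	K03520
N-F-01	Nitrogenase (nifHDK)	Nitrogen	N-S-01	K02586;K02588;K02591
N-F-02	Ammonia monooxygenase (amoAB)	Nitrogen	N-S-02	K10944;K10945
N-F-03	Hydroxylamine oxidation (hao)	Nitrogen	N-S-02	K10535
N-F-04	Nitrite oxidoreductase (nxrAB)	Nitrogen	N-S-03	K00370;K00371
N-F-05	Membrane-bound nitrate reductase (narGH)	Nitrogen	N-S-04	K00370;K00371
N-F-06	Periplasmic nitrate reductase (napAB)	Nitrogen	N-S-04	K02567;K02568
N-F-07	Copper nitrite reductase (nirK)	Nitrogen	N-S-05	K00368
N-F-08	Cytochrome cd1 nitrite reductase (nirS)	Nitrogen	N-S-05	K15864
N-F-09	Nitric oxide reductase (norBC)	Nitrogen	N-S-06	K04561;K02305
N-F-10	Nitrous oxide reductase (nosZ)	Nitrogen	N-S-07	K00376
N-F-11	Cytochrome c nitrite reductase (nrfAH)	Nitrogen	N-S-08	K03385;K15876
N-F-12	NADH-dependent nitrite reductase (nirBD)	Nitrogen	N-S-08	K00362;K00363
N-F-13	Hydrazine synthase (hzsA)	Nitrogen	N-S-09	K20932
N-F-14	Hydrazine dehydrogenase (hdh)	Nitrogen	N-S-09	K20935
S-F-01	Sulfide:quinone oxidoreductase (sqr)	Sulfur	S-S-01	K17218
S-F-02	Flavocytochrome c sulfide dehydrogenase	Sulfur	S-S-01	K17229
S-F-03	Sulfur reductase (sreA)	Sulfur	S-S-02	Sre_custom
S-F-04	Sox system sulfur oxidation	Sulfur	S-S-03	K17222;K17224
S-F-05	Sulfur dioxygenase (sdo)	Sulfur	S-S-03	K17725
S-F-06	Sulfite dehydrogenase (sorA)	Sulfur	S-S-04	K05301
S-F-07	Sulfate adenylyltransferase (sat)	Sulfur	S-S-05	K00958
S-F-08	Adenylylsulfate reductase (aprAB)	Sulfur	S-S-05	K00394;K00395
S-F-09	Dissimilatory sulfite reductase (dsrAB)	Sulfur	S-S-05	K11180;K11181
S-F-10	DsrC sulfur relay	Sulfur	S-S-06	K11179
S-F-11	Anaerobic sulfite reductase (asrAB)	Sulfur	S-S-06	K16950;K16951
S-F-12	Thiosulfate oxidation (soxB)	Sulfur	S-S-07	K17224
S-F-13	Thiosulfate reductase (phsA)	Sulfur	S-S-08	K08352
O-F-01	Dissimilatory iron reduction (mtrB)	Other	O-S-01	MtrB_custom
O-F-02	Iron reduction via omcS	Other	O-S-01	OmcS_custom
O-F-03	Iron oxidation (cyc2)	Other	O-S-02	Cyc2_custom
O-F-04	Arsenate reductase (arsC)	Other	O-S-03	K00537
O-F-05	Respiratory arsenate reductase (arrA)	Other	O-S-03	ArrA_custom
O-F-06	Selenate reductase (ynfE)	Other	O-S-04	K12527
O-F-07	Respiratory selenate reductase (srdA)	Other	O-S-04	SrdA_custom
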