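step_id	name	cycle	profile_ids
C-S-01	Organic carbon oxidation	Carbon	K00134
C-S-02	Carbon fixation	Carbon	K01601;K14138;K00198;K15230;K15231
C-S-03	Ethanol oxidation	Carbon	K00001
C-S-04	Acetate oxidation	Carbon	K01895
C-S-05	Hydrogen generation	Carbon	FeFe_GroupA;NiFe_Group4
C-S-06	Fermentation	Carbon	K00656
C-S-07	Methanogenesis	Carbon	K00925;K00399;K00401;K04480
C-S-08	Methanotrophy	Carbon	K10944;K16157
C-S-09	Hydrogen oxidation	Carbon	NiFe_Group1;Fe_hydrogenase
C-S-10	CO oxidation	Carbon	K03520
N-S-01	N2 fixation	Nitrogen	K02586;K02588;K02591
N-S-02	Ammonia oxidation	Nitrogen	K10944;K10945;K10535
N-S-03	Nitrite oxidation	Nitrogen	K00370;K00371
N-S-04	Nitrate reduction	Nitrogen	K00370;K00371;K02567;K02568
N-S-05	Nitrite reduction	Nitrogen	K00368;K15864
N-S-06	Nitric oxide reduction	Nitrogen	K04561;K02305
N-S-07	Nitrous oxide reduction	Nitrogen	K00376
N-S-08	Nitrite ammonification	Nitrogen	K03385;K15876;K00362;K00363
N-S-09	Anammox	Nitrogen	K20932;K20935
S-S-01	Sulfide oxidation	Sulfur	K17218;K17229
S-S-02	Sulfur reduction	Sulfur	Sre_custom
S-S-03	Sulfur oxidation	Sulfur	K17222;K17224;K17725
S-S-04	Sulfite oxidation	Sulfur	K05301
S-S-05	Sulfate reduction	Sulfur	K00958;K00394;K00395;K11180;K11181
S-S-06	Sulfite reduction	Sulfur	K11179;K16950;K16951
S-S-07	Thiosulfate oxidation	Sulfur	K17224
S-S-08	Thiosulfate disproportionation	Sulfur	K08352
O-S-01	Iron reduction	Other	MtrB_custom;OmcS_custom
O-S-02	Iron oxidation	Other	Cyc2_custom
O-S-03	Arsenate reduction	Other	K00537;ArrA_custom
O-S-04	Selenate reduction	Other	K12527;SrdA_custom
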