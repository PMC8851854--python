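module_id	name	definition
M00175	Nitrogen fixation, nitrogen => ammonia	K02588+K02586+K02591
M00528	Nitrification, ammonia => nitrite	(K10944+K10945) K10535
M00529	Denitrification, nitrate => nitrogen	K00370+K00371 K00368,K15864 K04561+K02305 K00376
M00530	Dissimilatory nitrate reduction, nitrate => ammonia	K00370+K00371 (K03385+K15876),(K00362+K00363)
M00531	Assimilatory nitrate reduction (toy)	K00370-K00371 K00362+K00363
M00596	Dissimilatory sulfate reduction, sulfate => H2S	K00958 K00394+K00395 K11180+K11181
M00595	Thiosulfate oxidation by SOX complex (toy)	K17222+K17224
M00567	Methanogenesis, CO2 => methane (toy)	K00200 K00319 -- K00399+K00401+K00402
M00357	Methanogenesis, acetate => methane (toy)	K00925 K00625 K00399+K00401
M00165	Reductive pentose phosphate cycle (toy)	K01601 K00855 K00134,K05298
M00173	Reductive citrate cycle (toy)	K15230+K15231 K01902-K01903 K00239,K00244
M00936	Anammox (toy)	K20932 K20935
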