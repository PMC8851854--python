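chain_id	letter	step_id	label
denitrification	A	N-S-04	Nitrate reduction
denitrification	B	N-S-05	Nitrite reduction
denitrification	C	N-S-06	Nitric oxide reduction
denitrification	D	N-S-07	Nitrous oxide reduction
sulfate_reduction	A	S-S-05	Sulfate reduction
sulfate_reduction	B	S-S-06	Sulfite reduction
organic_carbon	A	C-S-01	Organic carbon oxidation
organic_carbon	B	C-S-06	Fermentation
organic_carbon	C	C-S-04	Acetate oxidation
organic_carbon	D	C-S-07	Methanogenesis
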