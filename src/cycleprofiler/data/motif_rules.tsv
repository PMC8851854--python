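rule_id	required_motif	forbidden_motif	description
DsrC	GPXKXXCXXXGXPXPXXCX		Conserved C-terminal residue window diagnostic for DsrC; absent from the confounding tRNA-thiouridine synthase TusE, which shares KO family K11179.
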