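name	a	b	c	d	description
missense_synonymous_dr_nr	41691	20282	176888	92314	DR missense / DR synonymous / NR missense / NR synonymous population variant counts
peptide_dr_nr	287	58706	254	285859	DR residues in active peptides / other DR / NR residues in active peptides / other NR (from 541 peptide residues, 53% disordered, 58993 DR and 286113 NR totals)
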