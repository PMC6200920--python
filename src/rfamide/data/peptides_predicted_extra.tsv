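peptide_id	sequence	amidated	identified	copy_number	gene_id	species	clade_label	reference_group
Quail predicted RSa peptide	APNLSNRS	true	false	1	Quail GnIH precursor	Quail	chordate
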