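receptor	flp_ligands	putative_roles
NPR-1	21	Feeding behavior; Thermal avoidance; Ethanol tolerance; Innate immunity; Regulation of aggregation; Aerotaxis
NPR-3	15-1, 15-2	Locomotion
NPR-4	1-6, 4-2, 18-2, 18-5	Fat storage; Olfaction; Foraging; Reproduction
NPR-5a, NPR-5b	18-1, 18-2, 18-3, 18-4, 18-5, 18-6	Fat storage; Dauer formation
NPR-10a, NPR-10b	3-1, 3-3, 3-5, 3-7, 3-8	
NPR-11	21	Local search behavior; Olfactory adaptation; Reproduction
FRPR-18a, FRPR-18b	2-1	
NPR-22a, NPR-22b	7-3	
EGL-6a, EGL-6b	10, 17-1, 17-2	Inhibition of egg laying
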