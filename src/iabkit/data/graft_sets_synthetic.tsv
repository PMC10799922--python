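# Synthetic reconstruction of the iAb graft residue sets (Kabat numbering, heavy chain).
# The published residue identities are figure-encoded and not machine-readable; this
# table preserves their documented structure: framework beta-strand A/B/D/E positions,
# hydrophobic targets for the affinity-interface sets (with two optional strengthening
# substitutions each), and a domain-exchange set with exactly one CDRH2 exception label.
set_name	kabat_label	target_residue	strengthening_flag	cdr_exception_flag
iAb_dx	6	R	0	0
iAb_dx	16	D	0	0
iAb_dx	19	R	0	0
iAb_dx	57	E	0	1
iAb_dx	75	K	0	0
iAb_dx	77	T	0	0
iAb_dx	84	N	0	0
iAb_dx	112	V	0	0
iAb_aff1	3	F	0	0
iAb_aff1	5	I	0	0
iAb_aff1	19	L	0	0
iAb_aff1	68	V	0	0
iAb_aff1	70	M	0	0
iAb_aff1	72	L	0	0
iAb_aff1	79	V	0	0
iAb_aff1	81	I	0	0
iAb_aff1	23	V	1	0
iAb_aff1	76	I	1	0
iAb_aff2	3	L	0	0
iAb_aff2	5	F	0	0
iAb_aff2	19	V	0	0
iAb_aff2	68	I	0	0
iAb_aff2	70	L	0	0
iAb_aff2	72	F	0	0
iAb_aff2	79	I	0	0
iAb_aff2	81	L	0	0
iAb_aff2	23	I	1	0
iAb_aff2	76	L	1	0
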