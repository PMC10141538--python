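name	formula	scaffold	side_chain_kind	side_chain_loss	flags	aliases
ADB-BUTINACA	C18H26N4O2	indazole-3-carboxamide	alkyl	C4H8	terminal_amide	ADB-BUTINACA;ADB-BUPINACA
MDMB-4en-PINACA	C20H27N3O3	indazole-3-carboxamide	alkenyl	C5H8	methyl_ester;alkene
BZO-HEXOXIZID	C21H23N3O2	isatin-acyl-hydrazone	alkyl	C6H12	benzoyl
BZO-POXIZID	C20H21N3O2	isatin-acyl-hydrazone	alkyl	C5H10	benzoyl
BZO-4en-POXIZID	C20H19N3O2	isatin-acyl-hydrazone	alkenyl	C5H8	alkene;benzoyl
5F-BZO-POXIZID	C20H20FN3O2	isatin-acyl-hydrazone	fluoroalkyl	C5H9F	fluorine;benzoyl	5-fluoro BZO-POXIZID;5F BZO-POXIZID
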