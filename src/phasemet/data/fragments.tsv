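scaffold	id	formula	diagnostic_of	covers	parents	modified
indazole-3-carboxamide	indazole_acylium	C8H5N2O	indazole-core	indazole-core		0
indazole-3-carboxamide	indazole_rearranged	C8H7N2O2	indazole-core	indazole-core		0
indazole-3-carboxamide	methyl_indazole	C8H7N2	indazole-core	indazole-core		0
indazole-3-carboxamide	tbutyl_iminium	C5H12N	t-butyl	t-butyl		0
indazole-3-carboxamide	butyl_indazole_acylium	C12H13N2O	N-butyl-indazole	indazole-core;side-chain	ADB-BUTINACA	0
indazole-3-carboxamide	butyl_indazole_rearranged	C12H15N2O2	N-butyl-indazole	indazole-core;side-chain	ADB-BUTINACA	0
indazole-3-carboxamide	adb_alpha_cleavage	C17H24N3O	alpha-cleavage	indazole-core;side-chain;t-butyl	ADB-BUTINACA	0
indazole-3-carboxamide	pentenyl_indazole_acylium	C13H13N2O	N-pentenyl-indazole	indazole-core;side-chain	MDMB-4en-PINACA	0
indazole-3-carboxamide	pentenyl_indazole_rearranged	C13H15N2O2	N-pentenyl-indazole	indazole-core;side-chain	MDMB-4en-PINACA	0
indazole-3-carboxamide	mdmb_alpha_cleavage	C18H24N3O	alpha-cleavage	indazole-core;side-chain;t-butyl	MDMB-4en-PINACA	0
indazole-3-carboxamide	pentenyl_cation	C5H9	side-chain	side-chain	MDMB-4en-PINACA	0
isatin-acyl-hydrazone	oxoindoline	C8H5N2O	oxoindoline-core	oxoindoline-core		0
isatin-acyl-hydrazone	isatin_hydrazone_core	C9H8N3O	oxoindoline-core	oxoindoline-core		0
isatin-acyl-hydrazone	benzoyl_cation	C7H5O	benzoyl	benzoyl		0
isatin-acyl-hydrazone	phenyl_cation	C6H5	benzoyl	benzoyl		0
isatin-acyl-hydrazone	hydroxybenzoyl_cation	C7H5O2	benzoyl-hydroxylated	benzoyl		1
isatin-acyl-hydrazone	oxoindoline_ketone	C14H16N3O2	oxoindoline-ketone	oxoindoline-core;side-chain	BZO-HEXOXIZID	1
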