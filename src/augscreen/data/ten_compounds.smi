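# The ten vanilloid/phenolic natural products assayed against SERCA2a.
# SMILES derived from the published IUPAC names and verified against
# molecular formulas. Format: smiles<TAB>id<TAB>name
COc1cc(CCC(=O)CCCCc2ccccc2)ccc1O	yakuchinone_a	Yakuchinone A
CCCCCCCC(=O)CCc1ccc(O)c(OC)c1	paradol_6	6-paradol
CCCCC/C=C/C(=O)CCc1ccc(O)c(OC)c1	shogaol_6	6-shogaol
CCCCCCC/C=C/C(=O)CCc1ccc(O)c(OC)c1	shogaol_8	8-shogaol
CCCCC[C@@H](O)CC(=O)CCc1ccc(O)c(OC)c1	gingerol_6	6-gingerol
CCCCCCC[C@@H](O)CC(=O)CCc1ccc(O)c(OC)c1	gingerol_8	8-gingerol
COc1cc(CCC(O)CCCCc2ccccc2)ccc1O	oxyphyllacinol	Oxyphyllacinol
COc1cc(Cc2ccc(CCc3ccccc3)o2)ccc1O	alpinoid_d	Alpinoid D
COc1cc(CNC(=O)CCCC/C=C/C(C)C)ccc1O	capsaicin	Capsaicin
CCCCCCCCC(=O)NCc1ccc(O)c(OC)c1	nonivamide	Nonivamide
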