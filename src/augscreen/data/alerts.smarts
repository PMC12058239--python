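# Built-in structural-alert library: common mutagenicity / reactivity /
# toxicity substructure patterns (Brenk-style curated subset).
# Format: pattern<TAB>name<TAB>category
[N+](=O)[O-]	nitro_group	mutagenic
a[N+](=O)[O-]	nitroaromatic	mutagenic
N=[N+]=[N-]	azide	reactive
N=N	azo_group	mutagenic
[NX3][NX3]	hydrazine	mutagenic
C(=O)[Cl,Br,I]	acyl_halide	reactive
[CX4][Cl,Br,I]	alkyl_halide	reactive
O=C1OC1	beta_lactone	reactive
C1OC1	epoxide	reactive
C1NC1	aziridine	reactive
[OX2][OX2]	peroxide	reactive
[CX3H1](=O)	aldehyde	reactive
N=C=O	isocyanate	reactive
N=C=S	isothiocyanate	reactive
[SX2H]	thiol	reactive
S(=O)(=O)[Cl,Br]	sulfonyl_halide	reactive
S(=O)(=O)O[CX4]	sulfonate_ester	mutagenic
C=[N+]=[N-]	diazo	reactive
[N;R0]=[N;R0]C#N	azocyanamide	reactive
cN=Nc	azobenzene	carcinogenic
[NX3;H2][cX3]	aromatic_primary_amine	mutagenic
O=[CX3][CX3]=[CX3][CX3H0]=O	bis_michael_acceptor	reactive
[CX3]=[CX3][CX3](=O)[O,N;!R]	acyclic_michael_acceptor	reactive
C(=O)Oc1ccccc1	phenyl_ester	reactive
[#6]S(=O)(=O)O[#6]	sulfuric_acid_ester	mutagenic
[Hg,Pb,As,Sb,Sn,Cd]	heavy_metal	toxic
P(=O)(O[#6])O[#6]	phosphate_triester	reproductive
[I]	iodine	reactive
C=C-[Cl,Br,I]	vinyl_halide	mutagenic
[C;!R](=[N;!R])[N;!R]	acyclic_amidine	reactive
[NX2]=[OX1]	nitroso	mutagenic
O=N(~O)N	nitrosamine_like	carcinogenic
[#16]=[#6]	thiocarbonyl	reactive
c1ccc2c(c1)ccc1ccccc12	anthracene_like	carcinogenic
C#N.C#N	multiple_nitrile	reactive
[N+!$([N+](=O)[O-])](~[!#8])(~[!#8])(~[!#8])~[!#8]	quaternary_nitrogen	toxic
C(=O)N(O)	hydroxamic_acid	mutagenic
N#CC=C	acrylonitrile	carcinogenic
OS(=O)(=O)F	fluorosulfonate	reactive
C=C=C	allene	reactive
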