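# Built-in fragment library for analog growth.
# Format: smiles_with_attachment_point<TAB>name
*O	hydroxy_c0
*OC	methoxy_c0
*N	amino_c0
*N(C)C	dimethylamino_c0
*C(=O)O	carboxy_c0
*C(N)=O	amide_c0
*C(C)=O	methylketone_c0
*C#N	nitrile_c0
*F	fluoro_c0
*Cl	chloro_c0
*C(F)(F)F	trifluoromethyl_c0
*S(C)(=O)=O	methylsulfonyl_c0
*C	alkyl_c1
*CO	hydroxy_c1
*COC	methoxy_c1
*CN	amino_c1
*CN(C)C	dimethylamino_c1
*CC(=O)O	carboxy_c1
*CC(N)=O	amide_c1
*CC(C)=O	methylketone_c1
*CC#N	nitrile_c1
*CF	fluoro_c1
*CCl	chloro_c1
*CC(F)(F)F	trifluoromethyl_c1
*CS(C)(=O)=O	methylsulfonyl_c1
*CC	alkyl_c2
*CCO	hydroxy_c2
*CCOC	methoxy_c2
*CCN	amino_c2
*CCN(C)C	dimethylamino_c2
*CCC(=O)O	carboxy_c2
*CCC(N)=O	amide_c2
*CCC(C)=O	methylketone_c2
*CCC#N	nitrile_c2
*CCF	fluoro_c2
*CCCl	chloro_c2
*CCC(F)(F)F	trifluoromethyl_c2
*CCS(C)(=O)=O	methylsulfonyl_c2
*CCC	alkyl_c3
*CCCO	hydroxy_c3
*CCCOC	methoxy_c3
*CCCN	amino_c3
*CCCN(C)C	dimethylamino_c3
*CCCC(=O)O	carboxy_c3
*CCCC(N)=O	amide_c3
*CCCC(C)=O	methylketone_c3
*CCCC#N	nitrile_c3
*CCCF	fluoro_c3
*CCCCl	chloro_c3
*CCCC(F)(F)F	trifluoromethyl_c3
*CCCS(C)(=O)=O	methylsulfonyl_c3
*CCCC	alkyl_c4
*CCCCO	hydroxy_c4
*CCCCOC	methoxy_c4
*CCCCN	amino_c4
*CCCCN(C)C	dimethylamino_c4
*CCCCC(=O)O	carboxy_c4
*CCCCC(N)=O	amide_c4
*CCCCC(C)=O	methylketone_c4
*CCCCC#N	nitrile_c4
*CCCCF	fluoro_c4
*CCCCCl	chloro_c4
*CCCCC(F)(F)F	trifluoromethyl_c4
*CCCCS(C)(=O)=O	methylsulfonyl_c4
*CCCCC	alkyl_c5
*CCCCCO	hydroxy_c5
*CCCCCOC	methoxy_c5
*CCCCCN	amino_c5
*CCCCCN(C)C	dimethylamino_c5
*CCCCCC(=O)O	carboxy_c5
*CCCCCC(N)=O	amide_c5
*CCCCCC(C)=O	methylketone_c5
*CCCCCC#N	nitrile_c5
*CCCCCF	fluoro_c5
*CCCCCCl	chloro_c5
*CCCCCC(F)(F)F	trifluoromethyl_c5
*CCCCCS(C)(=O)=O	methylsulfonyl_c5
*CCCCCC	alkyl_c6
*CCCCCCO	hydroxy_c6
*CCCCCCOC	methoxy_c6
*CCCCCCN	amino_c6
*CCCCCCN(C)C	dimethylamino_c6
*CCCCCCC(=O)O	carboxy_c6
*CCCCCCC(N)=O	amide_c6
*CCCCCCC(C)=O	methylketone_c6
*CCCCCCC#N	nitrile_c6
*CCCCCCF	fluoro_c6
*CCCCCCCl	chloro_c6
*CCCCCCC(F)(F)F	trifluoromethyl_c6
*CCCCCCS(C)(=O)=O	methylsulfonyl_c6
*c1ccccc1	phenyl_direct
*c1ccc(O)cc1	4-hydroxyphenyl_direct
*c1ccc(OC)cc1	4-methoxyphenyl_direct
*c1ccc(F)cc1	4-fluorophenyl_direct
*c1ccc(C)cc1	4-methylphenyl_direct
*c1ccc(N)cc1	4-aminophenyl_direct
*c1ccncc1	4-pyridyl_direct
*c1cccnc1	3-pyridyl_direct
*c1ccco1	2-furyl_direct
*c1cccs1	2-thienyl_direct
*c1cc[nH]c1	2-pyrrolyl_direct
*c1cnc[nH]1	imidazolyl_direct
*C1CC1	cyclopropyl_direct
*C1CCC1	cyclobutyl_direct
*C1CCCC1	cyclopentyl_direct
*C1CCCCC1	cyclohexyl_direct
*C1CCOC1	tetrahydrofuryl_direct
*C1CCNC1	pyrrolidinyl_direct
*N1CCOCC1	morpholino_direct
*N1CCNCC1	piperazinyl_direct
*c1ccc2ccccc2c1	2-naphthyl_direct
*Cc1ccccc1	phenyl_C
*Cc1ccc(O)cc1	4-hydroxyphenyl_C
*Cc1ccc(OC)cc1	4-methoxyphenyl_C
*Cc1ccc(F)cc1	4-fluorophenyl_C
*Cc1ccc(C)cc1	4-methylphenyl_C
*Cc1ccc(N)cc1	4-aminophenyl_C
*Cc1ccncc1	4-pyridyl_C
*Cc1cccnc1	3-pyridyl_C
*Cc1ccco1	2-furyl_C
*Cc1cccs1	2-thienyl_C
*Cc1cc[nH]c1	2-pyrrolyl_C
*Cc1cnc[nH]1	imidazolyl_C
*CC1CC1	cyclopropyl_C
*CC1CCC1	cyclobutyl_C
*CC1CCCC1	cyclopentyl_C
*CC1CCCCC1	cyclohexyl_C
*CC1CCOC1	tetrahydrofuryl_C
*CC1CCNC1	pyrrolidinyl_C
*CN1CCOCC1	morpholino_C
*CN1CCNCC1	piperazinyl_C
*Cc1ccc2ccccc2c1	2-naphthyl_C
*CCc1ccccc1	phenyl_CC
*CCc1ccc(O)cc1	4-hydroxyphenyl_CC
*CCc1ccc(OC)cc1	4-methoxyphenyl_CC
*CCc1ccc(F)cc1	4-fluorophenyl_CC
*CCc1ccc(C)cc1	4-methylphenyl_CC
*CCc1ccc(N)cc1	4-aminophenyl_CC
*CCc1ccncc1	4-pyridyl_CC
*CCc1cccnc1	3-pyridyl_CC
*CCc1ccco1	2-furyl_CC
*CCc1cccs1	2-thienyl_CC
*CCc1cc[nH]c1	2-pyrrolyl_CC
*CCc1cnc[nH]1	imidazolyl_CC
*CCC1CC1	cyclopropyl_CC
*CCC1CCC1	cyclobutyl_CC
*CCC1CCCC1	cyclopentyl_CC
*CCC1CCCCC1	cyclohexyl_CC
*CCC1CCOC1	tetrahydrofuryl_CC
*CCC1CCNC1	pyrrolidinyl_CC
*CCN1CCOCC1	morpholino_CC
*CCN1CCNCC1	piperazinyl_CC
*CCc1ccc2ccccc2c1	2-naphthyl_CC
*CCCc1ccccc1	phenyl_CCC
*CCCc1ccc(O)cc1	4-hydroxyphenyl_CCC
*CCCc1ccc(OC)cc1	4-methoxyphenyl_CCC
*CCCc1ccc(F)cc1	4-fluorophenyl_CCC
*CCCc1ccc(C)cc1	4-methylphenyl_CCC
*CCCc1ccc(N)cc1	4-aminophenyl_CCC
*CCCc1ccncc1	4-pyridyl_CCC
*CCCc1cccnc1	3-pyridyl_CCC
*CCCc1ccco1	2-furyl_CCC
*CCCc1cccs1	2-thienyl_CCC
*CCCc1cc[nH]c1	2-pyrrolyl_CCC
*CCCc1cnc[nH]1	imidazolyl_CCC
*CCCC1CC1	cyclopropyl_CCC
*CCCC1CCC1	cyclobutyl_CCC
*CCCC1CCCC1	cyclopentyl_CCC
*CCCC1CCCCC1	cyclohexyl_CCC
*CCCC1CCOC1	tetrahydrofuryl_CCC
*CCCC1CCNC1	pyrrolidinyl_CCC
*CCCN1CCOCC1	morpholino_CCC
*CCCN1CCNCC1	piperazinyl_CCC
*CCCc1ccc2ccccc2c1	2-naphthyl_CCC
*C(=O)c1ccccc1	phenyl_C(=O)
*C(=O)c1ccc(O)cc1	4-hydroxyphenyl_C(=O)
*C(=O)c1ccc(OC)cc1	4-methoxyphenyl_C(=O)
*C(=O)c1ccc(F)cc1	4-fluorophenyl_C(=O)
*C(=O)c1ccc(C)cc1	4-methylphenyl_C(=O)
*C(=O)c1ccc(N)cc1	4-aminophenyl_C(=O)
*C(=O)c1ccncc1	4-pyridyl_C(=O)
*C(=O)c1cccnc1	3-pyridyl_C(=O)
*C(=O)c1ccco1	2-furyl_C(=O)
*C(=O)c1cccs1	2-thienyl_C(=O)
*C(=O)c1cc[nH]c1	2-pyrrolyl_C(=O)
*C(=O)c1cnc[nH]1	imidazolyl_C(=O)
*C(=O)C1CC1	cyclopropyl_C(=O)
*C(=O)C1CCC1	cyclobutyl_C(=O)
*C(=O)C1CCCC1	cyclopentyl_C(=O)
*C(=O)C1CCCCC1	cyclohexyl_C(=O)
*C(=O)C1CCOC1	tetrahydrofuryl_C(=O)
*C(=O)C1CCNC1	pyrrolidinyl_C(=O)
*C(=O)N1CCOCC1	morpholino_C(=O)
*C(=O)N1CCNCC1	piperazinyl_C(=O)
*C(=O)c1ccc2ccccc2c1	2-naphthyl_C(=O)
*CC(=O)c1ccccc1	phenyl_CC(=O)
*CC(=O)c1ccc(O)cc1	4-hydroxyphenyl_CC(=O)
*CC(=O)c1ccc(OC)cc1	4-methoxyphenyl_CC(=O)
*CC(=O)c1ccc(F)cc1	4-fluorophenyl_CC(=O)
*CC(=O)c1ccc(C)cc1	4-methylphenyl_CC(=O)
*CC(=O)c1ccc(N)cc1	4-aminophenyl_CC(=O)
*CC(=O)c1ccncc1	4-pyridyl_CC(=O)
*CC(=O)c1cccnc1	3-pyridyl_CC(=O)
*CC(=O)c1ccco1	2-furyl_CC(=O)
*CC(=O)c1cccs1	2-thienyl_CC(=O)
*CC(=O)c1cc[nH]c1	2-pyrrolyl_CC(=O)
*CC(=O)c1cnc[nH]1	imidazolyl_CC(=O)
*CC(=O)C1CC1	cyclopropyl_CC(=O)
*CC(=O)C1CCC1	cyclobutyl_CC(=O)
*CC(=O)C1CCCC1	cyclopentyl_CC(=O)
*CC(=O)C1CCCCC1	cyclohexyl_CC(=O)
*CC(=O)C1CCOC1	tetrahydrofuryl_CC(=O)
*CC(=O)C1CCNC1	pyrrolidinyl_CC(=O)
*CC(=O)N1CCOCC1	morpholino_CC(=O)
*CC(=O)N1CCNCC1	piperazinyl_CC(=O)
*CC(=O)c1ccc2ccccc2c1	2-naphthyl_CC(=O)
*C=Cc1ccccc1	phenyl_C=C
*C=Cc1ccc(O)cc1	4-hydroxyphenyl_C=C
*C=Cc1ccc(OC)cc1	4-methoxyphenyl_C=C
*C=Cc1ccc(F)cc1	4-fluorophenyl_C=C
*C=Cc1ccc(C)cc1	4-methylphenyl_C=C
*C=Cc1ccc(N)cc1	4-aminophenyl_C=C
*C=Cc1ccncc1	4-pyridyl_C=C
*C=Cc1cccnc1	3-pyridyl_C=C
*C=Cc1ccco1	2-furyl_C=C
*C=Cc1cccs1	2-thienyl_C=C
*C=Cc1cc[nH]c1	2-pyrrolyl_C=C
*C=Cc1cnc[nH]1	imidazolyl_C=C
*C=CC1CC1	cyclopropyl_C=C
*C=CC1CCC1	cyclobutyl_C=C
*C=CC1CCCC1	cyclopentyl_C=C
*C=CC1CCCCC1	cyclohexyl_C=C
*C=CC1CCOC1	tetrahydrofuryl_C=C
*C=CC1CCNC1	pyrrolidinyl_C=C
*C=CN1CCOCC1	morpholino_C=C
*C=CN1CCNCC1	piperazinyl_C=C
*C=Cc1ccc2ccccc2c1	2-naphthyl_C=C
*OCc1ccccc1	phenyl_OC
*OCc1ccc(O)cc1	4-hydroxyphenyl_OC
*OCc1ccc(OC)cc1	4-methoxyphenyl_OC
*OCc1ccc(F)cc1	4-fluorophenyl_OC
*OCc1ccc(C)cc1	4-methylphenyl_OC
*OCc1ccc(N)cc1	4-aminophenyl_OC
*OCc1ccncc1	4-pyridyl_OC
*OCc1cccnc1	3-pyridyl_OC
*OCc1ccco1	2-furyl_OC
*OCc1cccs1	2-thienyl_OC
*OCc1cc[nH]c1	2-pyrrolyl_OC
*OCc1cnc[nH]1	imidazolyl_OC
*OCC1CC1	cyclopropyl_OC
*OCC1CCC1	cyclobutyl_OC
*OCC1CCCC1	cyclopentyl_OC
*OCC1CCCCC1	cyclohexyl_OC
*OCC1CCOC1	tetrahydrofuryl_OC
*OCC1CCNC1	pyrrolidinyl_OC
*OCN1CCOCC1	morpholino_OC
*OCN1CCNCC1	piperazinyl_OC
*OCc1ccc2ccccc2c1	2-naphthyl_OC
*NCc1ccccc1	phenyl_NC
*NCc1ccc(O)cc1	4-hydroxyphenyl_NC
*NCc1ccc(OC)cc1	4-methoxyphenyl_NC
*NCc1ccc(F)cc1	4-fluorophenyl_NC
*NCc1ccc(C)cc1	4-methylphenyl_NC
*NCc1ccc(N)cc1	4-aminophenyl_NC
*NCc1ccncc1	4-pyridyl_NC
*NCc1cccnc1	3-pyridyl_NC
*NCc1ccco1	2-furyl_NC
*NCc1cccs1	2-thienyl_NC
*NCc1cc[nH]c1	2-pyrrolyl_NC
*NCc1cnc[nH]1	imidazolyl_NC
*NCC1CC1	cyclopropyl_NC
*NCC1CCC1	cyclobutyl_NC
*NCC1CCCC1	cyclopentyl_NC
*NCC1CCCCC1	cyclohexyl_NC
*NCC1CCOC1	tetrahydrofuryl_NC
*NCC1CCNC1	pyrrolidinyl_NC
*NCN1CCOCC1	morpholino_NC
*NCN1CCNCC1	piperazinyl_NC
*NCc1ccc2ccccc2c1	2-naphthyl_NC
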