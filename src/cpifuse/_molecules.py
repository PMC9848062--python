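"""Packaged fixture of 50 drug-like SMILES (common approved drugs and
fragments), used by the synthetic interaction generator and the test suite.
All strings parse with RDKit; verified by the test suite."""

DRUG_SMILES: list[str] = [
    "CC(=O)Oc1ccccc1C(=O)O",                        # aspirin
    "Cn1cnc2c1c(=O)n(C)c(=O)n2C",                   # caffeine
    "CC(C)Cc1ccc(cc1)C(C)C(=O)O",                   # ibuprofen
    "CC(=O)Nc1ccc(O)cc1",                           # paracetamol
    "Clc1ccccc1C2=NCC(=O)Nc3ccc(cc23)[N+](=O)[O-]", # clonazepam core
    "CN1C2CCC1CC(C2)OC(=O)C(CO)c1ccccc1",           # atropine
    "CN(C)CCc1c[nH]c2ccc(CC3COC(=O)N3)cc12",        # zolmitriptan-like
    "OC(=O)c1cc(O)c(O)c(O)c1",                      # gallic acid
    "Nc1ccc(cc1)S(=O)(=O)Nc1ncccn1",                # sulfadiazine
    "CC(N)Cc1ccccc1",                               # amphetamine
    "NC(=O)c1ccc[nH]1",                             # pyrrole amide
    "COc1ccc2cc(ccc2c1)C(C)C(=O)O",                 # naproxen
    "CC(C)NCC(O)COc1ccc(CC(N)=O)cc1",               # atenolol
    "CN1CCC[C@H]1c1cccnc1",                         # nicotine
    "Oc1ccc(cc1)C(=O)O",                            # 4-hydroxybenzoic acid
    "O=C(O)CCCCCCCCC=C",                            # undecylenic acid
    "Nc1ncnc2n(cnc12)C1OC(CO)C(O)C1O",              # adenosine
    "CC12CCC3c4ccc(O)cc4CCC3C1CCC2O",               # estradiol
    "CC(C)(C)NCC(O)c1ccc(O)c(CO)c1",                # salbutamol
    "CCN(CC)CCNC(=O)c1ccc(N)cc1",                   # procainamide
    "COc1cc2c(cc1OC)C(=O)C(CC2)Cc1ccn(C)c1",        # alkaloid-like
    "O=C1N(C)C(=O)N(C)c2ncn(C)c12",                 # theophylline-like
    "Clc1ccc(cc1)C(c1ccccc1)N1CCN(CCOCCO)CC1",      # hydroxyzine
    "CC(CS)C(=O)N1CCCC1C(=O)O",                     # captopril
    "NC(Cc1ccc(O)cc1)C(=O)O",                       # tyrosine
    "NC(CC(=O)O)C(=O)O",                            # aspartate
    "OCC(O)C(O)C(O)C(O)CO",                         # sorbitol
    "Nc1ccn(C2OC(CO)C(O)C2O)c(=O)n1",               # cytidine
    "CN(C)c1ccc(cc1)C(=O)O",                        # DMAB acid
    "COc1ccccc1OCCNCC(O)COc1cccc2[nH]ccc12",        # carvedilol-like
    "O=C(Nc1ccccc1)c1ccccc1",                       # benzanilide
    "Clc1ccccc1Cl",                                 # dichlorobenzene
    "c1ccc2c(c1)ccc1ccccc21",                       # phenanthrene
    "OC(=O)c1ccccc1O",                              # salicylic acid
    "CCOC(=O)c1ccccc1N",                            # benzocaine-like
    "CC(C)(C)c1ccc(O)cc1",                          # tert-butylphenol
    "O=S(=O)(N)c1ccc(Cl)cc1",                       # chlorobenzenesulfonamide
    "N#Cc1ccccc1",                                  # benzonitrile
    "CC(=O)NC1C(O)OC(CO)C(O)C1O",                   # N-acetylglucosamine
    "c1ccc(cc1)-c1ccccc1",                          # biphenyl
    "OCCN1CCN(CCCN2c3ccccc3Sc3ccc(Cl)cc23)CC1",     # perphenazine-like
    "CC1=CC(=O)CC(C)(C)C1",                         # isophorone
    "O=C1CCCCC1",                                   # cyclohexanone
    "c1ccsc1",                                      # thiophene
    "c1ccoc1",                                      # furan
    "c1cc[nH]c1",                                   # pyrrole
    "c1ccncc1",                                     # pyridine
    "C1CCNCC1",                                     # piperidine
    "C1COCCN1",                                     # morpholine
    "CC(=O)N1CCCC1",                                # N-acetylpyrrolidine
]
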