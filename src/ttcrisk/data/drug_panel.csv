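name,smiles,is_biologic,iarc_group
carmustine,ClCCN(N=O)C(=O)NCCCl,,2A
lomustine,O=NN(CCCl)C(=O)NC1CCCCC1,,2A
streptozocin,CN(N=O)C(=O)NC1C(O)OC(CO)C(O)C1O,,2B
cisplatin,N.N.Cl[Pt]Cl,,2A
carboplatin,O=C1O[Pt](N)(N)OC(=O)C12CCC2,,
oxaliplatin,O=C1O[Pt]2(OC1=O)NC1CCCCC1N2,,
arsenic trioxide,O=[As]O[As]=O,,1
rituximab,,true,
trastuzumab,,true,
cyclophosphamide,ClCCN(CCCl)P1(=O)NCCCO1,,1
ifosfamide,ClCCNP1(=O)OCCCN1CCCl,,3
5-fluorouracil,Fc1c[nH]c(=O)[nH]c1=O,,3
methotrexate,CN(Cc1cnc2nc(N)nc(N)c2n1)c1ccc(C(=O)NC(CCC(=O)O)C(=O)O)cc1,,3
chlorambucil,OC(=O)CCCc1ccc(N(CCCl)CCCl)cc1,,1
melphalan,NC(Cc1ccc(N(CCCl)CCCl)cc1)C(=O)O,,1
doxorubicin,COc1cccc2C(=O)c3c(O)c4CC(O)(CC(OC5CC(N)C(O)C(C)O5)c4c(O)c3C(=O)c12)C(=O)CO,,2A
gemcitabine,NC1=NC(=O)N(C=C1)C1OC(CO)C(O)C1(F)F,,
busulfan,CS(=O)(=O)OCCCCOS(C)(=O)=O,,1
cytarabine,NC1=NC(=O)N(C=C1)C1OC(CO)C(O)C1O,,
tamoxifen,CC/C(=C(\c1ccccc1)c1ccc(OCCN(C)C)cc1)c1ccccc1,,1
temozolomide,CN1C(=O)N2C=NC(=C2N=N1)C(N)=O,,
dacarbazine,CN(C)N=Nc1[nH]cnc1C(N)=O,,2B
hydroxyurea,NC(=O)NO,,3
thiotepa,S=P(N1CC1)(N1CC1)N1CC1,,1
mitomycin C,COC1(C)C2CN3C1C(COC(N)=O)C(=C(N)C3=O)C2=O,,2B
azoxymethane,C/N=[N+](\[O-])C,,
aflatoxin B1,COC1=C2C3=C(C(=O)CC3)C(=O)OC2=C4C5C=COC5OC4=C1,,1
"2,3,7,8-TCDD",Clc1cc2Oc3cc(Cl)c(Cl)cc3Oc2cc1Cl,,1
"PCB 77",Clc1ccc(-c2ccc(Cl)c(Cl)c2)cc1Cl,,1
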