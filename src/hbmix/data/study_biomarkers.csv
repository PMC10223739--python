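biomarker,parent_substance,family
Cd,Cadmium,element
Cr,Chromium,element
Hg,Mercury,element
Sb,Antimony,element
Se,Selenium,element
As,Arsenic,element
5-HNMP,NMP,aprotic solvent
2-HMSI,NMP,aprotic solvent
2-HESI,NEP,aprotic solvent
AAMA,Acrylamide,process contaminant
GAMA,Acrylamide,process contaminant
NMMA,CIT/MIT,biocide
TBBA,Lysmeral,fragrance
OH-MEHTP,DEHTP,phthalate substitute
oxo-MEHTP,DEHTP,phthalate substitute
cx-MEPTP,DEHTP,phthalate substitute
OH-MINCH,DINCH,phthalate substitute
oxo-MINCH,DINCH,phthalate substitute
cx-MINCH,DINCH,phthalate substitute
MEHP,DEHP,phthalate
OH-MEHP,DEHP,phthalate
oxo-MEHP,DEHP,phthalate
cx-MEPP,DEHP,phthalate
MBzP,BBzP,phthalate
MnBP,DnBP,phthalate
OH-MnBP,DnBP,phthalate
MiBP,DiBP,phthalate
OH-MiBP,DiBP,phthalate
MEP,DEP,phthalate
OH-MiNP,DiNP,phthalate
oxo-MiNP,DiNP,phthalate
cx-MiNP,DiNP,phthalate
OH-MiDP,DiDP,phthalate
oxo-MiDP,DiDP,phthalate
cx-MiDP,DiDP,phthalate
MMP,DMP,phthalate
oxo-MPHP,DPHP,phthalate
BHT,BHT,antioxidant
SPMA,Benzene,aromatic solvent
1-NAPH,Naphthalene,PAH
2-NAPH,Naphthalene,PAH
2-FLUO,Fluorene,PAH
1-PHEN,Phenanthrene,PAH
2-PHEN,Phenanthrene,PAH
3-PHEN,Phenanthrene,PAH
4-PHEN,Phenanthrene,PAH
9-PHEN,Phenanthrene,PAH
1-OH-PYR,Pyrene,PAH
MeP,Methylparaben,paraben
EP,Ethylparaben,paraben
BPA,Bisphenol A,phenol
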