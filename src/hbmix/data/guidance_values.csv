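substance,label,biomarkers,value,units,age_min,age_max,population,value_type,source_tier
BBzP,BBzP (MBzP),MBzP,2000,ug/L,,,general,HBM-GV,1
DiBP,DiBP (MiBP),MiBP,160,ug/L,,,general,HBM-GV,1
DnBP,DnBP (MnBP),MnBP,120,ug/L,,,general,HBM-GV,1
DEHP,DEHP Sum 1 (OH-MEHP + oxo-MEHP),OH-MEHP;oxo-MEHP,340,ug/L,,,general,HBM-GV,1
DEHP,DEHP Sum 2 (OH-MEHP + cx-MEPP),OH-MEHP;cx-MEPP,380,ug/L,,,general,HBM-GV,1
DINCH,DINCH Sum (oxo-MINCH + cx-MINCH),oxo-MINCH;cx-MINCH,3000,ug/L,,,general,HBM-GV,1
DPHP,DPHP (oxo-MPHP),oxo-MPHP,190,ug/L,,,general,HBM-GV,1
DEHTP,DEHTP (cx-MEPTP),cx-MEPTP,1800,ug/L,,,general,HBM-I,3
Mercury,Mercury (Hg),Hg,7,ug/L,,,general,HBM-I,3
Cadmium,Cadmium (Cd) 10 years and younger,Cd,0.1,ug/g creatinine,0,10,general,HBM-GV,1
Cadmium,Cadmium (Cd) 11-20 years,Cd,0.2,ug/g creatinine,11,20,general,HBM-GV,1
Bisphenol A,Bisphenol A (BPA),BPA,135,ug/L,,,general,HBM-GV,1
NMP,NMP Sum (5-HNMP + 2-HMSI),5-HNMP;2-HMSI,10000,ug/L,,,general,HBM-GV,1
Pyrene,Pyrene (1-OH-PYR),1-OH-PYR,4,umol/mol creatinine,,,occupational,BMGV,3
Chromium,Chromium (Cr),Cr,10,umol/mol creatinine,,,occupational,BMGV,3
Acrylamide,Acrylamide (AAMA),AAMA,13,ug/L,,,general,BE,4
Arsenic,Arsenic (As total),As,6.4,ug/L,,,general,BE,4
Selenium,Selenium (Se),Se,90,ug/L,,,general,BE,4
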