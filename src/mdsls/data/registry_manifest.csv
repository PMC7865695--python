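name,category,statistic,channel,population,analysis_eligible
RBC,CBC,NA,NA,NA,False
Hb,CBC,NA,NA,NA,False
Hct,CBC,NA,NA,NA,False
MCV,CBC,NA,NA,NA,False
MCH,CBC,NA,NA,NA,False
MCHC,CBC,NA,NA,NA,False
RDW,CBC,NA,NA,NA,False
Plt,CBC,NA,NA,NA,False
MPV,CBC,NA,NA,NA,False
MPC,CBC,NA,NA,NA,False
WBC,CBC,NA,NA,NA,False
% NE,CBC,NA,NA,NA,False
% LY,CBC,NA,NA,NA,False
% MO,CBC,NA,NA,NA,False
% EO,CBC,NA,NA,NA,False
% BA,CBC,NA,NA,NA,False
Abs NE,CBC,NA,NA,NA,False
Abs LY,CBC,NA,NA,NA,False
Abs MO,CBC,NA,NA,NA,False
Abs EO,CBC,NA,NA,NA,False
Abs BA,CBC,NA,NA,NA,False
% NRBC,CBC,NA,NA,NA,False
Abs NRBC,CBC,NA,NA,NA,False
MN-V-NE,CPD,MN,V,NE,True
MN-V-LY,CPD,MN,V,LY,True
MN-V-MO,CPD,MN,V,MO,True
MN-V-EO,CPD,MN,V,EO,True
MN-V-NRBC,CPD,MN,V,NRBC,True
MN-V-NNRBC,CPD,MN,V,NNRBC,True
MN-V-RET,CPD,MN,V,RET,False
MN-C-NE,CPD,MN,C,NE,True
MN-C-LY,CPD,MN,C,LY,True
MN-C-MO,CPD,MN,C,MO,True
MN-C-EO,CPD,MN,C,EO,True
MN-C-NRBC,CPD,MN,C,NRBC,True
MN-C-NNRBC,CPD,MN,C,NNRBC,True
MN-C-RET,CPD,MN,C,RET,False
MN-MALS-NE,CPD,MN,MALS,NE,True
MN-MALS-LY,CPD,MN,MALS,LY,True
MN-MALS-MO,CPD,MN,MALS,MO,True
MN-MALS-EO,CPD,MN,MALS,EO,True
MN-MALS-NRBC,CPD,MN,MALS,NRBC,True
MN-MALS-NNRBC,CPD,MN,MALS,NNRBC,True
MN-MALS-RET,CPD,MN,MALS,RET,False
MN-UMALS-NE,CPD,MN,UMALS,NE,True
MN-UMALS-LY,CPD,MN,UMALS,LY,True
MN-UMALS-MO,CPD,MN,UMALS,MO,True
MN-UMALS-EO,CPD,MN,UMALS,EO,True
MN-UMALS-NRBC,CPD,MN,UMALS,NRBC,True
MN-UMALS-NNRBC,CPD,MN,UMALS,NNRBC,True
MN-UMALS-RET,CPD,MN,UMALS,RET,False
MN-LMALS-NE,CPD,MN,LMALS,NE,True
MN-LMALS-LY,CPD,MN,LMALS,LY,True
MN-LMALS-MO,CPD,MN,LMALS,MO,True
MN-LMALS-EO,CPD,MN,LMALS,EO,True
MN-LMALS-NRBC,CPD,MN,LMALS,NRBC,True
MN-LMALS-NNRBC,CPD,MN,LMALS,NNRBC,True
MN-LMALS-RET,CPD,MN,LMALS,RET,False
MN-LALS-NE,CPD,MN,LALS,NE,True
MN-LALS-LY,CPD,MN,LALS,LY,True
MN-LALS-MO,CPD,MN,LALS,MO,True
MN-LALS-EO,CPD,MN,LALS,EO,True
MN-LALS-NRBC,CPD,MN,LALS,NRBC,True
MN-LALS-NNRBC,CPD,MN,LALS,NNRBC,True
MN-LALS-RET,CPD,MN,LALS,RET,False
MN-AL2-NE,CPD,MN,AL2,NE,True
MN-AL2-LY,CPD,MN,AL2,LY,True
MN-AL2-MO,CPD,MN,AL2,MO,True
MN-AL2-EO,CPD,MN,AL2,EO,True
MN-AL2-NRBC,CPD,MN,AL2,NRBC,True
MN-AL2-NNRBC,CPD,MN,AL2,NNRBC,True
MN-AL2-RET,CPD,MN,AL2,RET,False
SD-V-NE,CPD,SD,V,NE,True
SD-V-LY,CPD,SD,V,LY,True
SD-V-MO,CPD,SD,V,MO,True
SD-V-EO,CPD,SD,V,EO,True
SD-V-NRBC,CPD,SD,V,NRBC,True
SD-V-NNRBC,CPD,SD,V,NNRBC,True
SD-V-RET,CPD,SD,V,RET,False
SD-C-NE,CPD,SD,C,NE,True
SD-C-LY,CPD,SD,C,LY,True
SD-C-MO,CPD,SD,C,MO,True
SD-C-EO,CPD,SD,C,EO,True
SD-C-NRBC,CPD,SD,C,NRBC,True
SD-C-NNRBC,CPD,SD,C,NNRBC,True
SD-C-RET,CPD,SD,C,RET,False
SD-MALS-NE,CPD,SD,MALS,NE,True
SD-MALS-LY,CPD,SD,MALS,LY,True
SD-MALS-MO,CPD,SD,MALS,MO,True
SD-MALS-EO,CPD,SD,MALS,EO,True
SD-MALS-NRBC,CPD,SD,MALS,NRBC,True
SD-MALS-NNRBC,CPD,SD,MALS,NNRBC,True
SD-MALS-RET,CPD,SD,MALS,RET,False
SD-UMALS-NE,CPD,SD,UMALS,NE,True
SD-UMALS-LY,CPD,SD,UMALS,LY,True
SD-UMALS-MO,CPD,SD,UMALS,MO,True
SD-UMALS-EO,CPD,SD,UMALS,EO,True
SD-UMALS-NRBC,CPD,SD,UMALS,NRBC,True
SD-UMALS-NNRBC,CPD,SD,UMALS,NNRBC,True
SD-UMALS-RET,CPD,SD,UMALS,RET,False
SD-LMALS-NE,CPD,SD,LMALS,NE,True
SD-LMALS-LY,CPD,SD,LMALS,LY,True
SD-LMALS-MO,CPD,SD,LMALS,MO,True
SD-LMALS-EO,CPD,SD,LMALS,EO,True
SD-LMALS-NRBC,CPD,SD,LMALS,NRBC,True
SD-LMALS-NNRBC,CPD,SD,LMALS,NNRBC,True
SD-LMALS-RET,CPD,SD,LMALS,RET,False
SD-LALS-NE,CPD,SD,LALS,NE,True
SD-LALS-LY,CPD,SD,LALS,LY,True
SD-LALS-MO,CPD,SD,LALS,MO,True
SD-LALS-EO,CPD,SD,LALS,EO,True
SD-LALS-NRBC,CPD,SD,LALS,NRBC,True
SD-LALS-NNRBC,CPD,SD,LALS,NNRBC,True
SD-LALS-RET,CPD,SD,LALS,RET,False
SD-AL2-NE,CPD,SD,AL2,NE,True
SD-AL2-LY,CPD,SD,AL2,LY,True
SD-AL2-MO,CPD,SD,AL2,MO,True
SD-AL2-EO,CPD,SD,AL2,EO,True
SD-AL2-NRBC,CPD,SD,AL2,NRBC,True
SD-AL2-NNRBC,CPD,SD,AL2,NNRBC,True
SD-AL2-RET,CPD,SD,AL2,RET,False
LHD,RUO,NA,NA,NA,True
MAF,RUO,NA,NA,NA,False
PDW,RUO,NA,NA,NA,True
EGC,RUO,NA,NA,NA,True
WNOP,RUO,NA,NA,NA,True
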