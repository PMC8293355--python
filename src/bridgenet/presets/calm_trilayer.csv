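,MR,Pea,Spell,Read,NO,DR,BDR,Dot,MrX,Ins,CAC,CMF,FP,MOF,RAC,RMF,SFG,STG,SMG,TTG,ATR,CST,CING,CINGh,FMaj,FMin,IFOF,ILF,SLF,UNC,Age
MR,0.00,0.15,0.00,0.00,0.18,0.08,0.04,0.09,0.06,0.07,0.00,0.00,0.00,0.00,0.00,0.08,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.05
Pea,0.15,0.00,0.09,0.12,0.16,0.11,0.06,0.03,0.07,0.05,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.08,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.05
Spell,0.00,0.09,0.00,0.63,0.08,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.05,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.05
Read,0.00,0.12,0.63,0.00,0.09,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.10,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.05
NO,0.18,0.16,0.08,0.09,0.00,0.07,0.10,0.13,0.02,0.03,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.08,0.00,0.00,0.00,0.00,0.05
DR,0.08,0.11,0.00,0.00,0.07,0.00,0.27,0.04,0.12,0.10,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,-0.05,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.05
BDR,0.04,0.06,0.00,0.00,0.10,0.27,0.00,0.07,0.14,0.02,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,-0.06,0.00,0.00,0.00,0.05
Dot,0.09,0.03,0.00,0.00,0.13,0.04,0.07,0.00,0.20,0.05,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.06,0.00,0.05
MrX,0.06,0.07,0.00,0.00,0.02,0.12,0.14,0.20,0.00,0.08,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.05,0.00,0.00,0.05
Ins,0.07,0.05,0.00,0.00,0.03,0.10,0.02,0.05,0.08,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.15,0.00,0.00,0.00,0.00,0.05
CAC,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.30,0.00,0.18,0.00,0.15,0.24,0.08,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.03
CMF,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,-0.15,0.17,0.00,0.21,0.25,0.00,0.00,0.11,0.00,0.06,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.03
FP,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,-0.15,0.00,0.09,0.00,0.10,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,-0.10,0.03
MOF,0.00,0.00,0.05,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.17,0.09,0.00,0.22,0.26,0.00,0.12,0.10,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.08,0.03
RAC,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.30,0.00,0.00,0.22,0.00,0.08,0.00,0.20,0.00,0.14,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.03
RMF,0.08,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.21,0.10,0.26,0.08,0.00,0.16,0.13,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.07,0.00,0.00,0.00,0.00,0.03
SFG,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.18,0.25,0.00,0.00,0.00,0.16,0.00,0.00,0.00,0.28,0.06,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.03
STG,0.00,0.08,0.00,0.10,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.12,0.20,0.13,0.00,0.00,0.52,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.08,0.00,0.00,0.03
SMG,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.15,0.00,0.00,0.10,0.00,0.00,0.00,0.52,0.00,0.19,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.10,0.00,0.03
TTG,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.24,0.11,0.00,0.00,0.14,0.00,0.28,0.00,0.19,0.00,0.00,0.00,0.05,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.03
ATR,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.08,0.00,0.00,0.00,0.00,0.00,0.06,0.00,0.00,0.00,0.00,0.30,0.18,0.00,0.06,0.00,0.12,0.00,0.00,0.08,0.03
CST,0.00,0.00,0.00,0.00,0.00,-0.05,0.00,0.00,0.00,0.00,0.00,0.06,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.30,0.00,0.13,0.16,0.09,0.00,0.07,0.00,0.00,0.00,0.03
CING,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.05,0.18,0.13,0.00,0.28,0.00,0.00,0.07,0.00,0.00,0.08,0.03
CINGh,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.16,0.28,0.00,0.00,0.14,0.00,0.11,0.00,0.00,0.03
FMaj,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.06,0.09,0.00,0.00,0.00,0.44,0.00,0.00,0.00,0.15,0.03
FMin,0.00,0.00,0.00,0.00,0.08,0.00,0.00,0.00,0.00,0.15,0.00,0.00,0.00,0.00,0.00,0.07,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.14,0.44,0.00,0.00,0.00,0.10,0.00,0.03
IFOF,0.00,0.00,0.00,0.00,0.00,0.00,-0.06,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.12,0.07,0.07,0.00,0.00,0.00,0.00,0.26,0.22,0.00,0.03
ILF,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.05,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.08,0.00,0.00,0.00,0.00,0.00,0.11,0.00,0.00,0.26,0.00,0.12,0.20,0.03
SLF,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.06,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.10,0.00,0.00,0.00,0.00,0.00,0.00,0.10,0.22,0.12,0.00,0.24,0.03
UNC,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,-0.10,0.08,0.00,0.00,0.00,0.00,0.00,0.00,0.08,0.00,0.08,0.00,0.15,0.00,0.00,0.20,0.24,0.00,0.03
Age,0.05,0.05,0.05,0.05,0.05,0.05,0.05,0.05,0.05,0.05,0.03,0.03,0.03,0.03,0.03,0.03,0.03,0.03,0.03,0.03,0.03,0.03,0.03,0.03,0.03,0.03,0.03,0.03,0.03,0.03,0.00
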