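,ATR,CST,CING,CINGh,FMaj,FMin,IFOF,ILF,SLF,UNC,Age
ATR,0.00,0.30,0.18,0.00,0.06,0.00,0.12,0.00,0.00,0.08,0.05
CST,0.30,0.00,0.13,0.16,0.09,0.00,0.07,0.00,0.00,0.00,0.05
CING,0.18,0.13,0.00,0.28,0.00,0.00,0.07,0.00,0.00,0.08,0.05
CINGh,0.00,0.16,0.28,0.00,0.00,0.14,0.00,0.11,0.00,0.00,0.05
FMaj,0.06,0.09,0.00,0.00,0.00,0.44,0.00,0.00,0.00,0.15,0.05
FMin,0.00,0.00,0.00,0.14,0.44,0.00,0.00,0.00,0.10,0.00,0.05
IFOF,0.12,0.07,0.07,0.00,0.00,0.00,0.00,0.26,0.22,0.00,0.05
ILF,0.00,0.00,0.00,0.11,0.00,0.00,0.26,0.00,0.12,0.20,0.05
SLF,0.00,0.00,0.00,0.00,0.00,0.10,0.22,0.12,0.00,0.24,0.05
UNC,0.08,0.00,0.08,0.00,0.15,0.00,0.00,0.20,0.24,0.00,0.05
Age,0.05,0.05,0.05,0.05,0.05,0.05,0.05,0.05,0.05,0.05,0.00
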