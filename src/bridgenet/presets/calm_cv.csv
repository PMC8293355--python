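,CAC,CMF,FP,MOF,RAC,RMF,SFG,STG,SMG,TTG,Age
CAC,0.00,0.00,0.00,0.00,0.30,0.00,0.18,0.00,0.15,0.24,0.05
CMF,0.00,0.00,-0.15,0.17,0.00,0.21,0.25,0.00,0.00,0.11,0.05
FP,0.00,-0.15,0.00,0.09,0.00,0.10,0.00,0.00,0.00,0.00,0.05
MOF,0.00,0.17,0.09,0.00,0.22,0.26,0.00,0.12,0.10,0.00,0.05
RAC,0.30,0.00,0.00,0.22,0.00,0.08,0.00,0.20,0.00,0.14,0.05
RMF,0.00,0.21,0.10,0.26,0.08,0.00,0.16,0.13,0.00,0.00,0.05
SFG,0.18,0.25,0.00,0.00,0.00,0.16,0.00,0.00,0.00,0.28,0.05
STG,0.00,0.00,0.00,0.12,0.20,0.13,0.00,0.00,0.52,0.00,0.05
SMG,0.15,0.00,0.00,0.10,0.00,0.00,0.00,0.52,0.00,0.19,0.05
TTG,0.24,0.11,0.00,0.00,0.14,0.00,0.28,0.00,0.19,0.00,0.05
Age,0.05,0.05,0.05,0.05,0.05,0.05,0.05,0.05,0.05,0.05,0.00
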