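,MR,Pea,Spell,Read,NO,DR,BDR,Dot,MrX,Ins,Age
MR,0.00,0.15,0.00,0.00,0.18,0.08,0.04,0.09,0.06,0.07,0.06
Pea,0.15,0.00,0.09,0.12,0.16,0.11,0.06,0.03,0.07,0.05,0.06
Spell,0.00,0.09,0.00,0.63,0.08,0.00,0.00,0.00,0.00,0.00,0.06
Read,0.00,0.12,0.63,0.00,0.09,0.00,0.00,0.00,0.00,0.00,0.06
NO,0.18,0.16,0.08,0.09,0.00,0.07,0.10,0.13,0.02,0.03,0.06
DR,0.08,0.11,0.00,0.00,0.07,0.00,0.27,0.04,0.12,0.10,0.06
BDR,0.04,0.06,0.00,0.00,0.10,0.27,0.00,0.07,0.14,0.02,0.06
Dot,0.09,0.03,0.00,0.00,0.13,0.04,0.07,0.00,0.20,0.05,0.06
MrX,0.06,0.07,0.00,0.00,0.02,0.12,0.14,0.20,0.00,0.08,0.06
Ins,0.07,0.05,0.00,0.00,0.03,0.10,0.02,0.05,0.08,0.00,0.06
Age,0.06,0.06,0.06,0.06,0.06,0.06,0.06,0.06,0.06,0.06,0.00
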