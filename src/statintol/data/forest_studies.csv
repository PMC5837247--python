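study,or,ci_lo,ci_hi,n
GoDARTS (LDI),1.43,1.10,1.86,1034
CPRD-STAGE (SIM),1.03,0.72,1.49,2630
PREDICTION-ADR (SIM),1.48,1.05,2.10,661
JUPITER (myalgia),1.35,1.07,1.71,8749
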