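condition,duration_fs,rate_per_frame,stderr
HCage 620,200,1.24,0.16
HCage 620,400,0.62,0.01
HCage 620,1200,0.12,0.01
ONB-2SiR,200,1.33,0.08
ONB-2SiR,400,0.72,0.02
ONB-2SiR,1200,0.23,0.02
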