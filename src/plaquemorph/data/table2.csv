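specimen_id,group,cvf,spherical,sheet,irregular
P1,LS,0.11,158,1,12
P2,LS,0.32,88,2,1
P3,LS,0.08,106,3,7
P4,MS,0.19,23,1,1
P5,MS,0.13,17,-,4
P6,HS,0.52,113,-,1
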