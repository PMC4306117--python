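specimen_id,group,initial_stiffness_MPa,cauchy_stress_MPa,stretch_ratio,calc_col,lip_col,cvf,surface_area_mm2
P1,LS,0.6,0.24,1.43,0.24,0.67,0.11,15.05
P2,LS,0.65,0.45,1.68,0.63,1.55,0.32,31.58
P3,LS,0.75,0.33,1.33,0.66,0.97,0.08,9.41
P4,MS,1.25,0.44,1.35,0.68,0.41,0.19,10.73
P5,MS,1.6,0.49,1.45,0.22,0.36,0.13,9.55
P6,HS,3.79,0.40,1.4,0.30,0.20,0.52,130.85
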