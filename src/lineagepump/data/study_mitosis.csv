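experiment,fa_rate_dividing,fa_rate_nondividing,pfa,fmc_rate_dividing,fmc_rate_nondividing,pfmc
a,49.0,76.9,0.64,61.1,120.1,0.51
a*,45.6,35.6,1.28,45.6,35.6,
b,89.4,73.3,1.22,113.5,153.3,0.74
c,66.7,29.9,2.23,51.4,11.4,4.51
d,75.0,65.8,1.88,102.0,100.1,1.02
e,39.9,15.8,2.53,73.0,50.0,1.46
f,45.6,32.6,1.40,49.1,39.2,1.25
g,64.9,42.1,1.54,94.0,65.9,1.43
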