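experiment,tau_fa,tau_fmc,grouping
a,0.55,0.53,all
b,0.15,0.11,all
c,0.76,0.68,all
d,0.51,0.45,all
e,0.13,0.08,all
f,0.55,0.51,all
g,0.54,0.41,all
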