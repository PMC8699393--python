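experiment,tau_fa,tau_fmc,grouping
a,0.10,0.18,starting+first
b,0.02,-0.02,starting+first
c,0.25,0.19,starting+first
d,0.06,0.04,starting+first
e,0.08,0.06,all
f,0.19,0.15,all
g,0.11,0.02,starting+first+second
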