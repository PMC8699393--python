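experiment,tau_fa,tau_fmc,grouping
a,-0.19,-0.22,starting+first
b,-0.02,-0.05,starting+first
c,-0.35,-0.36,starting+first
d,-0.24,-0.23,starting+first
e,0.10,0.16,starting+first
f,-0.12,-0.16,starting+first
g,-0.22,-0.18,starting+first
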