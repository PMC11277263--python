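#PPM n=100
A	0.050000	0.050000	0.050000	0.050000	0.050000	0.050000	0.050000	0.050000	0.050000	0.050000	0.050000	0.050000	0.050000	0.050000	0.050000	0.050000
C	0.850000	0.050000	0.850000	0.850000	0.050000	0.850000	0.850000	0.050000	0.850000	0.850000	0.050000	0.850000	0.850000	0.050000	0.850000	0.850000
G	0.050000	0.850000	0.050000	0.050000	0.850000	0.050000	0.050000	0.850000	0.050000	0.050000	0.850000	0.050000	0.050000	0.850000	0.050000	0.050000
T	0.050000	0.050000	0.050000	0.050000	0.050000	0.050000	0.050000	0.050000	0.050000	0.050000	0.050000	0.050000	0.050000	0.050000	0.050000	0.050000
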