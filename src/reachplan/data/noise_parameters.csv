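subject,k1,k2
A,0.180,0.660
B,0.300,0.740
C,0.100,0.590
D,0.710,1.070
E,0.530,0.740
F,0.660,0.720
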