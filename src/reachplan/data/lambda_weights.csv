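subject,direction,lam
A,front,1.44e6
B,front,2.03e6
C,front,5.82e5
D,front,9.37e5
E,front,1.60e5
F,front,6.18e5
A,back,1.24e6
B,back,1.15e6
C,back,5.49e5
D,back,6.39e5
E,back,2.14e5
F,back,3.77e5
A,left,2.58e6
B,left,2.12e6
C,left,1.61e6
D,left,3.01e6
E,left,1.90e5
F,left,8.27e5
A,right,3.05e6
B,right,1.88e6
C,right,1.62e6
D,right,3.13e6
E,right,2.31e5
F,right,5.57e5
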