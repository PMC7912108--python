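subject,direction,L1,L2,S1,S2,m1,m2,I1,I2,B11,B12,B21,B22
A,front,0.281,0.351,0.105,0.171,1.390,1.871,0.024,0.049,0.653,0.180,0.180,0.784
B,front,0.261,0.323,0.097,0.158,1.284,1.788,0.019,0.039,0.658,0.178,0.178,0.776
C,front,0.296,0.329,0.111,0.161,1.472,1.806,0.028,0.041,0.651,0.177,0.177,0.769
D,front,0.326,0.335,0.124,0.164,1.636,1.825,0.039,0.043,0.658,0.177,0.177,0.771
E,front,0.273,0.316,0.102,0.155,1.348,1.768,0.022,0.037,0.644,0.176,0.176,0.766
F,front,0.260,0.305,0.096,0.150,1.276,1.736,0.018,0.034,0.651,0.177,0.177,0.767
A,back,0.281,0.351,0.105,0.171,1.390,1.871,0.024,0.049,0.636,0.182,0.182,0.794
B,back,0.261,0.323,0.097,0.158,1.284,1.788,0.019,0.039,0.643,0.181,0.181,0.789
C,back,0.296,0.329,0.111,0.161,1.472,1.806,0.028,0.041,0.642,0.179,0.179,0.779
D,back,0.326,0.335,0.124,0.164,1.636,1.825,0.039,0.043,0.647,0.180,0.180,0.785
E,back,0.273,0.316,0.102,0.155,1.348,1.768,0.022,0.037,0.638,0.177,0.177,0.772
F,back,0.260,0.305,0.096,0.150,1.276,1.736,0.018,0.034,0.642,0.178,0.178,0.776
A,left,0.281,0.351,0.105,0.171,1.390,1.871,0.024,0.049,0.689,0.177,0.177,0.770
B,left,0.261,0.323,0.097,0.158,1.284,1.788,0.019,0.039,0.679,0.177,0.177,0.771
C,left,0.296,0.329,0.111,0.161,1.472,1.806,0.028,0.041,0.667,0.176,0.176,0.766
D,left,0.326,0.335,0.124,0.164,1.636,1.825,0.039,0.043,0.684,0.177,0.177,0.770
E,left,0.273,0.316,0.102,0.155,1.348,1.768,0.022,0.037,0.652,0.176,0.176,0.764
F,left,0.260,0.305,0.096,0.150,1.276,1.736,0.018,0.034,0.663,0.177,0.177,0.769
A,right,0.281,0.351,0.105,0.171,1.390,1.871,0.024,0.049,0.684,0.177,0.177,0.768
B,right,0.261,0.323,0.097,0.158,1.284,1.788,0.019,0.039,0.675,0.177,0.177,0.770
C,right,0.296,0.329,0.111,0.161,1.472,1.806,0.028,0.041,0.664,0.176,0.176,0.767
D,right,0.326,0.335,0.124,0.164,1.636,1.825,0.039,0.043,0.684,0.177,0.177,0.770
E,right,0.273,0.316,0.102,0.155,1.348,1.768,0.022,0.037,0.651,0.176,0.176,0.764
F,right,0.260,0.305,0.096,0.150,1.276,1.736,0.018,0.034,0.660,0.177,0.177,0.769
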