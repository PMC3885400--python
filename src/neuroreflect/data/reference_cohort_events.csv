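rat_id,fluence_J_cm2,scattering_change,eeg_suppression,long_hypoxemia,heme_reduction
1,0.75,0,0,0,0
2,0.75,1,1,1,1
3,0.75,0,0,0,0
4,0.75,1,1,1,1
5,0.75,0,0,0,0
1,1.0,1,1,0,0
2,1.0,0,0,0,0
3,1.0,1,1,1,1
4,1.0,1,1,1,0
5,1.0,1,1,1,1
6,1.0,1,1,1,1
7,1.0,1,1,1,0
8,1.0,1,1,1,1
9,1.0,0,0,0,0
10,1.0,0,0,0,0
11,1.0,1,1,1,1
12,1.0,1,1,1,1
1,1.25,1,1,1,1
2,1.25,1,1,1,1
3,1.25,1,1,1,1
4,1.25,1,1,0,1
5,1.25,1,1,1,1
1,1.5,1,1,0,0
2,1.5,1,1,1,1
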