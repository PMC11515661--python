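construct,reporter,mean,cv_percent,cv_sd_percent
L0 (P_TEF1),yEGFP,1560,11.8,0.5
U5,yEGFP,261,12.4,0.6
M1Ug,yEGFP,408,13.1,0.6
M3g,yEGFP,226,16.0,0.4
G10,yEGFP,448,12.9,0.5
G14,yEGFP,,,
M3Wn,yEGFP,,,
M3n,yEGFP,,,
M3Un,yEGFP,,,
L0 (P_PAB1),yEGFP,288,13.8,0.2
L0 (P_TEF1),ymNeonGreen,3050,12.2,0.3
U5,ymNeonGreen,,,
M1Ug,ymNeonGreen,,,
M3g,ymNeonGreen,,,
G10,ymNeonGreen,,,
G14,ymNeonGreen,317,15.4,1.5
M3Wn,ymNeonGreen,1143,13.1,0.8
M3n,ymNeonGreen,579,13.3,0.5
M3Un,ymNeonGreen,377,13.9,0.6
L0 (P_PAB1),ymNeonGreen,495,13.7,0.4
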