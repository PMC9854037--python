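r_cm,ch12_geant4,ch12_egsnrc,ch3_geant4,ch3_egsnrc
0.25,0.963,0.965,0.964,0.969
0.5,1.037,1.035,1.033,1.039
0.75,1.015,1.01,1.011,1.015
1.0,1.0,1.0,1.0,1.0
1.5,0.991,0.991,0.989,0.994
2.0,0.981,0.982,0.981,0.985
2.5,0.971,0.973,0.972,0.976
3.0,0.966,0.965,0.963,0.967
4.0,0.95,0.947,0.947,0.95
5.0,0.936,0.931,0.935,0.933
6.0,0.917,0.914,0.921,0.916
7.0,0.898,0.898,0.901,0.9
8.0,0.883,0.882,0.885,0.884
10.0,0.852,0.85,0.849,0.853
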