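theta_deg,0.25,0.5,0.75,1.0,1.5,2.0,2.5,3.0,4.0,5.0,6.0,7.0,8.0,10.0
0.0,0.717,0.945,0.951,0.95,0.954,0.928,0.932,0.969,0.952,0.936,0.94,0.968,0.946,0.935
5.0,0.711,0.941,0.954,0.96,0.961,0.954,0.975,0.965,0.978,0.964,0.949,0.97,0.946,0.958
10.0,0.705,0.948,0.956,0.967,0.965,0.97,0.973,0.971,0.964,0.969,0.968,0.978,0.955,0.96
15.0,0.787,0.942,0.953,0.963,0.963,0.964,0.967,0.968,0.968,0.966,0.97,0.973,0.962,0.968
20.0,0.76,0.942,0.967,0.972,0.962,0.966,0.969,0.963,0.961,0.959,0.967,0.974,0.969,0.967
25.0,0.733,0.947,0.96,0.972,0.963,0.969,0.961,0.97,0.97,0.961,0.973,0.977,0.97,0.965
30.0,0.774,0.948,0.97,0.977,0.964,0.974,0.973,0.969,0.975,0.97,0.968,0.975,0.976,0.981
40.0,0.803,0.972,0.983,0.99,0.98,0.979,0.984,0.979,0.986,0.985,0.977,0.982,0.991,0.984
50.0,0.884,0.984,0.987,0.987,0.988,0.994,0.987,0.991,0.988,0.991,0.991,0.986,0.993,0.99
60.0,0.941,0.994,0.994,0.994,0.992,0.996,0.992,0.996,0.993,0.993,0.995,0.996,1.0,0.994
70.0,0.972,0.998,0.991,1.002,0.992,0.993,0.999,0.998,1.002,0.995,1.0,0.994,1.002,1.0
80.0,0.991,1.002,0.995,1.0,0.995,0.998,1.002,1.001,1.0,0.997,0.998,1.0,1.0,1.0
90.0,1.0,1.0,1.0,1.0,1.0,1.0,1.0,1.0,1.0,1.0,1.0,1.0,1.0,1.0
100.0,0.995,0.997,0.996,1.004,0.999,0.998,1.001,1.0,1.003,0.999,0.999,1.001,1.003,0.998
110.0,0.978,0.998,1.0,0.995,0.996,0.997,0.999,1.001,0.998,0.993,0.999,0.994,1.002,1.002
120.0,0.949,0.994,0.994,0.998,0.993,0.994,0.994,0.995,0.998,0.998,0.995,0.998,0.994,0.995
130.0,0.921,0.983,0.991,0.993,0.987,0.995,0.99,0.994,0.991,0.987,0.99,0.994,0.995,0.994
140.0,0.834,0.977,0.979,0.992,0.982,0.983,0.984,0.983,0.985,0.981,0.981,0.985,0.985,0.983
150.0,0.825,0.945,0.968,0.969,0.967,0.975,0.975,0.972,0.973,0.968,0.973,0.975,0.973,0.972
155.0,,0.912,0.95,0.959,0.954,0.962,0.963,0.961,0.961,0.961,0.96,0.959,0.962,0.969
160.0,,0.859,0.947,0.946,0.937,0.945,0.949,0.948,0.941,0.949,0.945,0.947,0.943,0.939
165.0,,0.802,0.921,0.927,0.921,0.922,0.924,0.927,0.932,0.931,0.928,0.935,0.932,0.933
170.0,,,0.915,0.923,0.907,0.915,0.918,0.92,0.925,0.925,0.919,0.917,0.927,0.924
175.0,,,,,,0.929,0.922,0.92,0.92,0.923,0.927,0.928,0.907,0.931
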