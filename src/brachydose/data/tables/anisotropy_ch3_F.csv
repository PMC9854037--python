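theta_deg,0.25,0.5,0.75,1.0,1.5,2.0,2.5,3.0,4.0,5.0,6.0,7.0,8.0,10.0
0.0,0.698,0.943,0.954,0.965,0.951,0.93,0.93,0.962,0.937,0.957,0.949,0.957,0.946,0.932
5.0,0.697,0.944,0.968,0.968,0.961,0.96,0.965,0.963,0.97,0.961,0.958,0.956,0.951,0.955
10.0,0.687,0.947,0.966,0.975,0.974,0.968,0.962,0.968,0.966,0.963,0.956,0.966,0.952,0.972
15.0,0.771,0.952,0.973,0.973,0.966,0.962,0.964,0.973,0.971,0.969,0.961,0.96,0.961,0.973
20.0,0.741,0.945,0.969,0.97,0.969,0.971,0.974,0.963,0.975,0.961,0.966,0.98,0.965,0.972
25.0,0.799,0.951,0.975,0.98,0.972,0.975,0.971,0.974,0.97,0.972,0.97,0.984,0.972,0.972
30.0,0.77,0.959,0.977,0.981,0.977,0.981,0.979,0.978,0.98,0.975,0.972,0.981,0.976,0.969
40.0,0.806,0.973,0.984,0.984,0.986,0.984,0.986,0.986,0.991,0.983,0.978,0.988,0.985,0.988
50.0,0.892,0.992,0.988,0.986,0.997,0.995,0.993,0.994,0.995,0.993,0.984,0.991,0.989,0.992
60.0,0.945,0.996,0.991,0.996,1.001,1.005,0.993,0.998,1.0,0.996,0.989,0.995,0.993,0.995
70.0,0.978,1.0,0.999,0.998,1.0,1.0,0.998,1.001,1.0,0.992,0.99,0.991,0.993,0.993
80.0,0.995,1.004,1.0,0.999,1.006,1.331,1.002,1.002,1.001,1.0,0.992,0.994,1.0,1.0
90.0,1.0,1.0,1.0,1.0,1.0,1.0,1.0,1.0,1.0,1.0,1.0,1.0,1.0,1.0
100.0,0.994,1.001,1.0,1.003,1.001,1.332,1.004,1.002,1.001,0.996,0.994,0.998,0.995,0.997
110.0,0.98,0.998,0.995,0.998,1.001,1.004,1.0,1.002,1.002,0.996,0.987,0.991,0.998,0.999
120.0,0.951,0.999,0.991,0.994,0.997,1.0,0.999,0.999,0.996,0.995,0.99,0.995,0.995,0.993
130.0,0.931,0.995,0.991,0.989,0.995,0.996,0.993,0.997,0.996,0.994,0.983,0.996,0.993,0.988
140.0,0.839,0.985,0.988,0.986,0.992,0.996,0.992,0.989,0.987,0.988,0.981,0.986,0.982,0.988
150.0,0.835,0.958,0.978,0.973,0.976,0.98,0.979,0.975,0.977,0.976,0.971,0.981,0.973,0.977
155.0,,0.923,0.958,0.964,0.966,0.966,0.969,0.966,0.968,0.959,0.959,0.966,0.966,0.966
160.0,,0.864,0.952,0.942,0.949,0.951,0.947,0.948,0.95,0.943,0.949,0.95,0.947,0.953
165.0,,0.774,0.919,0.92,0.921,0.934,0.929,0.926,0.929,0.921,0.923,0.936,0.934,0.937
170.0,,,0.899,0.907,0.905,0.91,0.911,0.906,0.912,0.913,0.903,0.911,0.916,0.937
175.0,,,,,0.896,0.902,0.904,0.911,0.904,0.902,0.895,0.908,0.906,0.913
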